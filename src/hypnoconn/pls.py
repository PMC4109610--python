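"""Mean-centered task PLS with permutation and bootstrap inference.

Task PLS asks whether a multivariate dataset (here: 378 edge connectivities,
or channel x frequency amplitudes) is systematically structured by the
experimental design (state x group).  The crossblock covariance between
design and data reduces, for a balanced mean-centered design, to the matrix
of group x condition cell means after centering; its singular value
decomposition yields latent variables (LVs): a design contrast (design
scores, left singular vector), a feature pattern (saliences, right singular
vector), and a singular value whose squared share of the total is the
percent of crossblock covariance explained.

Centering is within-group: each group's mean across its conditions is
removed from that group's cell means.  With 2 groups x 2 conditions this
leaves each group a rank-1 +/- condition contrast, so exactly 2 of the 4 LVs
carry signal (singular values 3-4 are numerically zero) and LV1 + LV2
account for 100% of the crossblock covariance.

Inference is by resampling:

* permutation - condition labels are shuffled within each subject (groups,
  a between-subject factor, are never permuted); the p-value of LV k is the
  fraction of permutations whose k-th singular value meets or exceeds the
  observed one (k/n convention, so 13 exceedances in 1000 reads p = 0.013).
* bootstrap - subjects are resampled with replacement within group, both
  conditions of a subject moving together; each resample's saliences are
  sign-aligned to the observed ones and the bootstrap ratio (BSR) is the
  observed salience over its bootstrap standard error, a pseudo-z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONDITIONS, GROUPS, StudyManifest

__all__ = ["FeatureMatrix", "PLSResult", "build_feature_matrix",
           "mean_centered_svd", "pct_crossblock", "permutation_pvalues",
           "bootstrap_ratios", "significant_features", "run_pls",
           "format_pvalue"]


@dataclass
class FeatureMatrix:
    """Observations (one row per subject x condition) by features.

    Rows are ordered by group (high before low), then subject, then
    condition (pre before hypnosis).  ``rows`` carries the per-row metadata.
    """

    X: np.ndarray
    rows: pd.DataFrame          # columns: subject, group, condition
    feature_ids: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.rows) != self.X.shape[0]:
            raise ValueError("row metadata length mismatch")
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature id length mismatch")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        counts = self.rows.groupby("subject")["condition"].nunique()
        if (counts != len(CONDITIONS)).any():
            bad = counts[counts != len(CONDITIONS)].index.tolist()
            raise ValueError(
                f"subject(s) {bad} lack exactly one row per condition")

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if (self.rows["group"] == g).any()]

    def condition_arrays(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(pre, hypnosis) row blocks for ``group``, subject-aligned."""
        sel = self.rows["group"] == group
        sub = self.rows[sel]
        subjects = sub["subject"].unique()
        out = []
        for cond in CONDITIONS:
            idx = [sub.index[(sub["subject"] == s)
                             & (sub["condition"] == cond)][0]
                   for s in subjects]
            out.append(self.X[idx])
        return out[0], out[1]


@dataclass
class PLSResult:
    """All LVs of a mean-centered task PLS with optional resampling fields."""

    singular_values: np.ndarray          # (n_lv,), non-increasing
    pct_crossblock: np.ndarray           # (n_lv,), sums to 100
    design_scores: np.ndarray            # (n_cells, n_lv)
    saliences: np.ndarray                # (n_features, n_lv)
    cells: list[tuple[str, str]]         # (group, condition) per row
    feature_ids: list
    perm_p: np.ndarray | None = None
    n_permutations: int | None = None
    bootstrap_ratios: np.ndarray | None = None   # (n_features, n_lv)
    salience_se: np.ndarray | None = None
    unstable_features: np.ndarray | None = None  # bool mask, SE == 0
    n_bootstraps: int | None = None
    seed: int | None = None

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)


def build_feature_matrix(features: Mapping[tuple[str, str], np.ndarray],
                         manifest: StudyManifest,
                         feature_ids: Sequence | None = None,
                         ) -> FeatureMatrix:
    """Assemble per-recording feature vectors into a FeatureMatrix.

    ``features`` maps (subject, condition) to a 1-D feature vector; every
    manifest subject must have both conditions.
    """
    rows = []
    vecs = []
    for group in GROUPS:
        block = manifest.entries[manifest.entries["group"] == group]
        for subject in block["subject"]:
            for cond in CONDITIONS:
                key = (subject, cond)
                if key not in features:
                    raise ValueError(
                        f"subject {subject!r} missing features for "
                        f"condition {cond!r}")
                vecs.append(np.asarray(features[key], dtype=float))
                rows.append({"subject": subject, "group": group,
                             "condition": cond})
    X = np.vstack(vecs)
    if feature_ids is None:
        feature_ids = list(range(X.shape[1]))
    return FeatureMatrix(X, pd.DataFrame(rows), list(feature_ids))


def _cell_means(fm: FeatureMatrix) -> tuple[np.ndarray, list[tuple[str, str]]]:
    cells = [(g, c) for g in fm.groups for c in CONDITIONS]
    M = np.empty((len(cells), fm.X.shape[1]))
    for r, (g, c) in enumerate(cells):
        sel = (fm.rows["group"] == g) & (fm.rows["condition"] == c)
        if not sel.any():
            raise ValueError(f"empty design cell {(g, c)}")
        M[r] = fm.X[sel.to_numpy()].mean(axis=0)
    return M, cells


def _center_within_group(M: np.ndarray, cells: list[tuple[str, str]],
                         ) -> np.ndarray:
    R = M.copy()
    groups = {g for g, _ in cells}
    for g in groups:
        idx = [i for i, (gg, _) in enumerate(cells) if gg == g]
        R[idx] -= M[idx].mean(axis=0, keepdims=True)
    return R


def _svd_signed(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD with a deterministic sign convention.

    The largest-magnitude element of each salience column is made positive
    (ties broken by index), removing the sign ambiguity of the SVD.
    """
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return U, s, V


def pct_crossblock(singular_values: np.ndarray) -> np.ndarray:
    """Percent of crossblock covariance per LV: 100 s_k^2 / sum s^2."""
    s = np.asarray(singular_values, dtype=float)
    if (s < 0).any():
        raise ValueError("singular values must be non-negative")
    total = (s ** 2).sum()
    if total == 0:
        raise ValueError("all singular values are zero")
    return 100.0 * s ** 2 / total


def mean_centered_svd(fm: FeatureMatrix) -> PLSResult:
    """Crossblock SVD of the within-group-centered cell means.

    Returns all n_cells LVs in decreasing singular-value order (with 2
    groups x 2 conditions: four LVs, of which the last two are numerically
    zero by the rank of the centering).
    """
    M, cells = _cell_means(fm)
    R = _center_within_group(M, cells)
    U, s, V = _svd_signed(R)
    return PLSResult(s, pct_crossblock(s), U, V, cells,
                     list(fm.feature_ids))


def permutation_pvalues(fm: FeatureMatrix, n_perm: int = 1000,
                        seed: int | np.random.SeedSequence = 0,
                        convention: str = "k/n") -> np.ndarray:
    """Per-LV permutation p-values for the observed singular values.

    Each permutation independently re-assigns condition labels within each
    subject (a fair coin per subject; groups are never exchanged), the
    crossblock SVD is recomputed, and LV k's p-value is the fraction of
    permutations with s_k_perm >= s_k_observed.  ``convention`` selects
    "k/n" (default; an observed maximum reports p = 0, i.e. "p < 1/n") or
    the add-one variant "(k+1)/(n+1)".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if convention not in ("k/n", "(k+1)/(n+1)"):
        raise ValueError(f"unknown p-value convention {convention!r}")
    rng = np.random.default_rng(seed)
    blocks = [fm.condition_arrays(g) for g in fm.groups]
    s_obs = mean_centered_svd(fm).singular_values
    exceed = np.zeros_like(s_obs)
    cells = [(g, c) for g in fm.groups for c in CONDITIONS]
    n_features = fm.X.shape[1]
    for _ in range(n_perm):
        M = np.empty((2 * len(blocks), n_features))
        for gi, (A, B) in enumerate(blocks):
            flip = rng.random(A.shape[0]) < 0.5
            pre = np.where(flip[:, None], B, A)
            hyp = np.where(flip[:, None], A, B)
            M[2 * gi] = pre.mean(axis=0)
            M[2 * gi + 1] = hyp.mean(axis=0)
        R = _center_within_group(M, cells)
        s_perm = np.linalg.svd(R, compute_uv=False)
        exceed += s_perm >= s_obs - 1e-12
    if convention == "k/n":
        return exceed / n_perm
    return (exceed + 1) / (n_perm + 1)


def bootstrap_ratios(fm: FeatureMatrix, n_boot: int = 1000,
                     seed: int | np.random.SeedSequence = 0,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap ratios (observed salience / bootstrap SE) per feature x LV.

    Subjects are resampled with replacement within their group; both
    conditions of a drawn subject enter together, so no design cell can
    empty.  Each resample's salience columns are sign-aligned to the
    observed saliences (sign of their dot product) before the standard
    error is accumulated.

    Returns ``(bsr, se, unstable)`` where ``unstable`` flags features whose
    bootstrap SE is zero on some LV (their BSR is NaN and they are excluded
    from significant sets).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    obs = mean_centered_svd(fm)
    V_obs = obs.saliences
    blocks = [fm.condition_arrays(g) for g in fm.groups]
    cells = obs.cells
    n_lv = obs.n_lv
    acc = np.zeros_like(V_obs)
    acc2 = np.zeros_like(V_obs)
    for _ in range(n_boot):
        M = np.empty((len(cells), V_obs.shape[0]))
        for gi, (A, B) in enumerate(blocks):
            idx = rng.integers(0, A.shape[0], A.shape[0])
            M[2 * gi] = A[idx].mean(axis=0)
            M[2 * gi + 1] = B[idx].mean(axis=0)
        R = _center_within_group(M, cells)
        _, _, Vb = _svd_signed(R)
        # align each resampled LV's sign with the observed salience pattern
        signs = np.sign(np.einsum("fk,fk->k", Vb[:, :n_lv], V_obs))
        signs[signs == 0] = 1.0
        Vb = Vb[:, :n_lv] * signs
        acc += Vb
        acc2 += Vb ** 2
    var = (acc2 - acc ** 2 / n_boot) / (n_boot - 1)
    se = np.sqrt(np.clip(var, 0.0, None))
    unstable = se <= 1e-10  # numerically-zero SE: salience not resampled
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(unstable, np.nan, V_obs / se)
    return bsr, se, unstable


def significant_features(result: PLSResult, threshold: float = 2.0,
                         ) -> list[list[tuple[int, int]]]:
    """Per-LV signed significant features: |BSR| >= threshold.

    Returns, for each LV, a list of (feature index, sign-of-salience) pairs.
    Features flagged unstable (zero bootstrap SE) are never significant.
    """
    if result.bootstrap_ratios is None:
        raise ValueError("bootstrap ratios not computed")
    out = []
    for k in range(result.n_lv):
        bsr = result.bootstrap_ratios[:, k]
        ok = np.isfinite(bsr) & (np.abs(bsr) >= threshold)
        if result.unstable_features is not None:
            ok &= ~result.unstable_features[:, k]
        out.append([(int(i), int(np.sign(result.saliences[i, k])) or 1)
                    for i in np.flatnonzero(ok)])
    return out


def run_pls(fm: FeatureMatrix, n_perm: int = 1000, n_boot: int = 1000,
            bsr_threshold: float = 2.0,
            seed: int | np.random.SeedSequence = 0) -> PLSResult:
    """Full task-PLS analysis: SVD + permutation test + bootstrap ratios."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    perm_seed, boot_seed = ss.spawn(2)
    result = mean_centered_svd(fm)
    result.perm_p = permutation_pvalues(fm, n_perm, perm_seed)
    result.n_permutations = n_perm
    bsr, se, unstable = bootstrap_ratios(fm, n_boot, boot_seed)
    result.bootstrap_ratios = bsr
    result.salience_se = se
    result.unstable_features = unstable
    result.n_bootstraps = n_boot
    return result


def format_pvalue(p: float, n_perm: int) -> str:
    """Report a permutation p-value; an empty exceedance count prints as a
    bound (e.g. '< 0.001' for 0/1000)."""
    if p <= 0:
        return f"< {1.0 / n_perm:.3g}"
    return f"{p:.3f}"
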