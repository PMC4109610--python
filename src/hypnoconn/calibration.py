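"""Monte-Carlo calibration and recovery experiments for the full pipeline.

Two study-level experiments validate the inference chain end to end:

* type-I calibration - many independent null studies (no planted effects;
  all four design cells share one generative process) are simulated and
  analysed; the fraction of studies whose theta-iCOH LV1 permutation p-value
  falls below alpha estimates the empirical type-I error, which should sit
  inside the binomial confidence band around alpha.
* recovery - replicate studies carrying the planted Pz-hub theta-iCOH
  increase in the (high, hypnosis) cell are analysed, and each replicate is
  scored on four criteria: LV1 significance, the design-score contrast being
  concentrated in the high group, at least half the planted edges reaching
  |BSR| >= 2, and the hub-degree maximum landing on Pz.

Both experiments run on reduced study sizes (6-8 subjects per group, 1-min
recordings, 200 resamples) so a few hundred studies complete in minutes on
one core; docs/methods.md discusses what the reductions do and do not test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import hub_degree
from .io import Config
from .montage import default_montage
from .pipeline import run_study
from .pls import significant_features
from .simulate import (SimulationSpec, default_effect_couplings, make_study,
                       null_study)

__all__ = ["type1_calibration", "binomial_interval", "recovery_experiment",
           "PLANTED_THETA_EDGES"]

# The default planted theta hub: Pz to its eight neighbours.
PLANTED_THETA_EDGES: list[tuple[str, str]] = [
    ("Pz", nb) for nb in ("Cz", "CP1", "CP2", "P3", "P4", "PO1", "PO2", "Oz")]


def type1_calibration(n_studies: int = 200, n_high: int = 6, n_low: int = 6,
                      duration_s: float = 60.0, n_perm: int = 200,
                      seed: int = 0) -> np.ndarray:
    """LV1 permutation p-values of the theta-iCOH PLS over null studies.

    Each study is simulated with an independent seed and analysed with the
    reduced configuration; returns the array of LV1 p-values.
    """
    ss = np.random.SeedSequence(seed)
    study_seeds = ss.generate_state(2 * n_studies) % (2 ** 31)
    pvals = np.empty(n_studies)
    for i in range(n_studies):
        spec = SimulationSpec(duration_s=duration_s,
                              seed=int(study_seeds[2 * i]))
        study = null_study(spec, n_high=n_high, n_low=n_low)
        cfg = Config(n_permutations=n_perm, n_bootstraps=2,
                     seed=int(study_seeds[2 * i + 1]))
        res = run_study(study, cfg, bands=["theta"], measures=("iCOH",),
                        amplitude=False)
        pvals[i] = res.connectivity_pls[("theta", "iCOH")].perm_p[0]
    return pvals


def binomial_interval(p: float, n: int, z: float = 1.96,
                      ) -> tuple[float, float]:
    """Normal-approximation 95% interval for a binomial proportion."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


@dataclass
class RecoveryOutcome:
    lv1_p: float
    design_contrast_high: float
    design_contrast_low: float
    frac_planted_recovered: float
    hub_max_labels: list[str]
    n_significant_edges: int

    @property
    def detected(self) -> bool:
        """All four recovery criteria: significance, design-score pattern,
        planted-edge recovery, and the Pz hub."""
        return (self.lv1_p <= 0.05
                and self.design_contrast_high > self.design_contrast_low
                and self.frac_planted_recovered >= 0.5
                and "Pz" in self.hub_max_labels)


def _score_replicate(res, bsr_threshold: float) -> RecoveryOutcome:
    r = res.connectivity_pls[("theta", "iCOH")]
    cell = {c: i for i, c in enumerate(r.cells)}
    u = r.design_scores[:, 0]
    hi = abs(u[cell[("high", "pre")]] - u[cell[("high", "hypnosis")]])
    lo = abs(u[cell[("low", "pre")]] - u[cell[("low", "hypnosis")]])
    sig = significant_features(r, bsr_threshold)[0]
    pairs = {tuple(sorted(res.pair_labels[i])) for i, _ in sig}
    planted = {tuple(sorted(e)) for e in PLANTED_THETA_EDGES}
    frac = len(planted & pairs) / len(planted)
    deg = hub_degree([res.pair_labels[i] for i, _ in sig], default_montage())
    return RecoveryOutcome(float(r.perm_p[0]), hi, lo, frac,
                           deg.attrs["max_labels"], len(sig))


def recovery_experiment(n_replicates: int = 50, n_high: int = 8,
                        n_low: int = 8, duration_s: float = 60.0,
                        n_perm: int = 200, n_boot: int = 200,
                        bsr_threshold: float = 2.0,
                        seed: int = 0) -> pd.DataFrame:
    """Detection of the planted theta effect over replicate studies.

    Returns one row per replicate with the four criterion columns and the
    overall ``detected`` flag.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * n_replicates) % (2 ** 31)
    rows = []
    for i in range(n_replicates):
        spec = SimulationSpec(duration_s=duration_s,
                              seed=int(rep_seeds[2 * i]),
                              couplings=default_effect_couplings())
        study = make_study(spec, n_high=n_high, n_low=n_low)
        cfg = Config(n_permutations=n_perm, n_bootstraps=n_boot,
                     bsr_threshold=bsr_threshold,
                     seed=int(rep_seeds[2 * i + 1]))
        res = run_study(study, cfg, bands=["theta"], measures=("iCOH",),
                        amplitude=False)
        out = _score_replicate(res, bsr_threshold)
        rows.append({
            "replicate": i, "lv1_p": out.lv1_p,
            "design_contrast_high": out.design_contrast_high,
            "design_contrast_low": out.design_contrast_low,
            "frac_planted_recovered": out.frac_planted_recovered,
            "hub_max": "+".join(out.hub_max_labels),
            "n_significant_edges": out.n_significant_edges,
            "detected": out.detected,
        })
    return pd.DataFrame(rows)
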