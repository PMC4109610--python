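import numpy as np
import pandas as pd
import pytest

import hypnoconn as hc
from hypnoconn.pls import _center_within_group, bootstrap_ratios, \
    format_pvalue, permutation_pvalues


def _manifest(n_high, n_low):
    rows = []
    for g, n in (("high", n_high), ("low", n_low)):
        for i in range(n):
            s = f"{g}{i}"
            rows.append({"subject": s, "group": g, "path_pre": s,
                         "path_hypnosis": s})
    return hc.StudyManifest(pd.DataFrame(rows))


def _features(manifest, p, seed=0, shift=None):
    """Random features; ``shift`` optionally maps (group, cond) -> offset
    added to the first p//2 features."""
    rng = np.random.default_rng(seed)
    out = {}
    for _, row in manifest.entries.iterrows():
        for cond in ("pre", "hypnosis"):
            x = rng.normal(size=p)
            if shift:
                x[: p // 2] += shift.get((row["group"], cond), 0.0)
            out[(row["subject"], cond)] = x
    return out


class TestFeatureMatrix:
    def test_study_sized_matrix(self):
        man = _manifest(12, 11)
        fm = hc.build_feature_matrix(_features(man, 378), man)
        assert fm.X.shape == (46, 378)
        # rows ordered by group, then subject, then condition
        assert list(fm.rows["group"][:24]) == ["high"] * 24
        assert list(fm.rows["condition"][:2]) == ["pre", "hypnosis"]

    def test_missing_condition_names_subject(self):
        man = _manifest(2, 2)
        feats = _features(man, 5)
        del feats[("high1", "hypnosis")]
        with pytest.raises(ValueError, match="high1"):
            hc.build_feature_matrix(feats, man)


class TestMeanCenteredSVD:
    def test_two_by_two_design_yields_four_lvs(self, random_feature_matrix):
        fm, _ = random_feature_matrix
        res = hc.mean_centered_svd(fm)
        assert res.n_lv == 4
        assert len(res.cells) == 4

    def test_lv3_and_lv4_numerically_zero(self, random_feature_matrix):
        """Within-group centering leaves each group a rank-1 contrast."""
        fm, _ = random_feature_matrix
        s = hc.mean_centered_svd(fm).singular_values
        assert (np.diff(s) <= 1e-12).all()  # non-increasing
        assert s[2] <= 1e-10 * s[0] and s[3] <= 1e-10 * s[0]

    def test_centered_rows_are_half_condition_difference(self):
        man = _manifest(3, 2)
        feats = _features(man, 6, shift={("high", "hypnosis"): 2.0})
        fm = hc.build_feature_matrix(feats, man)
        from hypnoconn.pls import _cell_means
        M, cells = _cell_means(fm)
        R = _center_within_group(M, cells)
        for gi in (0, 1):
            d = (M[2 * gi] - M[2 * gi + 1]) / 2
            np.testing.assert_allclose(R[2 * gi], d, atol=1e-12)
            np.testing.assert_allclose(R[2 * gi + 1], -d, atol=1e-12)

    def test_svd_reconstruction(self, random_feature_matrix):
        fm, _ = random_feature_matrix
        res = hc.mean_centered_svd(fm)
        from hypnoconn.pls import _cell_means
        M, cells = _cell_means(fm)
        R = _center_within_group(M, cells)
        rebuilt = (res.design_scores * res.singular_values
                   ) @ res.saliences.T
        err = np.linalg.norm(rebuilt - R) / np.linalg.norm(R)
        assert err <= 1e-10

    def test_orthonormal_scores_and_saliences(self, random_feature_matrix):
        fm, _ = random_feature_matrix
        res = hc.mean_centered_svd(fm)
        np.testing.assert_allclose(res.design_scores.T @ res.design_scores,
                                   np.eye(4), atol=1e-10)
        np.testing.assert_allclose(res.saliences.T @ res.saliences,
                                   np.eye(4), atol=1e-10)

    def test_pct_crossblock_examples(self):
        np.testing.assert_allclose(
            hc.pct_crossblock(np.array([2.0, 1.0, 0.0, 0.0])),
            [80.0, 20.0, 0.0, 0.0])
        rng = np.random.default_rng(1)
        s = np.sort(rng.uniform(0, 5, size=4))[::-1]
        assert hc.pct_crossblock(s).sum() == pytest.approx(100.0)

    def test_two_nonzero_lvs_sum_to_100(self, random_feature_matrix):
        fm, _ = random_feature_matrix
        res = hc.mean_centered_svd(fm)
        assert res.pct_crossblock[:2].sum() == pytest.approx(100.0)

    def test_all_zero_singular_values_rejected(self):
        with pytest.raises(ValueError):
            hc.pct_crossblock(np.zeros(4))


class TestPermutations:
    def test_counting_convention(self, random_feature_matrix):
        """p = (#permutations with s_perm >= s_obs) / n_perm."""
        fm, _ = random_feature_matrix
        p = permutation_pvalues(fm, n_perm=100, seed=3)
        assert p.shape == (4,)
        assert ((p * 100) % 1 < 1e-9).all()  # multiples of 1/100
        p1 = permutation_pvalues(fm, n_perm=100, seed=3,
                                 convention="(k+1)/(n+1)")
        np.testing.assert_allclose(p1, (p * 100 + 1) / 101)

    def test_reproducible_given_seed(self, random_feature_matrix):
        fm, _ = random_feature_matrix
        a = permutation_pvalues(fm, 50, seed=5)
        b = permutation_pvalues(fm, 50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_invariant_to_feature_order_and_subject_ids(self):
        man = _manifest(4, 3)
        feats = _features(man, 12, seed=9)
        fm = hc.build_feature_matrix(feats, man)
        p = permutation_pvalues(fm, 80, seed=1)
        # permute feature columns
        perm = np.random.default_rng(0).permutation(12)
        fm2 = hc.FeatureMatrix(fm.X[:, perm], fm.rows.copy(),
                               [fm.feature_ids[i] for i in perm])
        np.testing.assert_allclose(permutation_pvalues(fm2, 80, seed=1), p,
                                   atol=1e-12)
        # relabel subjects (order preserved)
        rows3 = fm.rows.copy()
        rows3["subject"] = rows3["subject"].map(lambda s: "x" + s)
        fm3 = hc.FeatureMatrix(fm.X, rows3, fm.feature_ids)
        np.testing.assert_allclose(permutation_pvalues(fm3, 80, seed=1), p,
                                   atol=1e-12)

    def test_strong_effect_beats_all_permutations(self):
        man = _manifest(6, 6)
        feats = _features(man, 20, seed=2,
                          shift={("high", "hypnosis"): 5.0,
                                 ("low", "hypnosis"): 5.0})
        fm = hc.build_feature_matrix(feats, man)
        p = permutation_pvalues(fm, 200, seed=4)
        assert p[0] == 0.0
        assert format_pvalue(p[0], 200) == "< 0.005"


class TestBootstrap:
    def test_sign_alignment_and_se(self, random_feature_matrix):
        fm, _ = random_feature_matrix
        bsr, se, unstable = bootstrap_ratios(fm, n_boot=100, seed=6)
        assert bsr.shape == se.shape == (20, 4)
        # signal-free LVs 3-4 have near-zero saliences -> tiny |BSR| overall
        assert np.isfinite(bsr[~unstable]).all()
        assert (se[:, :2] > 0).all()

    def test_constant_feature_is_flagged_unstable(self):
        man = _manifest(3, 3)
        feats = _features(man, 6, seed=8)
        for key in feats:
            feats[key][0] = 1.0  # constant across all rows
        fm = hc.build_feature_matrix(feats, man)
        res = hc.run_pls(fm, n_perm=10, n_boot=50, seed=0)
        # flagged on the two signal-carrying LVs (LVs 3-4 span an arbitrary
        # null basis, where even a constant feature's salience varies)
        assert res.unstable_features[0, :2].all()
        for lv_feats in hc.significant_features(res, 0.0)[:2]:
            assert 0 not in [i for i, _ in lv_feats]

    def test_planted_feature_has_large_bsr(self):
        man = _manifest(12, 11)
        feats = _features(man, 30, seed=10,
                          shift={("high", "hypnosis"): 1.5})
        fm = hc.build_feature_matrix(feats, man)
        bsr, _, _ = bootstrap_ratios(fm, n_boot=200, seed=11)
        planted = np.abs(bsr[:15, 0])
        background = np.abs(bsr[15:, 0])
        assert np.median(planted) > 2.0
        assert np.median(planted) > np.median(background)

    def test_reproducible_given_seed(self, random_feature_matrix):
        fm, _ = random_feature_matrix
        a = bootstrap_ratios(fm, 50, seed=12)[0]
        b = bootstrap_ratios(fm, 50, seed=12)[0]
        np.testing.assert_array_equal(a, b)


class TestSignificantFeatures:
    def _result_with_bsr(self, bsrs, saliences):
        n = len(bsrs)
        res = hc.PLSResult(
            singular_values=np.array([1.0]),
            pct_crossblock=np.array([100.0]),
            design_scores=np.ones((4, 1)),
            saliences=np.asarray(saliences)[:, None],
            cells=[("high", "pre"), ("high", "hypnosis"),
                   ("low", "pre"), ("low", "hypnosis")],
            feature_ids=list(range(n)),
            bootstrap_ratios=np.asarray(bsrs)[:, None],
            unstable_features=np.zeros((n, 1), bool))
        return res

    def test_threshold_selects_signed_features(self):
        res = self._result_with_bsr([2.5, -1.0, 3.0], [0.5, -0.2, -0.8])
        sig = hc.significant_features(res, 2.0)[0]
        assert sig == [(0, 1), (2, -1)]

    def test_threshold_above_max_gives_empty_set(self):
        res = self._result_with_bsr([2.5, -1.0, 3.0], [0.5, -0.2, -0.8])
        assert hc.significant_features(res, 10.0)[0] == []

    def test_lowering_threshold_is_monotone(self):
        rng = np.random.default_rng(13)
        bsrs = rng.normal(scale=2, size=50)
        res = self._result_with_bsr(bsrs, rng.normal(size=50))
        prev: set = set()
        for thr in (3.0, 2.0, 1.0, 0.5):
            cur = {i for i, _ in hc.significant_features(res, thr)[0]}
            assert prev <= cur
            prev = cur
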