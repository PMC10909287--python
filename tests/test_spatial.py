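"""Spatial statistics: thresholds, weights, Moran's I, ANOVA, Tukey."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from dynaccess.spatial import (
    auto_threshold,
    inverse_distance_weights,
    morans_i,
    one_way_anova,
    tukey_hsd,
)


def moran_oracle(values, w):
    """Direct double-loop evaluation of the cross-product formula."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    s0 = w.sum()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / s0 * num / (z @ z)


class TestAutoThreshold:
    def test_collinear_points(self):
        pts = [(0.0, 0.0), (1.0, 0.0), (3.0, 0.0)]
        assert auto_threshold(pts) == pytest.approx(2.0)

    def test_two_points(self):
        assert auto_threshold([(0, 0), (0, 7.5)]) == pytest.approx(7.5)

    def test_guarantees_a_neighbour_and_is_minimal(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1000, size=(20, 2))
        thr = auto_threshold(pts)
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert ((d <= thr).sum(axis=1) >= 1).all()
        assert not ((d <= thr * (1 - 1e-9)).sum(axis=1) >= 1).all()

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            auto_threshold([(0, 0), (0, 0), (1, 1)])


class TestInverseDistanceWeights:
    def test_two_points_half_weight(self):
        w = inverse_distance_weights([(0, 0), (2, 0)]).w
        assert w[0, 1] == w[1, 0] == pytest.approx(0.5)
        assert w[0, 0] == 0.0

    def test_beyond_threshold_zero(self):
        pts = [(0, 0), (1, 0), (10, 0)]
        w = inverse_distance_weights(pts, threshold_m=9.0).w
        assert w[0, 2] == 0.0
        assert w[1, 2] > 0.0

    def test_halving_coordinates_doubles_weights(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, size=(8, 2))
        a = inverse_distance_weights(pts)
        b = inverse_distance_weights(pts / 2.0)
        assert np.allclose(b.w, 2.0 * a.w)

    def test_below_auto_threshold_warns(self, caplog):
        with caplog.at_level("WARNING"):
            inverse_distance_weights([(0, 0), (5, 0)], threshold_m=1.0)
        assert any("no neighbour" in r.message for r in caplog.records)


class TestMoransI:
    def test_adjacent_like_values_positive_and_match_oracle(self):
        pts = [(0, 0), (0, 1), (3, 0), (3, 1)]
        values = [1.0, 1.0, -1.0, -1.0]  # like values adjacent within columns
        weights = inverse_distance_weights(pts, threshold_m=1.0)
        res = morans_i(values, weights, n_permutations=99, seed=0)
        assert res.I == pytest.approx(moran_oracle(values, weights.w), abs=1e-12)
        assert res.I > 0

    def test_checkerboard_negative(self):
        pts = [(i, j) for i in range(3) for j in range(3)]
        values = [(-1.0) ** (i + j) for i in range(3) for j in range(3)]
        weights = inverse_distance_weights(pts, threshold_m=1.0)
        res = morans_i(values, weights, n_permutations=99, seed=0)
        assert res.I == pytest.approx(moran_oracle(values, weights.w), abs=1e-12)
        assert res.I < 0

    def test_permuted_null_mean_is_expectation(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 10, size=(8, 2))
        values = rng.normal(size=8)
        weights = inverse_distance_weights(pts)
        perms = [
            moran_oracle(rng.permutation(values), weights.w) for _ in range(3000)
        ]
        mc_se = np.std(perms) / np.sqrt(len(perms))
        assert np.mean(perms) == pytest.approx(-1.0 / 7.0, abs=4 * mc_se)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 10, size=(7, 2))
        values = rng.normal(size=7)
        weights = inverse_distance_weights(pts)
        a = morans_i(values, weights, 49, seed=1)
        b = morans_i(5.0 * values + 3.0, weights, 49, seed=1)
        assert a.I == pytest.approx(b.I, abs=1e-12)
        assert a.p_permutation == b.p_permutation

    def test_constant_surface_rejected(self):
        weights = inverse_distance_weights([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError, match="constant"):
            morans_i([2.0, 2.0, 2.0], weights, 9, seed=0)

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 10, size=(9, 2))
        values = rng.normal(size=9)
        weights = inverse_distance_weights(pts)
        a = morans_i(values, weights, 199, seed=7)
        b = morans_i(values, weights, 199, seed=7)
        assert a.p_permutation == b.p_permutation

    def test_permutation_and_analytic_p_agree_roughly(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 10, size=(15, 2))
        # smooth surface: value = x coordinate -> strong clustering
        values = pts[:, 0] + rng.normal(scale=0.5, size=15)
        weights = inverse_distance_weights(pts)
        res = morans_i(values, weights, 999, seed=3)
        assert res.p_analytic < 0.1
        assert abs(res.p_permutation - res.p_analytic) < 0.1


def anova_oracle(groups):
    """Hand sum-of-squares decomposition."""
    allv = np.concatenate([np.asarray(v, float) for v in groups.values()])
    grand = allv.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, sps.f.sf(F, dfb, dfw)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.F == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_decomposition_and_scipy(self):
        groups = {"a": [2.1, 3.5, 1.9], "b": [4.0, 4.4, 5.1, 3.8], "c": [6.2, 5.9]}
        res = one_way_anova(groups)
        F, p = anova_oracle(groups)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)
        F2, p2 = sps.f_oneway(*[np.asarray(v) for v in groups.values()])
        assert res.F == pytest.approx(F2, rel=1e-9)
        assert res.df_between == 2
        assert res.df_within == 6

    def test_location_scale_behaviour(self):
        rng = np.random.default_rng(6)
        groups = {k: rng.normal(k, 1, size=5).tolist() for k in range(3)}
        base = one_way_anova(groups)
        shifted = one_way_anova({k: [v + 10 for v in g] for k, g in groups.items()})
        scaled = one_way_anova({k: [3 * v for v in g] for k, g in groups.items()})
        assert base.F == pytest.approx(shifted.F)
        assert base.F == pytest.approx(scaled.F)

    def test_degenerate_zero_within_variance(self):
        res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert math.isinf(res.F)
        assert res.p == 0.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": []})


def tukey_oracle(groups):
    """Pairwise intervals straight from the studentized-range quantile."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], float) for g in labels]
    k = len(arrays)
    N = sum(len(a) for a in arrays)
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (N - k)
    q = sps.studentized_range.ppf(0.95, k, N - k)
    out = {}
    for a, b in itertools.combinations(range(k), 2):
        na, nb = len(arrays[a]), len(arrays[b])
        hw = q / math.sqrt(2.0) * math.sqrt(msw * (1.0 / na + 1.0 / nb))
        out[(labels[a], labels[b])] = (arrays[a].mean() - arrays[b].mean(), hw)
    return out


class TestTukey:
    def test_identical_groups(self):
        pairs = tukey_hsd({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert pairs[0].difference == 0.0
        assert pairs[0].p_adjusted == pytest.approx(1.0)

    def test_two_groups_reduce_to_t_test(self):
        a, b = [1.2, 2.3, 1.8, 2.9], [3.1, 4.0, 3.4]
        pair = tukey_hsd({"a": a, "b": b})[0]
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert pair.p_adjusted == pytest.approx(t_p, rel=1e-6)

    def test_three_groups_match_quantile_oracle(self):
        groups = {"a": [2.0, 3.1, 2.5, 2.8], "b": [4.2, 3.9, 4.8], "c": [1.1, 0.9, 1.5, 1.2]}
        pairs = {(p.group_a, p.group_b): p for p in tukey_hsd(groups)}
        oracle = tukey_oracle(groups)
        for key, (diff, hw) in oracle.items():
            assert pairs[key].difference == pytest.approx(diff, rel=1e-9)
            assert pairs[key].half_width == pytest.approx(hw, rel=1e-6)

    def test_interval_p_consistency(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            groups = {
                k: rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(3, 7)).tolist()
                for k in range(3)
            }
            for p in tukey_hsd(groups):
                assert (abs(p.difference) > p.half_width) == (p.p_adjusted < 0.05)
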