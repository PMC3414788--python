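"""KS machinery, distribution fitting, grouping and mean tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import famotion as fm


def ecdf_enumeration_ks(a, b):
    """Independent oracle: evaluate both ECDFs on the pooled support."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    support = np.unique(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), support, side="right") / a.size
    fb = np.searchsorted(np.sort(b), support, side="right") / b.size
    return np.max(np.abs(fa - fb))


class TestKSStatistic:
    def test_identical_samples(self):
        assert fm.ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fully_separated(self):
        assert fm.ks_statistic([1, 2], [10, 11]) == 1.0

    def test_small_example_enumeration(self):
        # a={1,2}, b={1.5,2.5}: ECDFs differ by 1/2 on the pooled support
        assert fm.ks_statistic([1, 2], [1.5, 2.5]) == pytest.approx(0.5)

    def test_matches_oracle_on_random_samples(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, int(rng.integers(2, 30)))
            b = rng.normal(0.3, 1.2, int(rng.integers(2, 30)))
            assert fm.ks_statistic(a, b) == pytest.approx(
                ecdf_enumeration_ks(a, b), abs=1e-12)

    def test_pseudometric_properties(self, rng):
        for _ in range(200):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 1, 15)
            c = rng.exponential(1.0, 9)
            dab = fm.ks_statistic(a, b)
            dac = fm.ks_statistic(a, c)
            dbc = fm.ks_statistic(b, c)
            assert dab == pytest.approx(fm.ks_statistic(b, a))  # symmetry
            assert 0.0 <= dab <= 1.0
            assert fm.ks_statistic(a, a) == 0.0
            assert dac <= dab + dbc + 1e-12  # triangle inequality on ECDFs

    @given(st.floats(0.1, 5.0), st.floats(-3, 3))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_invariance_under_increasing_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 25)
        d0 = fm.ks_statistic(a, b)
        f = lambda x: np.exp(scale * x) + shift  # strictly increasing
        assert fm.ks_statistic(f(a), f(b)) == pytest.approx(d0, abs=1e-12)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            fm.ks_statistic([], [1.0])


class TestMeanPairwiseKS:
    def test_identical_groups(self):
        g = {"no": [1, 2, 3], "low": [1, 2, 3], "high": [1, 2, 3]}
        assert fm.mean_pairwise_ks(g) == 0.0

    def test_fully_separated_groups(self):
        g = {"no": [1, 2], "low": [10, 11], "high": [20, 21]}
        assert fm.mean_pairwise_ks(g) == 1.0

    def test_matches_hand_enumeration(self):
        g = {"a": [1.0, 2.0], "b": [1.5, 2.5], "c": [3.0, 4.0]}
        expected = (ecdf_enumeration_ks(g["a"], g["b"])
                    + ecdf_enumeration_ks(g["a"], g["c"])
                    + ecdf_enumeration_ks(g["b"], g["c"])) / 3
        assert fm.mean_pairwise_ks(g) == pytest.approx(expected)

    def test_wrong_group_count(self):
        with pytest.raises(ValueError, match="3"):
            fm.mean_pairwise_ks({"a": [1], "b": [2]})


class TestFitDistribution:
    def test_lognormal_quantile_construction(self):
        n = 500
        q = np.arange(1, n + 1) / (n + 1)
        x = stats.lognorm.ppf(q, s=0.5, scale=np.exp(1.0))
        fit = fm.fit_distribution(x, "lognormal")
        assert fit.params[0] == pytest.approx(1.0, rel=0.02)
        assert fit.params[1] == pytest.approx(0.5, rel=0.02)

    def test_gaussian_quantile_construction(self):
        n = 5000
        q = np.arange(1, n + 1) / (n + 1)
        fit = fm.fit_distribution(stats.norm.ppf(q), "gaussian")
        assert fit.params[0] == pytest.approx(0.0, abs=1e-3)
        assert fit.params[1] == pytest.approx(1.0, abs=1e-3)

    def test_weibull_recovery_from_draws(self, rng):
        x = 10.0 * np.random.default_rng(3).weibull(1.5, 5000)
        fit = fm.fit_distribution(x, "weibull")
        assert fit.params[0] == pytest.approx(1.5, rel=0.05)
        assert fit.params[1] == pytest.approx(10.0, rel=0.05)
        assert fit.ks_distance < 0.03

    def test_optimizer_improves_on_initialization(self, rng):
        x = rng.lognormal(0.5, 0.8, 300)
        fit = fm.fit_distribution(x, "lognormal")
        assert fit.ks_distance <= fit.ks_init + 1e-12

    def test_error_cases(self, rng):
        with pytest.raises(ValueError, match="positive"):
            fm.fit_distribution([-1.0] * 10 + [1.0] * 10, "lognormal")
        with pytest.raises(ValueError, match="constant"):
            fm.fit_distribution([2.0] * 20, "gaussian")
        with pytest.raises(ValueError):
            fm.fit_distribution(rng.normal(size=3), "gaussian")  # too few
        with pytest.raises(ValueError, match="family"):
            fm.fit_distribution(rng.lognormal(size=20), "gamma")

    def test_summary_and_cdf_roundtrip(self, rng):
        x = rng.lognormal(0.0, 0.5, 200)
        fit = fm.fit_distribution(x, "lognormal")
        assert "lognormal" in fit.summary()
        assert fm.one_sample_ks(x, fit.cdf) == pytest.approx(fit.ks_distance)


class TestGrouping:
    def test_egf_dose_binning(self):
        gs = fm.group_by_egf([0, 0.01, 0.1, 1, 10, 100], [1, 2, 3, 4, 5, 6])
        assert sorted(gs.groups["no"]) == [1]
        assert sorted(gs.groups["low"]) == [2, 3]
        assert sorted(gs.groups["high"]) == [4, 5, 6]

    def test_unrecognized_dose_names_it(self):
        with pytest.raises(ValueError, match="0.5"):
            fm.group_by_egf([0.5], [1.0])

    def test_speed_split_and_boundary(self):
        gs = fm.group_by_speed([30, 50], [1.0, 2.0], cutoff=42.0)
        assert list(gs.groups["slow"]) == [1.0]
        assert list(gs.groups["fast"]) == [2.0]
        # a speed exactly at the cutoff is slow under the strict "greater than"
        at = fm.group_by_speed([42.0], [9.0], cutoff=42.0)
        assert list(at.groups["slow"]) == [9.0]

    def test_cutoff_from_kmeans_is_consistent(self):
        part = fm.kmeans_speed_cutoff([10, 12, 14, 60, 62, 64])
        gs = fm.group_by_speed([10, 12, 14, 60, 62, 64],
                               np.arange(6.0), cutoff=part.cutoff)
        assert gs.groups["slow"].size == 3 and gs.groups["fast"].size == 3

    def test_missing_speed_error(self):
        with pytest.raises(ValueError, match="index 1"):
            fm.group_by_speed([30.0, np.nan], [1.0, 2.0], cutoff=42.0)


class TestMeanDifferenceTest:
    def test_identical_groups_not_significant(self, rng):
        x = rng.normal(0, 1, 40)
        t, p, sig = fm.mean_difference_test(x, x.copy())
        assert p > 0.9 and not sig

    def test_large_shift_significant(self, rng):
        a = rng.normal(0, 1, 50)
        t, p, sig = fm.mean_difference_test(a, a + 10.0)
        assert sig and p < 1e-10

    def test_student_variant_matches_pooled_formula_oracle(self, rng):
        a = rng.normal(0, 1.0, 17)
        b = rng.normal(0.4, 1.0, 23)
        t, p, _ = fm.mean_difference_test(a, b, equal_var=True)
        na, nb = a.size, b.size
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_oracle, rel=1e-10)

    def test_degenerate_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            fm.mean_difference_test([1.0, 1.0], [1.0, 1.0])


def test_null_mean_pairwise_ks_calibration(rng):
    # three groups from one distribution: averaged pairwise D stays small
    vals = []
    for _ in range(200):
        g = {k: rng.normal(0, 1, 200) for k in ("no", "low", "high")}
        vals.append(fm.mean_pairwise_ks(g))
    assert np.mean(vals) < 0.12
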