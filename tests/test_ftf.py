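"""One-way ANOVA F statistics, critical values, masks and topographies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import betaincinv

from ftfa.ftf import (
    FTFMap,
    GroupCountError,
    GroupedPixelSamples,
    ReplicationError,
    Topography,
    average_maps,
    band_topography,
    between_group_variance,
    critical_f,
    f_value,
    ftf_map,
    group_dof,
    significance_mask,
    within_group_variance,
)
from ftfa.tfr import TFRSet


def gps(*arrays):
    return GroupedPixelSamples({str(i): np.asarray(a, float) for i, a in enumerate(arrays)})


class TestDof:
    def test_study_groups(self):
        assert group_dof([72, 72, 72, 72]) == (3, 284)

    def test_minimal_replication(self):
        assert group_dof([2, 2]) == (1, 2)

    def test_single_group_rejected(self):
        with pytest.raises(GroupCountError):
            group_dof([10])

    def test_all_singletons_rejected(self):
        with pytest.raises(ReplicationError):
            group_dof([1, 1])


class TestVarianceComponents:
    def test_between_zero_for_equal_means(self):
        assert between_group_variance(gps([5, 5], [5, 5])) == 0.0

    def test_between_hand_value(self):
        # means 0 and 2, grand mean 1 → (2·1 + 2·1)/(2−1) = 4
        assert between_group_variance(gps([0, 0], [2, 2])) == pytest.approx(4.0)

    def test_between_singleton_groups(self):
        assert between_group_variance(gps([1], [3])) == pytest.approx(2.0)

    def test_within_zero_for_constant_groups(self):
        assert within_group_variance(gps([3, 3], [7, 7])) == 0.0

    def test_within_hand_value(self):
        # deviations ±1 in each group → 4/(4−2) = 2
        assert within_group_variance(gps([0, 2], [1, 3])) == pytest.approx(2.0)

    def test_within_requires_replication(self):
        with pytest.raises(ReplicationError):
            within_group_variance(gps([1], [3]))


class TestFValue:
    def test_equal_means_give_zero(self):
        assert f_value(gps([0, 2], [1, 1])) == 0.0

    def test_textbook_example(self):
        # between 8, within 1/3 → F = 24
        assert f_value(gps([0, 0, 1, 1], [2, 2, 3, 3])) == pytest.approx(24.0)

    def test_within_zero_between_positive_is_inf(self):
        assert f_value(gps([1, 1], [2, 2])) == np.inf

    def test_all_identical_is_zero(self):
        assert f_value(gps([2, 2], [2, 2])) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(seed=st.integers(0, 10_000))
    def test_matches_independent_anova(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 7))
        arrays = [rng.normal(size=int(rng.integers(2, 31))) for _ in range(K)]
        ours = f_value(gps(*arrays))
        ref = stats.f_oneway(*arrays).statistic
        assert ours == pytest.approx(ref, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_two_groups_equal_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=12), rng.normal(1.0, size=9)
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert f_value(gps(a, b)) == pytest.approx(t**2, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    def test_location_scale_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        arrays = [rng.normal(size=8), rng.normal(0.5, size=10), rng.normal(1.0, size=6)]
        f0 = f_value(gps(*arrays))
        f1 = f_value(gps(*[a * x + b for x in arrays]))
        assert f1 == pytest.approx(f0, rel=1e-6)


class TestCriticalF:
    def test_study_threshold(self):
        assert critical_f(0.01, 3, 284) == pytest.approx(3.851286, abs=1e-4)

    def test_small_sample_value(self):
        assert critical_f(0.05, 1, 10) == pytest.approx(4.9646, abs=1e-3)

    def test_monotone_in_alpha(self):
        assert critical_f(0.05, 3, 284) < critical_f(0.01, 3, 284)

    def test_agrees_with_incomplete_beta_inversion(self):
        # independent oracle: F quantile from the regularized incomplete beta
        for alpha in (0.1, 0.05, 0.01):
            for d1, d2 in [(1, 10), (3, 284), (5, 40)]:
                x = betaincinv(d2 / 2, d1 / 2, alpha)
                q = d2 * (1 - x) / (d1 * x)
                assert critical_f(alpha, d1, d2) == pytest.approx(q, rel=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            critical_f(0.0, 3, 284)
        with pytest.raises(ValueError):
            critical_f(0.01, 0, 284)


def _tfr_from(power, fs=250.0):
    n_tr, n_ch, n_f, n_t = power.shape
    labels = [f"g{t % 2 + 1}" for t in range(n_tr)]
    return TFRSet(
        power=power,
        freqs=np.arange(1, n_f + 1, dtype=float),
        times=np.arange(n_t) / fs,
        fs=fs,
        labels=labels,
        channel_labels=[f"c{i}" for i in range(n_ch)],
    )


class TestFtfMap:
    def test_identical_trials_give_zero_map(self):
        power = np.tile(np.random.default_rng(0).gamma(1.0, size=(1, 1, 4, 10)), (6, 1, 1, 1))
        tfr = _tfr_from(power)
        groups = {"g1": np.arange(0, 6, 2), "g2": np.arange(1, 6, 2)}
        fmap = ftf_map(tfr, groups)
        assert np.all(fmap.f_values == 0.0)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(1)
        power = rng.gamma(2.0, size=(20, 2, 3, 7))
        tfr = _tfr_from(power)
        groups = {"g1": np.arange(0, 20, 2), "g2": np.arange(1, 20, 2)}
        fmap = ftf_map(tfr, groups)
        assert fmap.df_between == 1 and fmap.df_within == 18
        for c in range(2):
            for f in range(3):
                for t in range(7):
                    ref = stats.f_oneway(
                        power[groups["g1"], c, f, t], power[groups["g2"], c, f, t]
                    ).statistic
                    assert fmap.f_values[c, f, t] == pytest.approx(ref, rel=1e-9)

    def test_planted_pixel_is_global_argmax(self):
        rng = np.random.default_rng(2)
        power = rng.normal(10.0, 1.0, size=(24, 1, 6, 20))
        groups = {"g1": np.arange(12), "g2": np.arange(12, 24)}
        power[groups["g2"], 0, 3, 11] += 10.0
        fmap = ftf_map(_tfr_from(np.abs(power)), groups)
        assert np.unravel_index(np.argmax(fmap.f_values), fmap.f_values.shape) == (0, 3, 11)

    def test_group_referencing_missing_trial_rejected(self):
        tfr = _tfr_from(np.ones((4, 1, 2, 3)))
        with pytest.raises(IndexError):
            ftf_map(tfr, {"g1": np.array([0, 1]), "g2": np.array([2, 9])})


class TestSignificanceMask:
    def _map(self, f):
        f = np.asarray(f, dtype=float)
        return FTFMap(
            f_values=f,
            df_between=3,
            df_within=284,
            group_sizes={c: 72 for c in "abcd"},
            freqs=np.arange(1, f.shape[1] + 1, dtype=float),
            times=np.arange(f.shape[2], dtype=float),
            channel_labels=[f"c{i}" for i in range(f.shape[0])],
        )

    def test_zero_map_nothing_significant(self):
        for corr in ("none", "bonferroni", "bh-fdr"):
            mask, _ = significance_mask(self._map(np.zeros((1, 2, 5))), 0.01, corr)
            assert not mask.any()

    def test_single_pixel_above_study_threshold(self):
        mask, thr = significance_mask(self._map([[[5.0]]]), 0.01, "none")
        assert mask[0, 0, 0] and thr == pytest.approx(3.851286, abs=1e-4)

    def test_bonferroni_divides_alpha_by_pixel_count(self):
        fmap = self._map(np.ones((1, 10, 10)))
        _, thr = significance_mask(fmap, 0.01, "bonferroni")
        assert thr == pytest.approx(critical_f(0.01 / 100, 3, 284), rel=1e-12)

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError, match="correction"):
            significance_mask(self._map(np.zeros((1, 1, 1))), 0.01, "holm")

    def test_fdr_matches_manual_step_up(self):
        rng = np.random.default_rng(3)
        f = rng.chisquare(3, size=(1, 8, 8)) / 3
        f[0, 0, :4] = 15.0
        fmap = self._map(f)
        mask, _ = significance_mask(fmap, 0.05, "bh-fdr")
        p = stats.f.sf(f.ravel(), 3, 284)
        order = np.argsort(p)
        m = len(p)
        crit = 0.05 * (np.arange(1, m + 1)) / m
        below = np.nonzero(p[order] <= crit)[0]
        expect = np.zeros(m, bool)
        if below.size:
            expect[order[: below.max() + 1]] = True
        assert np.array_equal(mask.ravel(), expect)


class TestAverageMaps:
    def _map(self, f):
        return TestSignificanceMask._map(self, f)

    def test_single_map_identity(self):
        m = self._map(np.random.default_rng(4).chisquare(3, (1, 2, 3)))
        out = average_maps([m])
        np.testing.assert_array_equal(out.f_values, m.f_values)

    def test_mean_of_constant_maps(self):
        out = average_maps([self._map(np.full((1, 2, 2), 2.0)), self._map(np.full((1, 2, 2), 4.0))])
        np.testing.assert_allclose(out.f_values, 3.0)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_maps([self._map(np.ones((1, 2, 2))), self._map(np.ones((1, 3, 2)))])


class TestBandTopography:
    def _map(self, f_values, freqs, times, labels):
        return FTFMap(
            f_values=f_values,
            df_between=3,
            df_within=284,
            group_sizes={c: 72 for c in "abcd"},
            freqs=freqs,
            times=times,
            channel_labels=labels,
        )

    def test_inclusive_band_edges_on_integer_grid(self):
        freqs = np.arange(1, 41.0)
        times = np.arange(0, 4, 0.1)
        f = np.zeros((1, 40, 40))
        f[0, 16:27, :] = 1.0  # rows 17..27 Hz
        fmap = self._map(f, freqs, times, ["Cz"])
        topo = band_topography(fmap, 17, 27, [(0.0, 4.0)], {"Cz": (0, 0)})[0]
        assert topo.channel_values["Cz"] == pytest.approx(1.0)  # 11 rows, all ones
        topo2 = band_topography(fmap, 9, 15, [(0.0, 4.0)], {"Cz": (0, 0)})[0]
        assert topo2.channel_values["Cz"] == 0.0  # 7 rows, all zero

    def test_uniform_map_gives_constant_value(self):
        fmap = self._map(np.full((2, 10, 20), 3.3), np.arange(1, 11.0),
                         np.arange(20) / 10, ["C3", "C4"])
        topos = band_topography(fmap, 2, 5, [(0.0, 1.0), (1.0, 2.0)],
                                {"C3": (-0.5, 0), "C4": (0.5, 0)})
        assert len(topos) == 2
        for t in topos:
            assert all(v == pytest.approx(3.3) for v in t.channel_values.values())

    def test_empty_band_rejected(self):
        fmap = self._map(np.ones((1, 5, 5)), np.arange(1, 6.0), np.arange(5.0), ["Cz"])
        with pytest.raises(ValueError, match="no frequency"):
            band_topography(fmap, 40, 50, [(0, 5)], {"Cz": (0, 0)})

    def test_topography_requires_positions(self):
        with pytest.raises(ValueError, match="position"):
            Topography({"Cz": 1.0}, {}, (9, 15), (0, 1))
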