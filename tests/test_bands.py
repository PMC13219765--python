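"""Band statistics: bandwidth, percentiles, RAD, impulse, extremes,
strategies, Wilcoxon."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solband.bands import (SolutionBand, band_summary, bandwidth_ratio,
                           cross_joint_effect, extreme_solutions, impulse,
                           peak_differences, percent_force_variation, rad,
                           strategy_matrix, wilcoxon_signed_rank)
from solband.errors import DegenerateDataError, ParameterError
from solband.solver import ActivationSolution, WeightVector

from oracles import wilcoxon_brute_p


def const_band(values, joint="knee", mode="unconstrained"):
    curves = np.tile(np.asarray(values, dtype=float)[:, None], (1, 101))
    weights = [WeightVector.ones(3) for _ in values]
    return SolutionBand(curves, weights, joint, mode)


class TestBandSummary:
    def test_constant_curves(self):
        bs = band_summary(const_band([1.0, 2.0, 5.0]), peaks=(25, 75))
        np.testing.assert_allclose(bs.bandwidth, 4.0)
        assert bs.mean_bandwidth == pytest.approx(4.0)
        assert bs.sd_bandwidth == pytest.approx(0.0)
        assert bs.peak_bandwidth == (4.0, 4.0)
        assert bs.peak_envelope == ((1.0, 5.0), (1.0, 5.0))

    def test_single_curve_zero_bandwidth(self):
        bs = band_summary(const_band([2.5]), peaks=(25, 75))
        np.testing.assert_allclose(bs.bandwidth, 0.0)

    def test_linear_interpolation_quantiles(self):
        bs = band_summary(const_band(list(range(1, 11))), peaks=(25, 75),
                          lo=10, hi=90)
        np.testing.assert_allclose(bs.percentile_lo, 1.9)
        np.testing.assert_allclose(bs.percentile_hi, 9.1)

    def test_percentile_band_nested_in_envelope(self):
        rng = np.random.default_rng(0)
        band = SolutionBand(rng.random((40, 101)),
                            [WeightVector.ones(2)] * 40, "hip", "unconstrained")
        bs = band_summary(band, peaks=(25, 75))
        assert np.all(bs.percentile_lo >= band.curves.min(axis=0) - 1e-12)
        assert np.all(bs.percentile_hi <= band.curves.max(axis=0) + 1e-12)
        full = band_summary(band, peaks=(25, 75), lo=0, hi=100)
        np.testing.assert_allclose(full.percentile_lo, band.curves.min(axis=0))
        np.testing.assert_allclose(full.percentile_hi, band.curves.max(axis=0))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        curves = rng.random((20, 101))
        b1 = SolutionBand(curves, [WeightVector.ones(2)] * 20, "hip", "unconstrained")
        perm = rng.permutation(20)
        b2 = SolutionBand(curves[perm], [WeightVector.ones(2)] * 20, "hip",
                          "unconstrained")
        s1 = band_summary(b1, (25, 75))
        s2 = band_summary(b2, (25, 75))
        np.testing.assert_allclose(s1.bandwidth, s2.bandwidth)
        np.testing.assert_allclose(s1.percentile_lo, s2.percentile_lo)

    def test_empty_band_rejected(self):
        with pytest.raises(ParameterError):
            SolutionBand(np.empty((0, 101)), [], "knee", "unconstrained")


class TestBandwidthRatio:
    def test_identical_bands(self):
        bs = band_summary(const_band([1.0, 3.0]), peaks=(25, 75))
        assert bandwidth_ratio(bs, bs) == pytest.approx(1.0)

    def test_half_bandwidth(self):
        u = band_summary(const_band([0.0, 2.0]), peaks=(25, 75))
        c = band_summary(const_band([0.5, 1.5]), peaks=(25, 75))
        assert bandwidth_ratio(c, u) == pytest.approx(0.5)

    def test_hand_computed_means(self):
        # constrained per-point bandwidths {1,1,3} vs unconstrained {2,2,2}
        con = np.zeros((2, 101))
        con[1, :34] = 1.0
        con[1, 34:67] = 1.0
        con[1, 67:] = 3.0
        unc = np.zeros((2, 101))
        unc[1] = 2.0
        cb = SolutionBand(con, [WeightVector.ones(2)] * 2, "knee",
                          "emg_constrained")
        ub = SolutionBand(unc, [WeightVector.ones(2)] * 2, "knee",
                          "unconstrained")
        # means: constrained (34*1 + 33*1 + 34*3)/101, unconstrained 2
        expected = ((34 + 33 + 34 * 3) / 101) / 2.0
        got = bandwidth_ratio(band_summary(cb, (25, 75)),
                              band_summary(ub, (25, 75)))
        assert got == pytest.approx(expected)

    def test_mismatched_windows_rejected(self):
        u = band_summary(const_band([0.0, 2.0]), peaks=(25, 75))
        c = band_summary(const_band([0.0, 2.0]), peaks=(25, 75),
                         window=(25, 75))
        with pytest.raises(ParameterError):
            bandwidth_ratio(c, u)


class TestImpulseAndRad:
    def test_impulse_constant(self):
        assert impulse(np.full(101, 2.0)) == pytest.approx(200.0)

    def test_impulse_zero(self):
        assert impulse(np.zeros(101)) == pytest.approx(0.0)

    def test_impulse_ramp(self):
        assert impulse(np.linspace(0, 4, 101)) == pytest.approx(200.0)

    def test_rad_identical(self):
        c = np.linspace(1, 2, 101)
        assert rad(c, c) == pytest.approx(0.0)

    @pytest.mark.parametrize("scale, expected", [(1.25, 25.0), (0.9, -10.0)])
    def test_rad_scaling(self, scale, expected):
        c = np.linspace(1, 2, 101)
        assert rad(c, scale * c) == pytest.approx(expected)

    def test_rad_nonpositive_reference(self):
        with pytest.raises(ParameterError):
            rad(np.zeros(101), np.ones(101))

    @given(scale=st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_under_scaling(self, scale):
        c = np.linspace(0.5, 3.0, 101)
        assert impulse(scale * c) == pytest.approx(scale * impulse(c))
        assert rad(c, scale * c) == pytest.approx(100.0 * (scale - 1.0))


class TestExtremesAndCrossJoint:
    def test_constant_band_extremes(self):
        imin, imax, _, _ = extreme_solutions(const_band([1.0, 2.0, 5.0]))
        assert (imin, imax) == (0, 2)

    def test_tie_breaks_to_lowest_index(self):
        imin, imax, _, _ = extreme_solutions(const_band([1.5, 1.5]))
        assert imin == 0 and imax == 0

    def test_mixed_curves_by_impulse(self):
        curves = np.vstack([np.linspace(0, 2, 101),
                            np.full(101, 1.5),
                            np.full(101, 0.5)])
        band = SolutionBand(curves, [WeightVector.ones(2)] * 3, "knee",
                            "unconstrained")
        imin, imax, _, _ = extreme_solutions(band)
        assert (imin, imax) == (2, 1)  # impulses {100, 150, 50}

    def test_cross_joint_hand_computed(self):
        # knee impulses {200, 100, 500}: min at 1, max at 2
        knee = const_band([2.0, 1.0, 5.0])
        hip = const_band([1.0, 1.2, 0.9], joint="hip")    # AUCs {100,120,90}
        ankle = const_band([1.0, 1.0, 1.0], joint="ankle")
        out = cross_joint_effect(knee, hip, ankle)
        assert out["hip"]["at_knee_min_vs_min_pct"] == pytest.approx(
            100 * (120 - 90) / 90)
        assert out["ankle"]["at_knee_min_vs_min_pct"] == pytest.approx(0.0)
        assert out["hip"]["at_knee_max_vs_max_pct"] == pytest.approx(
            100 * (90 - 120) / 120)

    def test_single_sample_degenerate(self):
        knee = const_band([2.0])
        hip = const_band([1.0], joint="hip")
        ankle = const_band([1.0], joint="ankle")
        out = cross_joint_effect(knee, hip, ankle)
        for j in ("hip", "ankle"):
            assert out[j]["at_knee_min_vs_min_pct"] == pytest.approx(0.0)
            assert out[j]["at_knee_max_vs_max_pct"] == pytest.approx(0.0)


class TestPeakAndForceComparisons:
    def test_peak_differences(self):
        ref = np.zeros(101)
        ref[25], ref[75] = 2.0, 3.0
        sol = np.zeros(101)
        sol[25], sol[75] = 1.2, 2.1
        assert peak_differences(sol, ref, (25, 75)) == (
            pytest.approx(-0.8), pytest.approx(-0.9))
        assert peak_differences(ref, ref, (25, 75)) == (0.0, 0.0)
        assert peak_differences(ref + 1.0, ref, (25, 75)) == (
            pytest.approx(1.0), pytest.approx(1.0))

    def _solution(self, forces):
        n, m = forces.shape
        return ActivationSolution(
            activations=forces, muscle_forces=forces,
            reserve_torques=np.zeros((n, 1)), cost=np.zeros(n),
            residuals=np.zeros((n, 1)), converged=np.ones(n, bool),
            frame_window=(0, n - 1), weights=WeightVector.ones(m))

    def test_percent_force_variation(self):
        names = ["a", "b", "c"]
        ref = self._solution(np.ones((11, 3)))
        sol_forces = np.ones((11, 3))
        sol_forces[:, 1] = 0.0          # zeroed muscle: -100 %
        sol_forces[:, 2] = 3.0          # tripled impulse: +200 %
        sol = self._solution(sol_forces)
        out = percent_force_variation(sol, ref, names, names)
        assert out["a"] == pytest.approx(0.0)
        assert out["b"] == pytest.approx(-100.0)
        assert out["c"] == pytest.approx(200.0)

    def test_undefined_reference_flagged(self):
        names = ["a"]
        ref = self._solution(np.zeros((11, 1)))
        sol = self._solution(np.ones((11, 1)))
        out = percent_force_variation(sol, ref, names, names)
        assert np.isnan(out["a"])


class TestStrategyMatrix:
    def test_identical_vectors_cluster(self):
        wv = WeightVector(np.array([1.0, 10.0, 1.0]))
        mat, clusters = strategy_matrix([wv, wv])
        assert mat.shape == (2, 3)
        assert clusters == {(1.0, 10.0, 1.0): [0, 1]}

    def test_distinct_vectors_singletons(self):
        vs = [WeightVector(np.array([1.0, 1.0])),
              WeightVector(np.array([10.0, 1.0])),
              WeightVector(np.array([100.0, 1.0]))]
        _, clusters = strategy_matrix(vs)
        assert all(len(v) == 1 for v in clusters.values())

    def test_mixed_grouping(self):
        a = WeightVector(np.array([1.0, 10.0]))
        b = WeightVector(np.array([10.0, 10.0]))
        _, clusters = strategy_matrix([a, a, b])
        assert sorted(len(v) for v in clusters.values()) == [1, 2]


class TestWilcoxon:
    def test_degenerate_identical_samples(self):
        x = np.arange(8.0)
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(x, x)

    def test_all_positive_differences_exact_p(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = x - 1.0
        stat, p, sig = wilcoxon_signed_rank(x, y)
        assert stat == pytest.approx(21.0)   # W+ = n(n+1)/2
        assert p == pytest.approx(2 / 64)
        assert sig

    def test_single_negative_difference(self):
        d = np.array([1.0, 2, 3, 4, 5, 6, 7, -8])
        stat, p, sig = wilcoxon_signed_rank(d, np.zeros(8))
        # W- = 8, so W+ = 28: p must match the brute-force oracle
        assert stat == pytest.approx(28.0)
        assert p == pytest.approx(wilcoxon_brute_p(d, np.zeros(8)))

    def test_matches_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 15))
            d = rng.standard_normal(n)
            d = d[d != 0]
            if np.unique(np.abs(d)).size != d.size or d.size < 5:
                continue  # scipy's exact path requires untied |d|
            _, p, _ = wilcoxon_signed_rank(d, np.zeros(d.size))
            ref = scipy_wilcoxon(d, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60) + 0.8
        y = np.zeros(60)
        _, p, sig = wilcoxon_signed_rank(x, y)
        from scipy.stats import wilcoxon as scipy_wilcoxon
        ref = scipy_wilcoxon(x, alternative="two-sided", method="approx",
                             correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert sig
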