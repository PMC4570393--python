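"""Log downsampling and flow quantification (A, tau_half, beta, Siegert)."""

import numpy as np
import pytest

import dcstools as d

TAU_C = 1e-3  # 1 ms reference decorrelation time
HALF = TAU_C / 2 * np.log(2)


def analytic_curve(beta=0.5, tau_c=TAU_C, n=1000, lo=1e-7, hi=1e-1):
    tau = np.logspace(np.log10(lo), np.log10(hi), n)
    g2 = 1.0 + beta * np.exp(-2.0 * tau / tau_c)
    return d.CorrelationCurve(tau, g2, "analytic", n, 1.0)


def linear_curve(g2_of_tau, dt=1e-6, n=20000):
    tau = np.arange(1, n + 1) * dt
    return d.CorrelationCurve(tau, g2_of_tau(tau), "analytic", n, 1.0)


class TestDownsampleLog:
    def test_constant_curve_stays_constant(self):
        tau = np.arange(1, 2001) * 1e-6
        curve = d.CorrelationCurve(tau, np.full(2000, 1.3), "x", 2000, 1.0)
        down = d.downsample_log(curve, d.LogGrid(1e-6, 2e-3, 8))
        np.testing.assert_allclose(down.g2, 1.3, rtol=1e-14)

    def test_nearest_assignment_matches_brute_force(self):
        tau = np.arange(1, 11) * 1e-3
        g2 = 1.0 + 0.1 * np.arange(10)
        curve = d.CorrelationCurve(tau, g2, "x", 10, 1.0)
        grid = d.LogGrid(1e-3, 1e-2, 1)  # grid points exactly {1, 10} ms
        down = d.downsample_log(curve, grid)
        gd = grid.delays()
        assign = np.argmin(np.abs(np.log(tau)[:, None] - np.log(gd)[None, :]), axis=1)
        expected = [g2[assign == j].mean() for j in range(gd.size) if np.any(assign == j)]
        np.testing.assert_allclose(down.g2, expected, rtol=1e-14)

    def test_output_size_and_value_bounds(self):
        tau = np.arange(1, 501) * 1e-6
        rng = np.random.default_rng(0)
        g2 = 1.0 + rng.random(500)
        curve = d.CorrelationCurve(tau, g2, "x", 500, 1.0)
        grid = d.LogGrid(1e-6, 5e-4, 8)
        down = d.downsample_log(curve, grid)
        assert len(down) <= min(grid.delays().size, len(curve))
        assert down.g2.min() >= g2.min() and down.g2.max() <= g2.max()

    def test_no_overlap_raises(self):
        curve = d.CorrelationCurve(np.array([1e-6, 2e-6]), np.array([1.0, 1.0]), "x", 2, 1.0)
        with pytest.raises(d.EmptyOverlapError):
            d.downsample_log(curve, d.LogGrid(1e-2, 1e-1, 8))


class TestAmplitude:
    def test_constant_curve_has_zero_amplitude(self):
        curve = d.CorrelationCurve(np.array([1e-6, 2e-6]), np.array([1.2, 1.2]), "x", 2, 1.0)
        assert d.amplitude(curve) == 0.0

    def test_analytic_amplitude_from_sampled_values(self):
        tau = np.logspace(np.log10(TAU_C / 100), np.log10(10 * TAU_C), 400)
        g2 = 1.0 + 0.5 * np.exp(-2.0 * tau / TAU_C)
        curve = d.CorrelationCurve(tau, g2, "x", 400, 1.0)
        expected = 0.5 * (np.exp(-0.02) - np.exp(-20.0))
        assert d.amplitude(curve) == pytest.approx(expected, rel=1e-12)

    def test_empty_curve_rejected(self):
        empty = d.CorrelationCurve(np.array([]), np.array([]), "x", 0, 1.0)
        with pytest.raises(ValueError):
            d.amplitude(empty)


class TestTauHalf:
    def test_closed_form_half_decay(self):
        assert d.tau_half(analytic_curve()) == pytest.approx(HALF, rel=1e-3)

    def test_two_point_midpoint(self):
        curve = d.CorrelationCurve(np.array([1e-3, 2e-3]), np.array([1.5, 1.0]), "x", 2, 1.0)
        assert d.tau_half(curve) == pytest.approx(1.5e-3)

    def test_halving_tau_c_halves_tau_half(self):
        t1 = d.tau_half(analytic_curve(tau_c=TAU_C))
        t2 = d.tau_half(analytic_curve(tau_c=TAU_C / 2))
        assert t2 / t1 == pytest.approx(0.5, rel=2e-3)

    def test_flat_curve_distinct_error(self):
        curve = d.CorrelationCurve(np.array([1e-6, 2e-6]), np.array([1.0, 1.0]), "x", 2, 1.0)
        with pytest.raises(d.FlatCurveError):
            d.tau_half(curve)

    def test_no_crossing_distinct_error(self):
        # rising curve: never decays after its maximum
        curve = d.CorrelationCurve(
            np.array([1e-6, 2e-6, 3e-6]), np.array([1.0, 1.2, 1.5]), "x", 3, 1.0
        )
        with pytest.raises(d.NoCrossingError):
            d.tau_half(curve)

    def test_nearest_sample_variant(self):
        curve = analytic_curve(n=40, lo=1e-5, hi=1e-2)
        snapped = d.tau_half(curve, interpolate=False)
        assert snapped in curve.delays

    def test_invariant_under_log_downsampling(self):
        dense = linear_curve(lambda t: 1.0 + 0.5 * np.exp(-2.0 * t / TAU_C), dt=2e-6, n=10000)
        t_dense = d.tau_half(dense)
        down = d.downsample_log(dense, d.LogGrid(2e-6, 2e-2, 10))
        assert d.tau_half(down) == pytest.approx(t_dense, rel=0.02)


class TestBeta:
    def test_analytic_intercept(self):
        assert d.estimate_beta(analytic_curve(beta=0.5)) == pytest.approx(0.5, rel=1e-3)

    def test_unity_curve_gives_zero(self):
        curve = d.CorrelationCurve(np.array([1e-6, 2e-6]), np.array([1.0, 1.0]), "x", 2, 1.0)
        assert d.estimate_beta(curve) == 0.0

    def test_negative_estimate_clipped_with_warning(self):
        curve = d.CorrelationCurve(np.array([1e-6, 2e-6]), np.array([0.9, 0.95]), "x", 2, 1.0)
        with pytest.warns(RuntimeWarning):
            assert d.estimate_beta(curve) == 0.0

    def test_k_validation(self):
        with pytest.raises(ValueError):
            d.estimate_beta(analytic_curve(), 0)


class TestSiegertInversion:
    def test_forward_then_inverse_recovers_g1(self):
        # tau <= 3 tau_c keeps g2-1 large enough that forming the forward
        # curve in double precision does not itself destroy 1e-12 agreement
        curve = analytic_curve(beta=0.5, lo=1e-7, hi=3e-3)
        g1_curve = d.g1_from_g2(curve, 0.5)
        np.testing.assert_allclose(
            g1_curve.g2, np.exp(-curve.delays / TAU_C), rtol=0, atol=1e-12
        )

    def test_limits(self):
        curve = d.CorrelationCurve(np.array([1e-6, 1e-2]), np.array([1.5, 1.0]), "x", 2, 1.0)
        g1 = d.g1_from_g2(curve, 0.5)
        assert g1.g2[0] == pytest.approx(1.0)
        assert g1.g2[1] == 0.0

    def test_beta_validation(self):
        with pytest.raises(ValueError):
            d.g1_from_g2(analytic_curve(), 0.0)


class TestFlowComparison:
    def test_identical_curves_zero_difference(self):
        c = analytic_curve()
        assert d.compare_flow(c, c) == 0.0

    def test_stated_formula(self):
        # flows in ratio 1.5 (tau_half scales with tau_c): symmetric percent
        # difference 100*|f_a-f_b|/((f_a+f_b)/2) = 40%
        a = analytic_curve(tau_c=TAU_C)
        b = analytic_curve(tau_c=TAU_C / 1.5)
        assert d.compare_flow(a, b) == pytest.approx(40.0, rel=1e-2)

    def test_replicate_summary_of_equal_curves(self):
        c = analytic_curve()
        summ = d.replicate_summary([c, c, c])
        assert summ.sd_flow == pytest.approx(0.0, abs=1e-8 * summ.mean_flow)
        assert summ.n == 3
        assert summ.mean_flow == pytest.approx(1.0 / d.tau_half(c))

    def test_replicate_summary_needs_two(self):
        with pytest.raises(ValueError):
            d.replicate_summary([analytic_curve()])

    def test_flow_summary_invariant(self):
        summary = d.summarize_curve(analytic_curve())
        assert summary.flow_parameter == 1.0 / summary.tau_half
        assert summary.beta == pytest.approx(0.5, rel=1e-3)
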