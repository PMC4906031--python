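"""Continuous-time model: transfer function, bilinear map, saturation, fitting."""

import numpy as np
import pytest
from scipy import signal

from emolearn import ConfigError, FitError
from emolearn.continuous import (
    ContinuousConfig,
    ContinuousTrace,
    ErrorSpikeTrain,
    bilinear_discretize,
    error_path_analysis,
    fit_parameters,
    inverse_bilinear,
    scenario_figure6,
    simulate_lti,
    simulate_saturating,
    transfer_function,
)


def step(amplitude, t0=0.0):
    return lambda t: np.where(t >= t0, amplitude, 0.0)


class TestTransferFunction:
    def test_printed_coefficients(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2.0, tau2=2.0)
        num, den = transfer_function(cfg)
        np.testing.assert_allclose(num, [0.5 * 2.0, 0.5 + 2.0, 1.0])
        d2 = 2.0 + 0.5 - 0.5 * 0.4
        np.testing.assert_allclose(den, [2.0 * d2, d2 + 2.0 - 0.4 * 2.0, 0.6])

    def test_dc_gain(self):
        num, den = transfer_function(ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2))
        assert num[-1] / den[-1] == pytest.approx(1 / 0.6)

    def test_first_order_low_pass_limit(self):
        """K -> 0, tau2 -> 0 degenerates to a gain-1/(1-alpha) RC filter."""
        alpha, tau1 = 0.4, 1.5
        num, den = transfer_function(ContinuousConfig(alpha=alpha, K=0.0, tau2=1e-9, tau1=tau1))
        w = np.logspace(-2, 1, 20)
        H = np.polyval(num, 1j * w) / np.polyval(den, 1j * w)
        H_ref = (1 / (1 - alpha)) / (1 + 1j * w * tau1)
        np.testing.assert_allclose(H, H_ref, rtol=1e-6)

    def test_denominator_stable_for_default_parameters(self):
        _, den = transfer_function(ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2))
        assert np.all(np.roots(den).real < 0)


class TestLinearSimulation:
    def test_rest_stays_at_rest(self):
        cfg = ContinuousConfig(alpha=0.5, K=0.2, tau1=1, tau2=1)
        trace = simulate_lti(lambda t: np.zeros_like(t), cfg, horizon=10)
        np.testing.assert_allclose(trace.y, 0.0, atol=1e-12)

    def test_step_final_value(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.0, tau1=1, tau2=1)
        trace = simulate_lti(step(10.0), cfg, horizon=60)
        assert trace.y[-1] == pytest.approx(10 / 0.6, abs=0.01)

    @pytest.mark.parametrize("alpha,K,tau1,tau2", [
        (0.2, 0.0, 1.0, 1.0), (0.5, 0.3, 2.0, 0.5), (0.8, 0.6, 0.5, 2.0),
    ])
    def test_final_value_consistency_grid(self, alpha, K, tau1, tau2):
        """LTI step asymptote equals the discrete asymptote x/(1-alpha)."""
        cfg = ContinuousConfig(alpha=alpha, K=K, tau1=tau1, tau2=tau2)
        trace = simulate_lti(step(3.0), cfg, horizon=120)
        assert trace.y[-1] == pytest.approx(3.0 / (1 - alpha), rel=1e-3)

    def test_impulse_response_integrates_to_dc_gain(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2)
        num, den = transfer_function(cfg)
        t, h = signal.impulse((num, den), T=np.linspace(0, 200, 20000))
        # biproper H: the impulse response carries a Dirac mass num0/den0
        feedthrough = num[0] / den[0]
        assert np.trapezoid(h, t) + feedthrough == pytest.approx(1 / 0.6, rel=1e-3)


class TestBilinear:
    def test_dc_preserved_exactly(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2)
        nz, dz = bilinear_discretize(transfer_function(cfg), T=0.5)
        assert np.sum(nz) / np.sum(dz) == pytest.approx(1 / 0.6, rel=1e-14)

    def test_matches_scipy_cont2discrete(self):
        cfg = ContinuousConfig(alpha=0.3, K=0.2, tau1=1.5, tau2=0.7)
        num, den = transfer_function(cfg)
        nz, dz = bilinear_discretize((num, den), T=0.2)
        (nz_ref,), dz_ref, _ = signal.cont2discrete((num, den), dt=0.2, method="bilinear")
        np.testing.assert_allclose(nz, np.atleast_1d(nz_ref) / dz_ref[0], atol=1e-12)
        np.testing.assert_allclose(dz, dz_ref / dz_ref[0], atol=1e-12)

    def test_round_trip_recovers_continuous_coefficients(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2)
        num, den = transfer_function(cfg)
        nz, dz = bilinear_discretize((num, den), T=0.5)
        ns, ds = inverse_bilinear((nz, dz), T=0.5)
        np.testing.assert_allclose(ns / ns[0], num / num[0], atol=1e-9)
        np.testing.assert_allclose(ds / ds[0], den / den[0], atol=1e-9)

    def test_discrete_step_response_reaches_same_asymptote(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2)
        nz, dz = bilinear_discretize(transfer_function(cfg), T=0.1)
        y = signal.lfilter(nz, dz, np.ones(5000))
        trace = simulate_lti(step(1.0), cfg, horizon=200)
        assert y[-1] == pytest.approx(trace.y[-1], rel=1e-3)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ConfigError):
            bilinear_discretize((np.array([1.0]), np.array([1.0, 1.0])), T=0.0)


@pytest.fixture(scope="module")
def fig6():
    return {p: scenario_figure6(p) for p in ("A1", "A2", "B1", "B2")}


class TestSaturating:
    def test_quiescent_without_drive(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2, T=2, sat_threshold=150)
        trace = simulate_saturating(None, 0.0, cfg, horizon=5.0)
        np.testing.assert_allclose(trace.y, 0.0, atol=1e-12)
        np.testing.assert_allclose(trace.P, 0.0, atol=1e-12)

    def test_missing_threshold_rejected(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2)
        with pytest.raises(ConfigError):
            simulate_saturating(None, 0.0, cfg, horizon=1.0)

    def test_traumatic_acquisition_plateaus_at_alpha_times_threshold(self, fig6):
        trace = fig6["B1"]
        tail = trace.i_R[trace.t > 8.0]
        np.testing.assert_allclose(tail, 60.0, atol=1e-9)
        assert trace.P.max() > 150.0

    def test_stressful_acquisition_stays_linear(self, fig6):
        assert fig6["A1"].P.max() < 150.0
        assert fig6["A1"].i_R.max() < 60.0

    def test_safe_context_devalues_sub_saturation_response(self, fig6):
        peak = fig6["A1"].y.max()
        assert fig6["A2"].y[-1] < 0.1 * peak

    def test_failed_devaluation_keeps_saturated_plateau(self, fig6):
        assert fig6["B2"].i_R[-1] == pytest.approx(fig6["B1"].i_R[-1], abs=1e-6)
        assert fig6["B2"].i_R[-1] == pytest.approx(60.0, abs=1e-6)

    def test_large_inhibition_desaturates_and_reduces_output(self):
        """A negative error larger than the accumulated degree of saturation
        pushes the state back into the linear zone, where it devalues."""
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2, T=2, sat_threshold=150)
        up = ErrorSpikeTrain(events=[(0.5, 200.0 / 0.05, 0.05)])
        down = ErrorSpikeTrain(events=[(0.5, 200.0 / 0.05, 0.05), (4.0, -180.0 / 0.05, 0.05)])
        tr_up = simulate_saturating(up, 0.0, cfg, horizon=20.0)
        tr_down = simulate_saturating(down, 0.0, cfg, horizon=20.0)
        assert tr_up.i_R[-1] == pytest.approx(60.0, abs=1e-9)
        assert tr_down.i_R[-1] < 10.0

    def test_spike_increments_accumulator_by_injected_mass(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.0, tau1=2, tau2=2, T=2, sat_threshold=np.inf)
        train = ErrorSpikeTrain(events=[(1.0, 7.0 / 0.1, 0.1)])
        trace = simulate_saturating(train, 0.0, cfg, horizon=1.2, loop_tracking=False)
        assert trace.P[-1] == pytest.approx(7.0, rel=1e-9)

    def test_linear_regime_matches_lti_step_asymptote(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2, T=2, sat_threshold=np.inf)
        sat = simulate_saturating(None, step(5.0), cfg, horizon=150.0)
        lti = simulate_lti(step(5.0), cfg, horizon=150.0)
        assert sat.y[-1] == pytest.approx(lti.y[-1], rel=0.02)

    def test_output_bounded_by_clamp_plus_input(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2, T=2, sat_threshold=150)
        train = ErrorSpikeTrain(events=[(0.5, 1e4, 0.05), (2.0, 1e4, 0.05)])
        trace = simulate_saturating(train, step(2.0), cfg, horizon=30.0)
        bound = (1 + 0.5) * (2.0 + 0.4 * 150.0)
        assert np.max(trace.y) <= bound + 1e-6

    def test_grid_refinement_convergence(self):
        base = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2, T=2,
                                sat_threshold=np.inf, dt=0.05)
        fine = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2, T=2,
                                sat_threshold=np.inf, dt=0.025)
        a = simulate_saturating(None, step(1.0), base, horizon=20.0)
        b = simulate_saturating(None, step(1.0), fine, horizon=20.0)
        scale = np.max(np.abs(a.y))
        np.testing.assert_allclose(a.y, b.y[::2], atol=1e-3 * scale)

    def test_unknown_panel_rejected(self):
        with pytest.raises(ConfigError):
            scenario_figure6("C1")


class TestErrorPath:
    def test_raw_accumulator_unbounded_full_loop_bounded(self):
        cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=2, tau2=2, T=2, sat_threshold=np.inf)
        report = error_path_analysis(cfg, horizon=100.0)
        assert not report.bounded_raw_accumulator
        assert 0.0 in report.poles_raw_accumulator  # pure integration
        assert report.bounded_full_loop
        assert np.all(report.poles_full_loop.real < 0)


@pytest.fixture(scope="module")
def step_trace():
    cfg = ContinuousConfig(alpha=0.4, K=0.5, tau1=1.0, tau2=2.0)
    return simulate_lti(step(3.0, t0=1.0), cfg, horizon=40)


class TestFit:
    def test_noiseless_recovery_within_one_percent(self, step_trace):
        fit = fit_parameters(step_trace, tau1=1.0)
        assert fit.alpha == pytest.approx(0.4, rel=0.01)
        assert fit.K == pytest.approx(0.5, rel=0.01)
        assert fit.tau2 == pytest.approx(2.0, rel=0.01)

    def test_noisy_recovery_within_five_percent(self, step_trace):
        rng = np.random.default_rng(11)
        noisy = ContinuousTrace(
            t=step_trace.t, x=step_trace.x,
            y=step_trace.y + 0.01 * np.max(np.abs(step_trace.y)) * rng.standard_normal(step_trace.y.size),
            i_R=step_trace.i_R, e=step_trace.e, P=step_trace.P, P_ofc=step_trace.P_ofc,
        )
        fit = fit_parameters(noisy, tau1=1.0)
        assert fit.alpha == pytest.approx(0.4, rel=0.05)
        assert fit.tau2 == pytest.approx(2.0, rel=0.05)

    def test_no_excitation_rejected(self):
        n = 100
        flat = ContinuousTrace(
            t=np.linspace(0, 10, n), x=np.zeros(n), y=np.zeros(n),
            i_R=np.zeros(n), e=np.zeros(n), P=np.zeros(n), P_ofc=np.zeros(n),
        )
        with pytest.raises(FitError):
            fit_parameters(flat, tau1=1.0)

    def test_discrete_trace_closed_form_regression(self):
        from emolearn.revaluation import RevaluationParams, StimulusSchedule, simulate_revaluation

        xs = 2.0 * np.abs(np.sin(0.7 * np.arange(1, 80)))
        trace = simulate_revaluation(StimulusSchedule(x=xs), RevaluationParams(alpha=0.35, K=0.2))
        fit = fit_parameters(trace)
        assert fit.alpha == pytest.approx(0.35, abs=1e-9)
        assert fit.K == pytest.approx(0.2, abs=1e-9)
        assert fit.tau2 is None
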