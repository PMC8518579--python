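"""Effluent-trace analysis and the synthesis/analysis closure."""

import numpy as np
import pytest

from cdisorb import (
    EffluentTrace,
    OperatingPoint,
    analyze_cycles,
    charge_efficiency_exp,
    detect_cycles,
    integrate_sac,
    predict_constant_current,
    solve_solution_state,
    synthesize_trace,
    trace_to_concentrations,
)


def flat_trace(acid, n=50, c=0.01, ph=8.0, current=None):
    kappa = solve_solution_state(c, ph, acid).conductivity
    if current is None:
        current = np.r_[np.full(n // 2, 0.05), np.zeros(n - n // 2)]
    return EffluentTrace(
        time=np.arange(n) * 10.0,
        conductivity=np.full(n, kappa),
        pH=np.full(n, ph),
        flow_rate=np.full(n, 2e-3),
        current_program=current,
        feed_c_total=c,
        feed_pH=ph,
    )


@pytest.fixture(scope="module")
def prediction(params, acid, cell):
    op = OperatingPoint(mode="constant_current", dphi_pot=1.3, current=0.05,
                        c_feed=0.01, pH_feed=8.0, flow_rate=2e-3)
    return op, predict_constant_current(op, params, acid, cell)


@pytest.fixture(scope="module")
def clean_trace(prediction, acid, cell):
    op, res = prediction
    return synthesize_trace(op, res, acid, cell, n_cycles=4, dt=10.0, seed=3)


class TestTraceToConcentrations:
    def test_constant_feed_recovers_exactly(self, acid):
        trace = flat_trace(acid)
        c, ok = trace_to_concentrations(trace, acid)
        assert ok.all()
        assert c == pytest.approx(np.full(c.size, 0.01), rel=1e-3)

    def test_step_depletion_recovered(self, acid):
        trace = flat_trace(acid, n=40)
        lowered = solve_solution_state(0.007, 8.0, acid).conductivity
        trace.conductivity[20:] = lowered
        c, ok = trace_to_concentrations(trace, acid)
        assert ok.all()
        assert c[:20] == pytest.approx(np.full(20, 0.010), rel=1e-3)
        assert c[20:] == pytest.approx(np.full(20, 0.007), rel=1e-3)

    def test_bad_samples_flagged_not_fatal(self, acid):
        trace = flat_trace(acid, n=10)
        trace.conductivity[3] = 1e-9  # below the water floor
        c, ok = trace_to_concentrations(trace, acid)
        assert not ok[3] and np.isnan(c[3])
        assert ok.sum() == 9


class TestIntegrateSac:
    def test_rectangular_depletion_hand_integral(self, acid):
        # 1 mM depletion for 30 min at 2 mL/min over 3.32 g
        n = 181
        trace = flat_trace(acid, n=n)
        trace.time = np.arange(n) * 10.0
        c = np.full(n, 0.009)
        sac = integrate_sac(c, trace, 3.32, (0, n))
        expected = (2e-3 / 60.0) * 1e-3 * 1800.0 / 3.32
        assert sac == pytest.approx(expected, rel=1e-12)
        assert sac == pytest.approx(1.807e-5, rel=1e-3)

    def test_no_depletion_no_capacity(self, acid):
        trace = flat_trace(acid, n=20)
        c = np.full(20, trace.feed_c_total)
        assert integrate_sac(c, trace, 3.32, (0, 20)) == 0.0

    def test_inverse_in_mass(self, acid):
        trace = flat_trace(acid, n=20)
        c = np.full(20, 0.009)
        assert integrate_sac(c, trace, 1.66, (0, 20)) == pytest.approx(
            2.0 * integrate_sac(c, trace, 3.32, (0, 20)))

    def test_empty_window_rejected(self, acid):
        trace = flat_trace(acid, n=20)
        with pytest.raises(ValueError, match="empty"):
            integrate_sac(np.zeros(20), trace, 3.32, (5, 5))


class TestChargeEfficiencyExp:
    def test_arithmetic_oracle(self):
        lam = charge_efficiency_exp(1.807e-5, 0.0, 120.0, 3.32)
        assert lam == pytest.approx(9.65, abs=0.02)

    def test_mean_charge_scaling(self):
        mono = charge_efficiency_exp(1e-5, 1.0, 100.0, 3.32)
        di = charge_efficiency_exp(1e-5, 0.0, 100.0, 3.32)
        assert di == pytest.approx(2.0 * mono, rel=1e-12)

    def test_zero_sac(self):
        assert charge_efficiency_exp(0.0, 0.5, 100.0, 3.32) == 0.0


class TestDetectCycles:
    def test_six_cycle_program(self, acid):
        program = np.tile(np.r_[np.full(10, 0.05), np.zeros(10)], 6)
        trace = flat_trace(acid, n=120, current=program)
        cycles = detect_cycles(trace)
        assert len(cycles) == 6
        (ads, des) = cycles[0]
        assert ads == (0, 10) and des == (10, 20)

    def test_all_zero_current_rejected(self, acid):
        trace = flat_trace(acid, n=20, current=np.zeros(20))
        with pytest.raises(ValueError, match="no adsorption"):
            detect_cycles(trace)


class TestSynthesisAnalysisClosure:
    def test_sac_closure_at_zero_noise(self, prediction, clean_trace, acid, cell):
        _, res = prediction
        _, mean = analyze_cycles(clean_trace, acid, cell)
        assert mean.sac_mol == pytest.approx(res.sac_mol, rel=0.01)

    def test_efficiency_closure_at_zero_noise(self, prediction, clean_trace, acid, cell):
        _, res = prediction
        _, mean = analyze_cycles(clean_trace, acid, cell)
        assert mean.lambda_exp == pytest.approx(res.lambda_corr * 100.0, rel=0.02)

    def test_full_cycle_mass_conservation(self, prediction, clean_trace, acid):
        op, _ = prediction
        c, ok = trace_to_concentrations(clean_trace, acid)
        assert ok.all()
        cycles = detect_cycles(clean_trace)
        (ads, des) = cycles[1]
        lo, hi = ads[0], des[1]
        net = np.trapezoid(op.c_feed - c[lo:hi], clean_trace.time[lo:hi])
        gross = np.trapezoid(np.abs(op.c_feed - c[lo:hi]), clean_trace.time[lo:hi])
        assert abs(net) < 0.05 * gross

    def test_noisy_closure_within_five_percent(self, prediction, acid, cell):
        op, res = prediction
        noisy = synthesize_trace(op, res, acid, cell, n_cycles=3, dt=10.0,
                                 noise=0.02, seed=42)
        _, mean = analyze_cycles(noisy, acid, cell, skip_first=0, n_average=3)
        assert mean.sac_mol == pytest.approx(res.sac_mol, rel=0.05)

    def test_lag_phase_delays_depletion_onset(self, prediction, clean_trace, acid):
        op, res = prediction
        c, _ = trace_to_concentrations(clean_trace, acid)
        (ads, _) = detect_cycles(clean_trace)[0]
        t = clean_trace.time[ads[0]:ads[1]]
        depleted = c[ads[0]:ads[1]] < 0.99 * op.c_feed
        onset = t[depleted.argmax()] - t[0]
        assert onset == pytest.approx(res.t_E, abs=60.0)

    def test_per_sample_alpha_close_to_window_mean(self, clean_trace, acid, cell):
        results, _ = analyze_cycles(clean_trace, acid, cell)
        r = results[2]
        feed_alpha = solve_solution_state(
            clean_trace.feed_c_total, clean_trace.feed_pH, acid).alpha_mono
        z_per_sample = r.alpha_mean + 2 * (1 - r.alpha_mean)
        z_feed = feed_alpha + 2 * (1 - feed_alpha)
        assert z_per_sample == pytest.approx(z_feed, rel=0.01)
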