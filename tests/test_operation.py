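"""Constant-current corrections: voltage drops, Tafel losses, lag time, cost."""

import math

import pytest

from cdisorb import (
    OperatingPoint,
    calibrate_tafel,
    corrected_efficiency,
    effective_voltage,
    energy_cost,
    lag_time,
    micropore_ph_shift,
    micropore_ratio_bound,
    pfl,
    predict_constant_current,
    redox_charge,
    solve_solution_state,
    tafel_current,
)
from cdisorb.donnan import CellSpec


def cc_point(ph=8.0, c_mM=10.0, threshold=1.3, current=0.05):
    return OperatingPoint(mode="constant_current", dphi_pot=threshold,
                          current=current, c_feed=c_mM * 1e-3, pH_feed=ph)


class TestTafelCurrent:
    def test_at_critical_voltage(self, cell):
        assert tafel_current(cell.dphi_crit, cell) == pytest.approx(cell.tafel_a)

    def test_one_tafel_slope_above(self, cell):
        assert tafel_current(cell.dphi_crit + cell.tafel_b, cell) == pytest.approx(
            cell.tafel_a * math.e)

    def test_clamped_below_onset(self, cell):
        assert tafel_current(0.5, cell) == 0.0


class TestEffectiveVoltage:
    def test_zero_current_identity(self, cell):
        op = OperatingPoint(mode="constant_voltage", dphi_pot=1.2,
                            c_feed=0.01, pH_feed=8.0)
        assert effective_voltage(op, cell, 0.15) == pytest.approx(1.2)

    def test_ohmic_drop_values(self, cell):
        # R_setup = 0.9 ohm: 45 mV at 50 mA, 90 mV at 100 mA
        assert cell.R_setup * 0.05 == pytest.approx(0.045)
        assert cell.R_setup * 0.10 == pytest.approx(0.090)

    def test_electrolyte_drop_arithmetic(self, cell):
        op = cc_point(current=0.05)
        # k_cell/kappa * I^2 = 6/0.15*0.0025 = 0.10 V on top of 45 mV ohmic
        got = effective_voltage(op, cell, 0.15)
        assert got == pytest.approx(1.3 - 0.045 - 0.10, rel=1e-12)

    def test_excessive_drops_rejected(self, cell):
        with pytest.raises(ValueError, match="exceed"):
            effective_voltage(cc_point(current=2.0), cell, 0.05)


class TestRedoxCharge:
    def test_zero_prefactor(self, cell):
        quiet = CellSpec(tafel_a=1e-300)
        assert redox_charge(cc_point(), quiet, 0.15) == pytest.approx(0.0)

    def test_clamped_regime(self, cell):
        # threshold below the redox onset: no parasitic charge at all
        op = cc_point(threshold=0.9)
        assert redox_charge(op, cell, 0.15) == 0.0

    def test_calibrated_fraction_drops_at_double_current(self, cell, acid):
        # calibrate a to 6% of total charge at 50 mA, then check that
        # traversing the same terminal-voltage window twice as fast loses
        # a smaller charge fraction to the parasitic reactions
        kappa = solve_solution_state(0.01, 8.0, acid, "activity_corrected").conductivity

        def fraction(current, spec):
            op = cc_point(current=current, threshold=1.3)
            dphi_eff = effective_voltage(op, spec, kappa)
            t_end = dphi_eff * spec.pair_mass * spec.Cg / (4 * current)
            return redox_charge(op, spec, kappa) / (current * t_end)

        cal = calibrate_tafel(cc_point(current=0.05, threshold=1.3), cell,
                              kappa, 0.06)
        assert fraction(0.05, cal) == pytest.approx(0.06, rel=1e-6)
        assert fraction(0.10, cal) < fraction(0.05, cal)


class TestCorrectedEfficiency:
    def test_no_loss(self):
        assert corrected_efficiency(0.45, 0.0, 100.0) == 0.45

    def test_total_loss(self):
        assert corrected_efficiency(0.45, 100.0, 100.0) == 0.0

    def test_six_percent_loss(self):
        assert corrected_efficiency(0.45, 6.0, 100.0) == pytest.approx(0.423)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            corrected_efficiency(0.45, 2.0, 1.0)


class TestPredictConstantCurrent:
    def test_donnan_potential_headline(self, params, acid, cell):
        res = predict_constant_current(cc_point(), params, acid, cell)
        assert res.phi_D == pytest.approx(0.97, abs=0.05)

    def test_zero_current_reduces_to_static(self, params, acid, cell):
        from cdisorb import predict_cv_grid

        op = OperatingPoint(mode="constant_voltage", dphi_pot=1.2,
                            c_feed=0.01, pH_feed=8.0)
        res = predict_constant_current(op, params, acid, cell)
        row = predict_cv_grid([8.0], [0.01], [1.2], params, acid, cell).iloc[0]
        assert res.lambda_eff == pytest.approx(row["lambda"], rel=1e-12)
        assert res.sac_eq == pytest.approx(row["sac_eq_g"], rel=1e-12)
        assert res.q_redox_fraction == 0.0

    def test_higher_current_lowers_sac(self, params, acid, cell):
        lo = predict_constant_current(cc_point(current=0.05), params, acid, cell)
        hi = predict_constant_current(cc_point(current=0.10), params, acid, cell)
        assert hi.sac_eq < lo.sac_eq

    def test_corrected_efficiency_never_exceeds_raw(self, params, acid, cell):
        res = predict_constant_current(cc_point(), params, acid, cell)
        assert res.lambda_corr <= res.lambda_eff
        assert res.sac_eq == pytest.approx(res.lambda_corr * res.sigma, rel=1e-12)
        assert res.sac_mol <= res.sac_eq


class TestLagTime:
    def test_headline_13_minutes(self, params, acid, cell):
        loading = pfl(0.01, 8.5, params, acid)
        t_e = lag_time(loading, cell, 0.05)
        assert t_e / 60.0 == pytest.approx(13.0, abs=1.0)

    def test_zero_pfl(self, cell):
        assert lag_time(0.0, cell, 0.05) == 0.0

    def test_inverse_in_current(self, cell):
        assert lag_time(0.24, cell, 0.10) == pytest.approx(
            0.5 * lag_time(0.24, cell, 0.05))


class TestMicroporePH:
    def test_shift_from_phi(self):
        assert micropore_ph_shift(0.97) == pytest.approx(0.42, abs=0.005)

    def test_zero_phi(self):
        assert micropore_ph_shift(0.0) == 0.0

    def test_ratio_bound(self):
        ratio, dph = micropore_ratio_bound(0.600, 0.020)
        assert ratio == pytest.approx(30.0)
        assert dph == pytest.approx(1.48, abs=0.01)


class TestEnergyCost:
    def test_fermenter_scale_estimate(self):
        per_h, per_mol, per_kg = energy_cost(86.2, 2.0, 0.25, 1.3, 0.1, 116.07)
        assert per_h == pytest.approx(1.2, abs=0.15)
        assert per_mol == pytest.approx(0.014, abs=0.002)

    def test_free_electricity(self):
        assert energy_cost(86.2, 2.0, 0.25, 1.3, 0.0, 116.07) == (0.0, 0.0, 0.0)

    def test_inverse_in_efficiency(self):
        _, a, _ = energy_cost(10.0, 2.0, 0.2, 1.3, 0.1, 116.07)
        _, b, _ = energy_cost(10.0, 2.0, 0.4, 1.3, 0.1, 116.07)
        assert a == pytest.approx(2.0 * b, rel=1e-12)
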