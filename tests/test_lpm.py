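"""Lumped-parameter heart model: valve formulas, elastance, calibration and
cycle identities."""

import numpy as np
import pytest
from scipy.integrate import quad

from coaflow.lpm import (CircuitParams, ElastanceCurve, NegativeResistanceError,
                         PatientInputs, build_patient_model,
                         energy_loss_coefficient, lv_pressure,
                         lv_workload, mitral_inflow, normalized_elastance,
                         extract_boundary_waveforms, simulate_cycles,
                         total_systemic_resistance, tpg_net,
                         upper_body_resistance, valve_elements)

HEALTHY = dict(SV=70, HR=75, ejection_time=0.30, A_ao=5.0, EOA_av=2.5,
               EOA_coa=4.0, A_dist=4.0, P_sys=120, P_dia=75)
COA = dict(SV=70, HR=80, ejection_time=0.31, A_ao=5.0, EOA_av=2.0,
           EOA_coa=0.8, A_dist=3.5, P_sys=145, P_dia=85)


@pytest.fixture(scope="module")
def healthy_solution():
    inputs = PatientInputs(**HEALTHY)
    circuit, curve = build_patient_model(inputs)
    return inputs, circuit, curve, simulate_cycles(inputs, circuit, curve)


class TestElastance:
    def test_peak_is_one_at_unit_time(self):
        assert normalized_elastance(1.0) == pytest.approx(1.0, abs=1e-6)
        tn = np.linspace(0, 2.5, 4001)
        en = normalized_elastance(tn)
        assert en.max() <= 1.0 + 1e-9
        assert abs(tn[np.argmax(en)] - 1.0) < 0.01

    def test_late_diastole_is_low(self):
        assert normalized_elastance(2.2) <= 0.1
        assert normalized_elastance(2.6) <= 0.1

    def test_nonnegative_and_integrable(self):
        tn = np.linspace(0, 3, 2000)
        en = normalized_elastance(tn)
        assert np.all(en >= 0)
        assert np.trapezoid(en, tn) > 0

    def test_lv_pressure_formula(self):
        curve = ElastanceCurve(E_max=2.0, T_Emax=0.35)
        # V = V_0 -> zero pressure at any time
        assert lv_pressure(curve.V_0, 0.2, curve) == pytest.approx(0.0)
        # at t = T_Emax with E_max = 2 and V - V_0 = 60 -> 120 mmHg
        assert lv_pressure(curve.V_0 + 60.0, 0.35, curve) == \
            pytest.approx(120.0, rel=1e-6)
        # linear in V at fixed t
        p1 = lv_pressure(curve.V_0 + 30.0, 0.2, curve)
        p2 = lv_pressure(curve.V_0 + 60.0, 0.2, curve)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)


class TestValveElements:
    def test_energy_loss_coefficient_values(self):
        assert energy_loss_coefficient(1.0, 2.0) == pytest.approx(2.0)
        # EOA = A/2 -> ELCo = A
        assert energy_loss_coefficient(1.5, 3.0) == pytest.approx(3.0)
        assert energy_loss_coefficient(1.0, 3.0) > 1.0

    def test_energy_loss_coefficient_domain(self):
        with pytest.raises(ValueError):
            energy_loss_coefficient(2.0, 2.0)
        with pytest.raises(ValueError):
            energy_loss_coefficient(3.0, 2.0)

    def test_tpg_quadratic_term_hand_value(self):
        # steady 300 mL/s through ELCo = 1 cm^2: 4725 Pa = 35.4 mmHg
        tpg = tpg_net(300.0, 0.0, 1.0, rho=1050.0)
        assert tpg == pytest.approx(4725.0 / 133.322, rel=1e-6)

    def test_tpg_zero_flow(self):
        assert tpg_net(0.0, 0.0, 2.0) == pytest.approx(0.0)

    def test_tpg_quadratic_scaling(self):
        assert tpg_net(600.0, 0.0, 1.5) == \
            pytest.approx(4 * tpg_net(300.0, 0.0, 1.5), rel=1e-12)

    def test_variable_resistance_reproduces_quadratic_term(self):
        R, L = valve_elements(1.0, 300.0)
        assert R * 300.0 == pytest.approx(float(tpg_net(300.0, 0.0, 1.0)),
                                          rel=1e-12)
        # R vanishes at zero flow; L independent of flow
        R0, L0 = valve_elements(1.0, 0.0)
        assert R0 == 0.0 and L0 == L


class TestMitralInflow:
    def test_integral_equals_stroke_volume(self):
        inputs = PatientInputs(**HEALTHY)
        mv = mitral_inflow(inputs)
        t = np.linspace(0.0, inputs.T, 400001)
        assert np.trapezoid(mv(t), t) == pytest.approx(inputs.SV, abs=1e-6)
        val, _ = quad(mv, 0, inputs.T, limit=400)
        assert val == pytest.approx(inputs.SV, abs=1e-5)

    def test_zero_during_systole(self):
        inputs = PatientInputs(**HEALTHY)
        mv = mitral_inflow(inputs)
        t_sys = np.linspace(0, mv.t0 * 0.999, 50)
        assert np.all(mv(t_sys) == 0.0)

    def test_e_a_peak_ratio(self):
        inputs = PatientInputs(**HEALTHY)
        mv = mitral_inflow(inputs, ea_ratio=1.6)
        t = np.linspace(0, inputs.T, 20001)
        q = mv(t)
        # E peak in the first part of diastole, A peak in the last
        split = mv.t0 + 0.6 * mv.Td
        e_peak = q[t < split].max()
        a_peak = q[t >= split].max()
        assert e_peak / a_peak == pytest.approx(1.6, rel=1e-3)


class TestSystemicResistance:
    def test_map_over_co(self):
        # MAP = 100, CO = 83.33 -> R_total = 1.2
        R_total, _ = total_systemic_resistance(120.0, 90.0, 83.3333)
        assert R_total == pytest.approx(1.2, rel=1e-4)

    def test_equal_pressures_give_map_equal_dia(self):
        R_total, _ = total_systemic_resistance(90.0, 90.0, 60.0)
        assert R_total == pytest.approx(90.0 / 60.0)

    def test_excessive_fixed_resistances_rejected(self):
        circuit = CircuitParams()
        with pytest.raises(NegativeResistanceError):
            total_systemic_resistance(30.0, 20.0, 300.0, circuit)

    def test_upper_body_fraction_algebra(self):
        R_ub = upper_body_resistance(0.05, 0.15)
        # resistive current divider: share = R_pda/(R_ub + R_pda)
        assert 0.05 / (R_ub + 0.05) == pytest.approx(0.15, rel=1e-12)


class TestCycleSolution:
    def test_converges_and_conserves_stroke_volume(self, healthy_solution):
        inputs, _, _, sol = healthy_solution
        assert sol.converged
        assert sol.stroke_integral() == pytest.approx(inputs.SV, rel=0.02)

    def test_mean_aortic_pressure_identity(self, healthy_solution):
        # no COA, no AR: mean P_ao = CO * R_total + P_CV0 within 5%
        inputs, circuit, _, sol = healthy_solution
        R_total = inputs.MAP / inputs.CO
        ident = inputs.CO * R_total + circuit.P_CV0
        assert sol.P_ao.mean() == pytest.approx(ident, rel=0.05)

    def test_upper_body_gets_15_percent(self, healthy_solution):
        _, _, _, sol = healthy_solution
        q_ub = np.trapezoid(sol.Q_ub, sol.t)
        q_tot = np.trapezoid(sol.Q_ub + sol.Q_coa, sol.t)
        assert q_ub / q_tot == pytest.approx(0.15, abs=0.01)

    def test_severity_monotonicity(self):
        # shrinking the COA orifice raises peak gradient, peak LV pressure
        # and workload
        base = PatientInputs(**COA)
        circuit, curve = build_patient_model(base)
        tighter = PatientInputs(**{**COA, "EOA_coa": COA["EOA_coa"] / 2})
        s1 = simulate_cycles(base, circuit, curve)
        s2 = simulate_cycles(tighter, circuit, curve)
        assert s2.peak_tpg_coa() > s1.peak_tpg_coa()
        assert s2.P_LV.max() > s1.P_LV.max()
        assert lv_workload(s2) > lv_workload(s1)

    def test_workload_exceeds_systemic_hydraulic_energy(self, healthy_solution):
        inputs, circuit, _, sol = healthy_solution
        w = lv_workload(sol)
        # net hydraulic energy delivered to the circuit per cycle
        e_hyd = np.trapezoid(sol.P_ao * sol.Q_av, sol.t) * 1.33322e-4
        assert w >= 0.9 * e_hyd

    def test_calibration_hits_cuff_pressures(self, healthy_solution):
        inputs, _, _, sol = healthy_solution
        pp = sol.P_ao.max() - sol.P_ao.min()
        assert pp == pytest.approx(inputs.P_sys - inputs.P_dia, abs=2.5)


class TestComplianceCalibration:
    def test_pulse_pressure_monotone_in_compliance(self, healthy_solution):
        from dataclasses import replace

        inputs, circuit, curve, sol = healthy_solution
        pp = []
        for lam in (0.6, 1.8):
            c = replace(circuit, C_ao=circuit.C_ao * lam,
                        C_SAC=circuit.C_SAC * lam)
            s = simulate_cycles(inputs, c, curve)
            pp.append(s.P_ao.max() - s.P_ao.min())
        assert pp[0] > pp[1]   # stiffer system -> wider pulse pressure

    def test_already_matched_target_returns_initial(self, healthy_solution):
        from coaflow.lpm import calibrate_compliances

        inputs, circuit, curve, sol = healthy_solution
        pp0 = float(sol.P_ao.max() - sol.P_ao.min())
        matched = PatientInputs(**{**HEALTHY,
                                   "P_sys": HEALTHY["P_dia"] + pp0})
        C_ao, C_SAC, iters = calibrate_compliances(matched, circuit, curve)
        assert iters == 0
        assert (C_ao, C_SAC) == (circuit.C_ao, circuit.C_SAC)

    def test_zero_pulse_pressure_target_raises(self, healthy_solution):
        from types import SimpleNamespace

        from coaflow.lpm import NoConvergenceError, calibrate_compliances

        _, circuit, curve, _ = healthy_solution
        degenerate = SimpleNamespace(P_sys=100.0, P_dia=100.0)
        with pytest.raises(NoConvergenceError):
            calibrate_compliances(degenerate, circuit, curve)


class TestWorkload:
    def test_rectangular_loop_hand_value(self):
        from coaflow.lpm import CycleSolution

        # rectangular P-V loop: 70 mL at 100 mmHg -> 0.933 J
        t = np.linspace(0, 1, 5)
        V = np.array([60., 130., 130., 60., 60.])
        P = np.array([0., 0., 100., 100., 0.])
        sol = CycleSolution(t=t, P_LV=P, P_ao=P, P_desc=P, Q_av=P, Q_coa=P,
                            Q_ub=P, Q_ar=P, Q_mv=P, V_LV=V, converged=True,
                            n_cycles_run=1)
        assert lv_workload(sol) == pytest.approx(0.933, abs=2e-3)
        # zero-area loop
        sol.P_LV = np.zeros_like(P)
        assert lv_workload(sol) == 0.0


class TestBoundaryWaveforms:
    def test_extraction_periodic_and_conservative(self, healthy_solution):
        inputs, _, _, sol = healthy_solution
        waves = extract_boundary_waveforms(sol)
        assert waves.T == pytest.approx(inputs.T, rel=1e-9)
        sv = np.trapezoid(waves.Q_inlet, waves.t)
        assert sv == pytest.approx(inputs.SV, rel=0.02)
        # refining the grid barely changes the integral
        fine = extract_boundary_waveforms(sol, n_samples=400)
        assert np.trapezoid(fine.Q_inlet, fine.t) == pytest.approx(sv, rel=1e-3)

    def test_inputs_validation(self):
        with pytest.raises(ValueError):
            PatientInputs(**{**HEALTHY, "EOA_av": 6.0})
        with pytest.raises(ValueError):
            PatientInputs(**{**HEALTHY, "P_dia": 130.0})
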