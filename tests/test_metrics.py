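"""WSS/TAWSS/TKE/Reynolds/pressure-drop formulas."""

import numpy as np
import pytest

from coaflow.metrics import (IncompleteCycleError, MismatchedPhaseGridError,
                             ZeroBaselineError, format_change, percent_change,
                             pressure_drop, reynolds_number, tawss, tke,
                             velocity_gradient_offwall, wss_traction)


class TestTraction:
    def test_couette_hand_value(self):
        # du_x/dy = 100 1/s, mu = 0.0035 -> |tau| = 0.35 Pa = 3.5 dyn/cm^2
        grad = np.zeros((3, 3))
        grad[1, 0] = 100.0        # d u_x / d y
        n = np.array([0.0, 1.0, 0.0])
        tau, mag = wss_traction(grad, n, mu=0.0035)
        assert mag == pytest.approx(0.35, rel=1e-12)
        assert abs(tau @ n) < 1e-12

    def test_pure_pressure_field_gives_zero(self):
        tau, mag = wss_traction(np.zeros((3, 3)), np.array([0, 0, 1.0]),
                                mu=0.0035)
        assert mag == 0.0

    def test_traction_is_tangential_random(self):
        rng = np.random.default_rng(9)
        grad = rng.normal(size=(40, 3, 3))
        n = rng.normal(size=(40, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        tau, mag = wss_traction(grad, n, mu=0.0035)
        dots = np.einsum("ni,ni->n", tau, n)
        assert np.abs(dots).max() < 1e-10 * max(1.0, mag.max())


class TestVelocityGradient:
    def test_rigid_translation_zero_gradient(self):
        from coaflow.units import LatticeSpec
        from coaflow.geometry import make_straight_tube

        dx = 1e-3
        spec = LatticeSpec(nx=1, ny=1, nz=1, dx=dx, dt=1e-3,
                           rho_phys=1050.0, nu_phys=5e-5)
        dom = make_straight_tube(8 * dx, 12 * dx, spec)
        u = np.ones(dom.flags.shape + (3,)) * np.array([0.1, -0.2, 0.3])
        _, grad, valid = velocity_gradient_offwall(u, dom, offset=2)
        assert valid.any()
        assert np.abs(grad[valid]).max() < 1e-12

    def test_linear_shear_recovered_exactly(self):
        from coaflow.units import LatticeSpec
        from coaflow.geometry import make_straight_tube

        dx = 1e-3
        spec = LatticeSpec(nx=1, ny=1, nz=1, dx=dx, dt=1e-3,
                           rho_phys=1050.0, nu_phys=5e-5)
        dom = make_straight_tube(8 * dx, 12 * dx, spec)
        gamma = 50.0
        jj = np.arange(dom.flags.shape[1]) * dx
        u = np.zeros(dom.flags.shape + (3,))
        u[:, :, :, 0] = gamma * jj[None, :, None]   # u_x = gamma * y
        _, grad, valid = velocity_gradient_offwall(u, dom, offset=2)
        assert np.allclose(grad[valid, 1, 0], gamma, rtol=1e-10)

    def test_offset_must_be_positive(self):
        with pytest.raises(ValueError):
            velocity_gradient_offwall(None, None, offset=0)


class TestTAWSS:
    def test_constant_series(self):
        t = np.linspace(0, 2.0, 401)
        assert tawss(np.full_like(t, 3.3), t, 1.0) == pytest.approx(3.3)

    def test_rectified_sine_closed_form(self):
        # mean of a |sin| wave of amplitude a over a period is 2a/pi
        a = 1.7
        T = 0.8
        t = np.linspace(0, 2 * T, 4001)
        series = a * np.abs(np.sin(2 * np.pi * t / T))
        got = tawss(series, t, T)
        assert got == pytest.approx(2 * a / np.pi, rel=1e-4)
        # doubling the sampling rate barely moves the estimate
        t2 = np.linspace(0, 2 * T, 8001)
        got2 = tawss(a * np.abs(np.sin(2 * np.pi * t2 / T)), t2, T)
        assert abs(got2 - got) / got < 1e-3

    def test_incomplete_cycle_rejected(self):
        t = np.linspace(0, 0.5, 100)
        with pytest.raises(IncompleteCycleError):
            tawss(np.ones_like(t), t, 1.0)


class TestTKE:
    def test_perfectly_periodic_flow_has_zero_tke(self):
        rng = np.random.default_rng(0)
        one_cycle = rng.normal(size=(16, 5, 5, 3))
        snaps = np.stack([one_cycle] * 4)
        field, peak = tke(snaps, rho=1050.0)
        assert peak == pytest.approx(0.0, abs=1e-20)

    def test_single_harmonic_fluctuation(self):
        # u' = a sin(fast phase) on one component -> TKE = rho a^2 / 4
        rho, a = 1050.0, 0.3
        phases = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        snaps = np.zeros((2, 64, 1, 3))
        snaps[0, :, 0, 0] = a * np.sin(phases)
        snaps[1, :, 0, 0] = -a * np.sin(phases)
        field, peak = tke(snaps, rho)
        assert peak == pytest.approx(rho * a**2 / 4, rel=1e-12)

    def test_invariant_to_cycle_periodic_mean_flow(self):
        rng = np.random.default_rng(1)
        fluct = rng.normal(size=(3, 8, 4, 3))
        base = rng.normal(size=(1, 8, 4, 3))
        f1, p1 = tke(fluct, 1050.0)
        f2, p2 = tke(fluct + base, 1050.0)
        assert np.allclose(f1, f2, rtol=1e-10)

    def test_needs_two_cycles(self):
        with pytest.raises(MismatchedPhaseGridError):
            tke(np.zeros((1, 8, 4, 3)), 1050.0)


class TestReynoldsAndPressure:
    def test_reynolds_hand_value(self):
        # 1 m/s, 2 cm, blood kinematic viscosity -> Re = 6000
        assert reynolds_number(1.0, 0.02, 0.0035 / 1050.0) == \
            pytest.approx(6000.0, rel=1e-3)
        assert reynolds_number(0.0, 0.02, 3.333e-6) == 0.0
        assert reynolds_number(1.0, 0.04, 3.333e-6) == \
            pytest.approx(2 * reynolds_number(1.0, 0.02, 3.333e-6))

    def test_uniform_pressure_no_drop(self):
        p = np.full((6, 6, 10), 1234.5)
        mask = np.ones((6, 6, 10), bool)
        assert pressure_drop(p, mask, 1, 8) == pytest.approx(0.0, abs=1e-12)

    def test_linear_pressure_field_drop_in_mmhg(self):
        p = np.zeros((4, 4, 11))
        p[:, :, :] = -133.322 * np.arange(11)[None, None, :]
        mask = np.ones((4, 4, 11), bool)
        assert pressure_drop(p, mask, 0, 10) == pytest.approx(10.0, rel=1e-9)


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,pct,text", [
        (1150.0, 820.0, -28.695652173913043, "29% decrease"),
        (31.0, 49.0, 58.06451612903226, "58% increase"),
        (5.0, 5.0, 0.0, "0% change"),
    ])
    def test_values_and_report_text(self, pre, post, pct, text):
        got = percent_change(pre, post)
        assert got == pytest.approx(pct, rel=1e-12)
        assert format_change(got) == text

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroBaselineError):
            percent_change(0.0, 1.0)
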