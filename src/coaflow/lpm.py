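"""Patient-specific lumped-parameter model of the left heart and circulation.

The left ventricle is a time-varying elastance E(t) = P_LV/(V - V0) whose
normalized shape E_N(t_N) is load-invariant; the aortic valve, an optional
regurgitant path and the coarctation are nonlinear valve elements whose net
pressure gradient follows the energy-loss-coefficient formulation

    TPG = 2 pi rho / sqrt(ELCo) * dQ/dt + rho / (2 ELCo^2) * Q^2,
    ELCo = EOA * A / (A - EOA),

i.e. an inductance L = 2 pi rho / sqrt(ELCo) in series with a flow-dependent
resistance R(Q) = rho/(2 ELCo^2) |Q|.  The systemic circulation is a
two-compartment Windkessel: aortic-root capacitor C_ao, a parallel pair of
branches (upper body R_ub; proximal descending aorta R_pda plus the
coarctation element), systemic arteries R_SA, systemic compartment C_SAC,
veins R_SV and a constant central venous pressure.

All circuit quantities are carried in clinical units (mmHg, mL, s); the
valve formulas are converted from SI internally.  The state system is
integrated with a fixed-step RK4 at 0.1 ms with one-way valves enforced by
per-step gating and clamping, cycle after cycle until the aortic pressure
waveform is periodic to 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .units import MMHG_PA

# unit conversion factors: SI valve elements -> clinical circuit units
_R_SI2CLIN = 1e-6 / MMHG_PA        # Pa s/m^3 -> mmHg s/mL
_KQ_SI2CLIN = 1e-12 / MMHG_PA      # Pa/(m^3/s)^2 -> mmHg/(mL/s)^2
_L_SI2CLIN = 1e-6 / MMHG_PA        # Pa s^2/m^3 -> mmHg s^2/mL
MMHG_ML_TO_J = MMHG_PA * 1e-6      # mmHg*mL -> J


class NegativeResistanceError(ValueError):
    pass


class NoConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# inputs and parameters


@dataclass(frozen=True)
class PatientInputs:
    """Echo + cuff measurements that parameterize the model.

    Areas in cm^2, pressures in mmHg, volumes in mL, times in s.
    """

    SV: float                  # stroke volume (mL)
    HR: float                  # heart rate (bpm)
    ejection_time: float       # s
    A_ao: float                # ascending aorta area (cm^2)
    EOA_av: float              # aortic valve effective orifice area (cm^2)
    EOA_coa: float             # coarctation effective orifice area (cm^2)
    A_dist: float              # aortic area downstream of the COA (cm^2)
    P_sys: float               # brachial systolic pressure (mmHg)
    P_dia: float               # brachial diastolic pressure (mmHg)
    REOA: float = 0.0          # regurgitant effective orifice area (cm^2)
    A_LVOT: float = 4.0        # LVOT area (cm^2)

    def __post_init__(self):
        if not 0 < self.EOA_av < self.A_ao:
            raise ValueError("need 0 < EOA_av < A_ao")
        if not 0 < self.EOA_coa <= self.A_dist:
            raise ValueError("need 0 < EOA_coa <= A_dist")
        if not 0 <= self.REOA < self.A_LVOT:
            raise ValueError("need 0 <= REOA < A_LVOT")
        if not self.P_sys > self.P_dia > 0:
            raise ValueError("need P_sys > P_dia > 0")

    @property
    def T(self) -> float:
        """Cycle duration 60/HR (s)."""
        return 60.0 / self.HR

    @property
    def CO(self) -> float:
        """Cardiac output SV*HR/60 (mL/s)."""
        return self.SV * self.HR / 60.0

    @property
    def MAP(self) -> float:
        """Mean arterial pressure P_dia + pulse pressure / 3 (mmHg)."""
        return self.P_dia + (self.P_sys - self.P_dia) / 3.0


@dataclass
class CircuitParams:
    """Systemic circuit constants (clinical units); defaults are the model's
    standard parameter set."""

    R_ao: float = 0.05         # aortic resistance (mmHg s/mL)
    R_SV: float = 0.05         # systemic vein resistance
    R_pda: float = 0.05        # proximal descending aorta resistance
    R_SA: float = 0.8          # systemic arteries (adjusted to R_total)
    R_ub: float = 0.2833       # upper body (15% of flow in healthy case)
    C_ao: float = 0.5          # aortic compliance (mL/mmHg)
    C_SAC: float = 2.0         # systemic compliance (mL/mmHg)
    P_CV0: float = 4.0         # central venous pressure (mmHg)
    rho: float = 1050.0        # blood density (kg/m^3)
    upper_body_fraction: float = 0.15

    def __post_init__(self):
        for name in ("R_ao", "R_SV", "R_pda", "R_SA", "R_ub", "C_ao", "C_SAC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def upper_body_resistance(R_pda: float, fraction: float = 0.15) -> float:
    """R_ub so the upper-body branch carries ``fraction`` of total flow in
    the healthy case (purely resistive split of the two parallel branches)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction in (0,1)")
    return R_pda * (1.0 - fraction) / fraction


# ---------------------------------------------------------------------------
# valve elements


def energy_loss_coefficient(EOA: float, A: float) -> float:
    """ELCo = EOA*A/(A - EOA); same units as the areas; > EOA always."""
    if not 0 < EOA < A:
        raise ValueError("need 0 < EOA < A")
    return EOA * A / (A - EOA)


def tpg_net(Q, dQdt, ELCo_cm2: float, rho: float = 1050.0):
    """Instantaneous net pressure gradient across a valve element, in mmHg.

    ``Q`` in mL/s, ``dQdt`` in mL/s^2, ``ELCo_cm2`` in cm^2.
    """
    if ELCo_cm2 <= 0:
        raise ValueError("ELCo must be positive")
    elco = ELCo_cm2 * 1e-4                       # m^2
    L = 2.0 * np.pi * rho / np.sqrt(elco)        # SI
    kq = rho / (2.0 * elco**2)
    Q = np.asarray(Q, dtype=np.float64)
    dQdt = np.asarray(dQdt, dtype=np.float64)
    tpg_pa = L * dQdt * 1e-6 + kq * (Q * 1e-6) ** 2
    return tpg_pa / MMHG_PA


def valve_elements(ELCo_cm2: float, Q, rho: float = 1050.0):
    """(variable resistance, inductance) of a valve element, clinical units.

    R = rho/(2 ELCo^2) |Q| so that R*Q reproduces the quadratic term of the
    net gradient with the correct sign; L = 2 pi rho / sqrt(ELCo).
    """
    if ELCo_cm2 <= 0:
        raise ValueError("ELCo must be positive")
    elco = ELCo_cm2 * 1e-4
    kq_clin = rho / (2.0 * elco**2) * _KQ_SI2CLIN
    L_clin = 2.0 * np.pi * rho / np.sqrt(elco) * _L_SI2CLIN
    R = kq_clin * np.abs(np.asarray(Q, dtype=np.float64))
    return R, L_clin


# ---------------------------------------------------------------------------
# elastance

# double-Hill shape constants: activation Hill (a1, n1), relaxation Hill
# (a2, n2), diastolic baseline fraction
_EL_A1, _EL_N1 = 0.55, 1.9
_EL_A2, _EL_N2 = 1.2, 21.9
_EL_BASE = 0.03


def _hill_raw(s):
    s = np.asarray(s, dtype=np.float64)
    up = (s / _EL_A1) ** _EL_N1
    return up / (1.0 + up) / (1.0 + (s / _EL_A2) ** _EL_N2)


def _hill_norm_consts():
    s = np.linspace(1e-6, 3.0, 20001)
    h = _hill_raw(s)
    i = int(np.argmax(h))
    return s[i], 1.0 / h[i]


_EL_SPEAK, _EL_AMP = _hill_norm_consts()


def normalized_elastance(t_N):
    """Normalized elastance shape E_N(t_N): smooth systolic rise and fall
    with its maximum of exactly 1 at t_N = 1, decaying to a small diastolic
    baseline.  ``t_N = t / T_Emax`` >= 0."""
    t_N = np.asarray(t_N, dtype=np.float64)
    h = _hill_raw(t_N * _EL_SPEAK) * _EL_AMP
    out = _EL_BASE + (1.0 - _EL_BASE) * h
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ElastanceCurve:
    """Time-varying elastance: P_LV = E_max E_N(t/T_Emax) (V - V_0)."""

    E_max: float               # mmHg/mL
    T_Emax: float              # s
    V_0: float = 10.0          # mL

    def en(self, t_N):
        return normalized_elastance(t_N)

    def elastance(self, t):
        return self.E_max * self.en(np.asarray(t) / self.T_Emax)


def lv_pressure(V, t, curve: ElastanceCurve):
    """P_LV = E_max E_N(t/T_Emax) (V - V_0); <= 0 when V <= V_0."""
    return curve.elastance(t) * (np.asarray(V, dtype=np.float64) - curve.V_0)


# ---------------------------------------------------------------------------
# mitral inflow

_MV_E_END = 0.55     # E-wave occupies [0, 0.55] of diastole
_MV_A_START = 0.65   # A-wave occupies [0.65, 1.0]


@dataclass(frozen=True)
class MitralWaveform:
    """Two-lobed (E-wave, A-wave) diastolic filling waveform.

    Supported on the diastolic interval [t0, t0 + Td] of the cycle; the
    integral over a cycle equals the stroke volume exactly (closed-form
    normalization of the sin^2 lobes); E-peak/A-peak = ``ea_ratio``.
    """

    SV: float
    T: float
    t0: float        # filling start (s into the cycle)
    Td: float        # filling duration (s)
    ea_ratio: float = 1.6

    @property
    def scale(self) -> float:
        # integral of sin^2 lobe of width D and unit amplitude is D/2
        raw = _MV_E_END * self.Td / 2.0 + \
            (1.0 - _MV_A_START) * self.Td / (2.0 * self.ea_ratio)
        return self.SV / raw

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64) % self.T
        s = (t - self.t0) / self.Td
        e_lobe = np.where((s >= 0) & (s <= _MV_E_END),
                          np.sin(np.pi * s / _MV_E_END) ** 2, 0.0)
        a_s = (s - _MV_A_START) / (1.0 - _MV_A_START)
        a_lobe = np.where((a_s >= 0) & (a_s <= 1.0),
                          np.sin(np.pi * a_s) ** 2 / self.ea_ratio, 0.0)
        out = self.scale * (e_lobe + a_lobe)
        return float(out) if out.ndim == 0 else out


def mitral_inflow(inputs: PatientInputs, ea_ratio: float = 1.6,
                  ivrt: float = 0.08) -> MitralWaveform:
    """Build the filling waveform from cycle timing.

    Filling starts after systole (ejection plus isovolumic phases) and lasts
    until end of cycle.
    """
    t0 = default_t_emax(inputs) + ivrt
    Td = inputs.T - t0
    if Td <= 0.05:
        raise ValueError("cycle too short for a diastolic filling phase")
    return MitralWaveform(SV=inputs.SV, T=inputs.T, t0=t0, Td=Td,
                          ea_ratio=ea_ratio)


def default_t_emax(inputs: PatientInputs, ivc: float = 0.05) -> float:
    """T_Emax = ejection time + isovolumic-contraction allowance."""
    return inputs.ejection_time + ivc


# ---------------------------------------------------------------------------
# systemic resistance calibration


def total_systemic_resistance(P_sys: float, P_dia: float, CO: float,
                              circuit: Optional[CircuitParams] = None,
                              kq_coa: float = 0.0):
    """R_total = MAP/CO and the R_SA that realizes it.

    The circuit's equivalent resistance R_ao + (R_ub || (R_pda + R_coa))
    + R_SA + R_SV is matched to R_total holding the constants fixed; the
    flow-dependent coarctation resistance is linearized at the mean
    trans-coarctation flow by a short fixed-point iteration.
    """
    if CO <= 0:
        raise ValueError("CO must be positive")
    MAP = P_dia + (P_sys - P_dia) / 3.0
    R_total = MAP / CO
    if circuit is None:
        return R_total, None
    R_coa_lin = 0.0
    for _ in range(20):
        branch = circuit.R_pda + R_coa_lin
        R_par = circuit.R_ub * branch / (circuit.R_ub + branch)
        frac_coa = circuit.R_ub / (circuit.R_ub + branch)
        R_coa_new = kq_coa * CO * frac_coa
        if abs(R_coa_new - R_coa_lin) < 1e-12:
            break
        R_coa_lin = R_coa_new
    R_SA = R_total - circuit.R_ao - circuit.R_SV - R_par
    if R_SA <= 0:
        raise NegativeResistanceError(
            f"fixed resistances exceed R_total = {R_total:.3g} mmHg s/mL")
    return R_total, R_SA


# ---------------------------------------------------------------------------
# cycle integration (numba kernel)

# parameter vector slots for the compiled integrator
_NP = 30


def _pack_params(inputs: PatientInputs, circuit: CircuitParams,
                 curve: ElastanceCurve, mv: MitralWaveform) -> np.ndarray:
    p = np.zeros(_NP)
    p[0] = inputs.T
    p[1] = curve.T_Emax
    p[2] = curve.E_max
    p[3] = curve.V_0
    # elastance shape
    p[4] = _EL_SPEAK
    p[5] = _EL_AMP
    # mitral
    p[6] = mv.t0
    p[7] = mv.Td
    p[8] = mv.ea_ratio
    p[9] = mv.scale
    # circuit
    p[10] = circuit.R_ao
    p[11] = circuit.C_ao
    p[12] = circuit.R_SV
    p[13] = circuit.C_SAC
    p[14] = circuit.R_SA
    p[15] = circuit.R_pda
    p[16] = circuit.R_ub
    p[17] = circuit.P_CV0
    rho = circuit.rho
    # aortic valve element
    elco_av = energy_loss_coefficient(inputs.EOA_av, inputs.A_ao) * 1e-4
    p[18] = rho / (2.0 * elco_av**2) * _KQ_SI2CLIN
    p[19] = 2.0 * np.pi * rho / np.sqrt(elco_av) * _L_SI2CLIN
    # regurgitant element
    if inputs.REOA > 0:
        elco_ar = energy_loss_coefficient(inputs.REOA, inputs.A_LVOT) * 1e-4
        p[20] = rho / (2.0 * elco_ar**2) * _KQ_SI2CLIN
        p[21] = 2.0 * np.pi * rho / np.sqrt(elco_ar) * _L_SI2CLIN
        p[22] = 1.0
    # coarctation element (degenerates to plain resistor as EOA -> A_dist)
    if inputs.EOA_coa < 0.98 * inputs.A_dist:
        elco_coa = energy_loss_coefficient(
            inputs.EOA_coa, inputs.A_dist) * 1e-4
        p[23] = rho / (2.0 * elco_coa**2) * _KQ_SI2CLIN
        p[24] = 2.0 * np.pi * rho / np.sqrt(elco_coa) * _L_SI2CLIN
        p[25] = 1.0
    return p


@njit(cache=True)
def _en_nb(tn, speak, amp):
    s = tn * speak
    up = (s / _EL_A1) ** _EL_N1
    h = up / (1.0 + up) / (1.0 + (s / _EL_A2) ** _EL_N2)
    return _EL_BASE + (1.0 - _EL_BASE) * amp * h


@njit(cache=True)
def _qmv_nb(t, T, t0, Td, ea, scale):
    tc = t % T
    s = (tc - t0) / Td
    out = 0.0
    if 0.0 <= s <= _MV_E_END:
        v = np.sin(np.pi * s / _MV_E_END)
        out = v * v
    else:
        sa = (s - _MV_A_START) / (1.0 - _MV_A_START)
        if 0.0 <= sa <= 1.0:
            v = np.sin(np.pi * sa)
            out = v * v / ea
    return scale * out


@njit(cache=True)
def _rhs(t, y, p, open_av, open_ar):
    T = p[0]
    tn = (t % T) / p[1]
    V, P1, P3, Qav, Qcoa, Qar = y[0], y[1], y[2], y[3], y[4], y[5]
    EN = _en_nb(tn, p[4], p[5])
    PLV = p[2] * EN * (V - p[3])
    Qmv = _qmv_nb(t, T, p[6], p[7], p[8], p[9])

    R_ao, C_ao = p[10], p[11]
    R_SV, C_SAC = p[12], p[13]
    R_SA, R_pda, R_ub, P_CV0 = p[14], p[15], p[16], p[17]
    has_coa = p[25] > 0.5

    dQavDt = 0.0
    if open_av:
        dQavDt = (PLV - P1 - p[18] * Qav * abs(Qav)) / p[19]
    dQarDt = 0.0
    if open_ar:
        dQarDt = (P1 - PLV - p[20] * Qar * abs(Qar)) / p[21]

    if has_coa:
        Qub = (P1 - P3 - (R_ao + R_SA) * Qcoa) / (R_ub + R_ao + R_SA)
        Qtot = Qub + Qcoa
        Psplit = P1 - R_ao * Qtot
        P2 = P3 + R_SA * Qtot
        dQcoaDt = (Psplit - P2 - R_pda * Qcoa
                   - p[23] * Qcoa * abs(Qcoa)) / p[24]
        Qcoa_used = Qcoa
    else:
        Rpar = R_ub * R_pda / (R_ub + R_pda)
        Qtot = (P1 - P3) / (R_ao + Rpar + R_SA)
        Qcoa_used = Qtot * R_ub / (R_ub + R_pda)
        Qub = Qtot - Qcoa_used
        P2 = P3 + R_SA * Qtot
        dQcoaDt = 0.0

    dV = Qmv + Qar - Qav
    dP1 = (Qav - Qtot - Qar) / C_ao
    dP3 = (Qtot - (P3 - P_CV0) / R_SV) / C_SAC

    dy = np.empty(6)
    dy[0] = dV
    dy[1] = dP1
    dy[2] = dP3
    dy[3] = dQavDt
    dy[4] = dQcoaDt
    dy[5] = dQarDt
    return dy


@njit(cache=True)
def _run_cycle(y0, t_start, p, dt, nsteps):
    """RK4 over one cycle with per-step valve gating and clamping.

    Returns state history (nsteps+1, 6) and derived series
    (PLV, Qmv, Qub, P2, Qcoa_used) at each saved point.
    """
    Y = np.empty((nsteps + 1, 6))
    D = np.empty((nsteps + 1, 5))
    y = y0.copy()
    T = p[0]
    has_coa = p[25] > 0.5
    for n in range(nsteps + 1):
        t = t_start + n * dt
        tn = (t % T) / p[1]
        EN = _en_nb(tn, p[4], p[5])
        PLV = p[2] * EN * (y[0] - p[3])
        # derived branch quantities for output
        R_ao, R_SA, R_pda, R_ub = p[10], p[14], p[15], p[16]
        if has_coa:
            Qub = (y[1] - y[2] - (R_ao + R_SA) * y[4]) / (R_ub + R_ao + R_SA)
            Qtot = Qub + y[4]
            P2 = y[2] + R_SA * Qtot
            Qcoa_used = y[4]
        else:
            Rpar = R_ub * R_pda / (R_ub + R_pda)
            Qtot = (y[1] - y[2]) / (R_ao + Rpar + R_SA)
            Qcoa_used = Qtot * R_ub / (R_ub + R_pda)
            Qub = Qtot - Qcoa_used
            P2 = y[2] + R_SA * Qtot
        Y[n] = y
        D[n, 0] = PLV
        D[n, 1] = _qmv_nb(t, T, p[6], p[7], p[8], p[9])
        D[n, 2] = Qub
        D[n, 3] = P2
        D[n, 4] = Qcoa_used
        if n == nsteps:
            break

        open_av = (y[3] > 1e-9) or (PLV > y[1])
        open_ar = (p[22] > 0.5) and (y[1] > PLV) and not open_av

        k1 = _rhs(t, y, p, open_av, open_ar)
        k2 = _rhs(t + 0.5 * dt, y + 0.5 * dt * k1, p, open_av, open_ar)
        k3 = _rhs(t + 0.5 * dt, y + 0.5 * dt * k2, p, open_av, open_ar)
        k4 = _rhs(t + dt, y + dt * k3, p, open_av, open_ar)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if y[3] < 0.0 or not open_av:
            y[3] = 0.0
        if y[5] < 0.0 or not open_ar:
            y[5] = 0.0
    return Y, D


# ---------------------------------------------------------------------------
# cycle solution container


@dataclass
class CycleSolution:
    """One converged cardiac cycle of the circuit."""

    t: np.ndarray              # s, from 0 (cycle onset)
    P_LV: np.ndarray           # mmHg
    P_ao: np.ndarray           # proximal aorta (on C_ao)
    P_desc: np.ndarray         # descending aorta distal to the COA
    Q_av: np.ndarray           # mL/s
    Q_coa: np.ndarray
    Q_ub: np.ndarray
    Q_ar: np.ndarray
    Q_mv: np.ndarray
    V_LV: np.ndarray           # mL
    converged: bool
    n_cycles_run: int
    inputs: Optional[PatientInputs] = None
    circuit: Optional[CircuitParams] = None
    curve: Optional[ElastanceCurve] = None

    @property
    def T(self) -> float:
        return float(self.t[-1] - self.t[0])

    def stroke_integral(self) -> float:
        """Forward valve volume per cycle, integral of Q_av dt (mL)."""
        return float(np.trapezoid(self.Q_av, self.t))

    def peak_tpg_coa(self) -> float:
        """Peak instantaneous trans-coarctation pressure gradient (mmHg)."""
        if self.inputs is None or self.circuit is None:
            raise ValueError("solution lacks its inputs")
        dt = self.t[1] - self.t[0]
        dQ = np.gradient(self.Q_coa, dt)
        if self.inputs.EOA_coa >= 0.98 * self.inputs.A_dist:
            return 0.0
        elco = energy_loss_coefficient(self.inputs.EOA_coa,
                                       self.inputs.A_dist)
        return float(np.max(tpg_net(self.Q_coa, dQ, elco, self.circuit.rho)))


def simulate_cycles(inputs: PatientInputs, circuit: CircuitParams,
                    curve: ElastanceCurve, n_cycles: int = 20,
                    dt: float = 1e-4, tol: float = 0.01,
                    mv: Optional[MitralWaveform] = None) -> CycleSolution:
    """Integrate the circuit from rest until the cycle is periodic.

    Starts at the onset of isovolumic contraction with zero stored pressures
    and flows; runs whole cycles until the aortic-pressure waveform changes
    by less than ``tol`` (relative max difference) between cycles, or
    ``n_cycles`` is reached.  Returns the last cycle.
    """
    if n_cycles < 3:
        raise ValueError("n_cycles >= 3 required")
    mv = mv or mitral_inflow(inputs)
    p = _pack_params(inputs, circuit, curve, mv)
    T = inputs.T
    nsteps = int(round(T / dt))
    y = np.zeros(6)
    y[0] = curve.V_0 + inputs.SV / 0.55   # end-diastolic volume estimate
    prev_P1 = None
    converged = False
    ncyc = 0
    for c in range(n_cycles):
        Y, D = _run_cycle(y, c * T, p, dt, nsteps)
        y = Y[-1].copy()
        ncyc = c + 1
        P1 = Y[:, 1]
        if prev_P1 is not None:
            scale = np.abs(P1).max()
            if scale > 0 and np.abs(P1 - prev_P1).max() / scale < tol:
                converged = True
                break
        prev_P1 = P1.copy()
    if not np.all(np.isfinite(Y)):
        raise NoConvergenceError("state blow-up in cycle integration")
    t = np.arange(nsteps + 1) * dt
    return CycleSolution(
        t=t, P_LV=D[:, 0], P_ao=Y[:, 1], P_desc=D[:, 3],
        Q_av=Y[:, 3], Q_coa=D[:, 4], Q_ub=D[:, 2], Q_ar=Y[:, 5],
        Q_mv=D[:, 1], V_LV=Y[:, 0], converged=converged, n_cycles_run=ncyc,
        inputs=inputs, circuit=circuit, curve=curve)


# ---------------------------------------------------------------------------
# calibration


def calibrate_emax(inputs: PatientInputs, circuit: CircuitParams,
                   V_0: float = 10.0, tol: float = 1.5,
                   max_iter: int = 30) -> ElastanceCurve:
    """Secant search for E_max matching the systolic pressure target.

    The target for peak LV pressure is cuff P_sys plus the quadratic
    transvalvular gradient at the peak ejection flow (sine-lobe estimate
    Q_peak = pi/2 * SV / ejection_time); without stenosis the two pressures
    coincide, with a narrow valve the LV must generate the extra gradient.
    """
    T_Emax = default_t_emax(inputs)
    q_peak = np.pi / 2.0 * inputs.SV / inputs.ejection_time
    elco_av = energy_loss_coefficient(inputs.EOA_av, inputs.A_ao)
    target = inputs.P_sys + float(tpg_net(q_peak, 0.0, elco_av, circuit.rho))

    def peak_plv(emax):
        curve = ElastanceCurve(E_max=emax, T_Emax=T_Emax, V_0=V_0)
        sol = simulate_cycles(inputs, circuit, curve)
        return float(sol.P_LV.max())

    e0, e1 = 1.5, 2.5
    f0 = peak_plv(e0) - target
    f1 = peak_plv(e1) - target
    for _ in range(max_iter):
        if abs(f1) < tol:
            break
        if f1 == f0:
            break
        e2 = e1 - f1 * (e1 - e0) / (f1 - f0)
        e2 = min(max(e2, 0.3), 10.0)
        e0, f0, e1 = e1, f1, e2
        f1 = peak_plv(e1) - target
    return ElastanceCurve(E_max=e1, T_Emax=T_Emax, V_0=V_0)


def calibrate_compliances(inputs: PatientInputs, circuit: CircuitParams,
                          curve: ElastanceCurve, tol: float = 2.0,
                          max_iter: int = 50):
    """Scale (C_ao, C_SAC) jointly until the simulated aortic pulse pressure
    matches the cuff pulse pressure within ``tol`` mmHg.

    Bounded secant on log(scale) from the standard initial values; pulse
    pressure decreases monotonically with total compliance.
    """
    target = inputs.P_sys - inputs.P_dia
    if target <= 0:
        raise NoConvergenceError("target pulse pressure must be positive")

    def pp(log_lam):
        lam = np.exp(log_lam)
        c = replace(circuit, C_ao=circuit.C_ao * lam,
                    C_SAC=circuit.C_SAC * lam)
        sol = simulate_cycles(inputs, c, curve)
        return float(sol.P_ao.max() - sol.P_ao.min())

    x0, x1 = 0.0, 0.4
    f0 = pp(x0) - target
    if abs(f0) < tol:
        return circuit.C_ao, circuit.C_SAC, 0
    f1 = pp(x1) - target
    best = (abs(f0), x0)
    for it in range(max_iter):
        if abs(f1) < tol:
            lam = np.exp(x1)
            return circuit.C_ao * lam, circuit.C_SAC * lam, it + 1
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        x2 = min(max(x2, -3.0), 3.0)
        x0, f0, x1 = x1, f1, x2
        f1 = pp(x1) - target
        if abs(f1) < best[0]:
            best = (abs(f1), x1)
    raise NoConvergenceError(
        f"pulse-pressure fit stalled; best residual {best[0]:.2f} mmHg")


def build_patient_model(inputs: PatientInputs,
                        circuit: Optional[CircuitParams] = None,
                        V_0: float = 10.0, outer_iter: int = 3):
    """Full non-invasive calibration: R_SA from MAP/CO, then alternate
    E_max (systolic pressure) and compliance (pulse pressure) fits.

    Returns ``(circuit, curve)`` ready for :func:`simulate_cycles`.
    """
    circuit = circuit or CircuitParams()
    circuit = replace(circuit, R_ub=upper_body_resistance(
        circuit.R_pda, circuit.upper_body_fraction))
    kq_coa = 0.0
    if inputs.EOA_coa < 0.98 * inputs.A_dist:
        elco = energy_loss_coefficient(inputs.EOA_coa, inputs.A_dist) * 1e-4
        kq_coa = circuit.rho / (2.0 * elco**2) * _KQ_SI2CLIN
    _, R_SA = total_systemic_resistance(
        inputs.P_sys, inputs.P_dia, inputs.CO, circuit, kq_coa)
    circuit = replace(circuit, R_SA=R_SA)
    curve = ElastanceCurve(E_max=2.0, T_Emax=default_t_emax(inputs), V_0=V_0)
    for _ in range(outer_iter):
        curve = calibrate_emax(inputs, circuit, V_0=V_0)
        try:
            C_ao, C_SAC, _ = calibrate_compliances(inputs, circuit, curve)
            circuit = replace(circuit, C_ao=C_ao, C_SAC=C_SAC)
        except NoConvergenceError:
            break
    return circuit, curve


# ---------------------------------------------------------------------------
# outputs


def lv_workload(sol: CycleSolution) -> float:
    """LV stroke work |closed P-V loop area| over the cycle, in joules."""
    w_mmhg_ml = np.trapezoid(sol.P_LV, sol.V_LV)
    return abs(float(w_mmhg_ml)) * MMHG_ML_TO_J


@dataclass
class BoundaryWaveforms:
    """Periodic waveforms handed from the circuit model to the 3-D solver."""

    t: np.ndarray              # s, uniform grid over one period
    Q_inlet: np.ndarray        # mL/s
    p_outlet: np.ndarray       # mmHg
    Q_branches_total: np.ndarray  # mL/s
    T: float                   # period (s)


def extract_boundary_waveforms(sol: CycleSolution,
                               n_samples: int = 200) -> BoundaryWaveforms:
    """Resample the converged cycle onto a uniform periodic grid.

    Inlet flow is the transvalvular flow, outlet pressure the descending
    aorta pressure, and the branch total the upper-body flow.
    """
    t_new = np.linspace(0.0, sol.T, n_samples + 1)

    def resamp(y):
        return np.interp(t_new, sol.t, y)

    return BoundaryWaveforms(
        t=t_new, Q_inlet=resamp(sol.Q_av), p_outlet=resamp(sol.P_desc),
        Q_branches_total=resamp(sol.Q_ub), T=sol.T)
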