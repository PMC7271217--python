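"""End-to-end pipeline: circuit model -> boundary waveforms -> 3-D solver ->
hemodynamic report.

The lumped-parameter model supplies the time-dependent inlet flow
(transvalvular flow at the ascending aorta) and outlet pressure (descending
aorta); the lattice-Boltzmann solver runs the voxelized geometry through a
ramped start-up plus a number of warm-up and measured cardiac cycles;
WSS/TAWSS, TKE, Reynolds number and trans-stenotic pressure drop are
extracted from phase snapshots of the measured cycles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .boundaries import BoundarySet
from .engine import Simulation
from .geometry import (StenosisShape, VoxelDomain, make_coarctation_tube,
                       make_straight_tube)
from .les import LESParams
from .lpm import (BoundaryWaveforms, CycleSolution, PatientInputs,
                  build_patient_model, extract_boundary_waveforms,
                  lv_workload, simulate_cycles)
from .metrics import (format_change, percent_change, pressure_drop,
                      reynolds_number, tawss, wall_shear_field)
from .units import LatticeSpec, mmhg_to_pa, pa_to_dyncm2


@dataclass
class RunConfig:
    """Fully serializable description of one coupled run."""

    patient: dict                      # PatientInputs fields
    geometry: dict = field(default_factory=dict)  # fixture parameters
    dx: float = 1.5e-3                 # m
    dt: float = 1e-4                   # s
    nu_phys: float = 3.3333e-6         # m^2/s
    rho_phys: float = 1050.0           # kg/m^3
    les: bool = True
    Cs: float = 0.1
    warmup_cycles: int = 2
    measured_cycles: int = 5
    phases_per_cycle: int = 20
    ramp_fraction: float = 0.25        # T_ramp as fraction of the cycle
    wss_offset: int = 2
    outdir: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def patient_inputs(self) -> PatientInputs:
        return PatientInputs(**self.patient)

    def make_domain(self) -> VoxelDomain:
        g = dict(self.geometry)
        kind = g.pop("kind", "coarctation")
        spec = LatticeSpec(nx=1, ny=1, nz=1, dx=self.dx, dt=self.dt,
                           rho_phys=self.rho_phys, nu_phys=self.nu_phys)
        if kind == "straight":
            return make_straight_tube(g["R0"], g["L"], spec)
        if kind == "coarctation":
            shape = StenosisShape(**g)
            return make_coarctation_tube(shape, spec)
        raise ValueError(f"unknown geometry kind {kind!r}")


@dataclass
class HemodynamicReport:
    """Scalar summary of one coupled run (units in the field names)."""

    peak_tawss_dyncm2: float
    peak_tke_nm2: float
    re_max: float
    peak_dp_mmhg: float
    peak_velocity_ms: float
    lv_workload_j: float
    lv_peak_pressure_mmhg: float
    peak_tpg_coa_mmhg: float
    mass_drift_fraction: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(d.pop("extras"))
        return d

    def metric_keys(self):
        return [f.name for f in dataclasses.fields(self)
                if f.name != "extras"]


def periodic_waveform(t, y, T: float, preserve_integral: bool = True):
    """Periodic cubic interpolant of a sampled cycle waveform.

    After interpolation the waveform is rescaled about its mean so the cycle
    integral of the samples is preserved exactly.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    yy = y.copy()
    yy[-1] = yy[0]                      # enforce exact periodicity
    cs = CubicSpline(t, yy, bc_type="periodic")
    if preserve_integral:
        target = np.trapezoid(yy, t)
        got = cs.integrate(t[0], t[-1])
        offset = (target - got) / T
    else:
        offset = 0.0

    def wave(s):
        return cs(np.asarray(s) % T) + offset

    wave.T = T
    return wave


class _TKEAccumulator:
    """Streaming phase-ensemble TKE: per-phase running sums of u and u^2."""

    def __init__(self, n_phases: int, grid_shape):
        self.n = np.zeros(n_phases, dtype=np.int64)
        self.s1 = np.zeros((n_phases,) + tuple(grid_shape) + (3,))
        self.s2 = np.zeros((n_phases,) + tuple(grid_shape) + (3,))

    def add(self, phase: int, u):
        self.n[phase] += 1
        self.s1[phase] += u
        self.s2[phase] += u * u

    def tke(self, rho: float):
        if self.n.min() < 2:
            raise ValueError("need at least 2 cycles per phase")
        n = self.n[:, None, None, None, None].astype(np.float64)
        var = self.s2 / n - (self.s1 / n) ** 2
        k = 0.5 * rho * var.sum(axis=-1).mean(axis=0)
        return k, float(np.nanmax(k))


def run_coupled(config: RunConfig):
    """Execute the full pipeline; returns (HemodynamicReport, artifacts).

    ``artifacts`` carries the cycle solution, boundary waveforms, domain and
    solver for further inspection; if ``config.outdir`` is set, JSON/CSV
    outputs are written there.  Deterministic given the config.
    """
    inputs = config.patient_inputs()
    circuit, curve = build_patient_model(inputs)
    sol = simulate_cycles(inputs, circuit, curve)
    waves = extract_boundary_waveforms(sol)
    report, artifacts = run_lbm_cycles(config, waves, sol=sol)
    if config.outdir:
        _write_outputs(Path(config.outdir), config, sol, waves, report)
    return report, artifacts


def run_lbm_cycles(config: RunConfig, waves: BoundaryWaveforms,
                   sol: Optional[CycleSolution] = None):
    """LBM part of the pipeline, reusable with externally supplied
    waveforms (e.g. read back from CSV)."""
    domain = config.make_domain()
    spec = domain.spec
    T = waves.T

    # inlet flow entering the descending-aorta path: the branch flow leaves
    # upstream of the fixture, so the tube carries Q_av - Q_ub
    q_net = waves.Q_inlet - waves.Q_branches_total
    q_wave = periodic_waveform(waves.t, q_net * 1e-6, T)   # m^3/s
    p_ref = float(np.mean(mmhg_to_pa(waves.p_outlet)))
    p_wave = periodic_waveform(waves.t, mmhg_to_pa(waves.p_outlet), T,
                               preserve_integral=False)

    def Q_lat(t):
        return spec.q_to_lat(q_wave(t))

    def rho_out(t):
        return spec.p_to_lat_rho(p_wave(t), p_ref)

    bset = BoundarySet(domain=domain, Q_inlet=Q_lat, rho_outlet=rho_out,
                       T_ramp=config.ramp_fraction * T)
    les = LESParams(Cs=config.Cs) if config.les else None
    sim = Simulation(domain, boundaries=bset, les=les)

    steps_per_cycle = int(round(T / spec.dt))
    n_phases = config.phases_per_cycle
    phase_steps = np.unique(np.linspace(
        0, steps_per_cycle, n_phases, endpoint=False).astype(int))
    n_phases = len(phase_steps)

    mu = spec.rho_phys * spec.nu_phys
    acc = _TKEAccumulator(n_phases, domain.flags.shape)
    tau_series = []
    tau_times = []
    dp_series = []
    umax_phys = 0.0
    re_max = 0.0
    mass_start = None
    mass_end = None
    mass_throughput = 0.0

    # stations for the pressure drop and Reynolds number
    nz = domain.flags.shape[2]
    # bulk metrics exclude the first/last two planes (inlet/outlet closure)
    interior = domain.fluid_mask.copy()
    interior[:, :, :2] = False
    interior[:, :, nz - 2:] = False
    z_prox = max(1, int(0.15 * nz))
    z_dist = min(nz - 2, int(0.85 * nz))
    if domain.radius_profile is not None:
        zt = np.argmin(domain.radius_profile(np.arange(nz).astype(float)))
        d_throat = 2.0 * float(domain.radius_profile(float(zt))) * spec.dx
    else:
        zt = nz // 2
        d_throat = 2.0 * domain.inlet_radius_vox * spec.dx

    total_cycles = config.warmup_cycles + config.measured_cycles
    for cyc in range(total_cycles):
        measured = cyc >= config.warmup_cycles
        if measured and mass_start is None:
            mass_start = sim.mass()
        phase_set = set(int(x) for x in phase_steps)
        for s in range(steps_per_cycle):
            at_phase = measured and (s in phase_set)
            sim.step(compute_diag=at_phase or (s % 25 == 24))
            t_now = sim.time
            if measured:
                mass_throughput += abs(Q_lat(t_now)) * 1.0  # lattice mass/step
            if at_phase:
                phase = int(np.searchsorted(phase_steps, s))
                rho_g, u_g = sim.macroscopics()
                u_phys = u_g * spec.u_scale
                acc.add(phase, u_phys)
                wss = wall_shear_field(u_phys, domain, mu,
                                       offset=config.wss_offset)
                tau_series.append(wss)
                tau_times.append(t_now)
                p = spec.p_to_phys(rho_g, p_ref)
                dp_series.append(float(pressure_drop(
                    p, domain.fluid_mask, z_prox, z_dist)))
                umag = np.linalg.norm(u_phys, axis=-1)
                umax_phys = max(umax_phys, float(umag[interior].max()))
                sect = umag[:, :, zt][domain.fluid_mask[:, :, zt]]
                if sect.size:
                    re_max = max(re_max, reynolds_number(
                        float(sect.mean()), d_throat, spec.nu_phys))
        if measured:
            mass_end = sim.mass()

    tau_arr = np.array(tau_series)
    tau_t = np.array(tau_times)
    tawss_field = tawss(tau_arr, tau_t, T)
    wz = domain.wall_nodes[:, 2]
    wall_sel = (wz >= 2) & (wz <= nz - 3)
    peak_tawss = float(np.nanmax(tawss_field[wall_sel]))
    k_field, _ = acc.tke(spec.rho_phys)
    peak_tke = float(np.nanmax(k_field[interior]))
    drift = abs(mass_end - mass_start) / max(mass_throughput, 1e-300)

    report = HemodynamicReport(
        peak_tawss_dyncm2=pa_to_dyncm2(peak_tawss),
        peak_tke_nm2=peak_tke,
        re_max=re_max,
        peak_dp_mmhg=float(np.max(dp_series)),
        peak_velocity_ms=umax_phys,
        lv_workload_j=lv_workload(sol) if sol is not None else float("nan"),
        lv_peak_pressure_mmhg=float(sol.P_LV.max()) if sol is not None
        else float("nan"),
        peak_tpg_coa_mmhg=sol.peak_tpg_coa() if sol is not None
        else float("nan"),
        mass_drift_fraction=float(drift),
        extras={"n_phases": int(n_phases),
                "steps_per_cycle": int(steps_per_cycle)},
    )
    artifacts = {"sim": sim, "domain": domain, "waves": waves, "sol": sol,
                 "tawss_field": tawss_field, "config": config}
    return report, artifacts


def compare_pre_post(report_pre, report_post) -> dict:
    """Percent-change table between two reports (pre -> post intervention).

    Values carry the raw signed percent plus the rounded report text; raises
    on mismatched metric keys.
    """
    pre = report_pre.to_dict() if hasattr(report_pre, "to_dict") \
        else dict(report_pre)
    post = report_post.to_dict() if hasattr(report_post, "to_dict") \
        else dict(report_post)
    if set(pre) != set(post):
        raise KeyError("reports carry different metric keys")
    table = {}
    for k in pre:
        a, b = pre[k], post[k]
        if not (np.isscalar(a) and np.isscalar(b)):
            continue
        if not np.isfinite([a, b]).all() or a == 0:
            table[k] = {"pre": a, "post": b, "percent": None, "text": "n/a"}
            continue
        pct = percent_change(a, b)
        table[k] = {"pre": a, "post": b, "percent": pct,
                    "text": format_change(pct)}
    return table


def _write_outputs(outdir: Path, config: RunConfig, sol, waves, report):
    from .io import write_cycle_csv, write_waveforms_csv

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    write_cycle_csv(outdir / "lpm_cycle.csv", sol)
    write_waveforms_csv(outdir / "boundary_waveforms.csv", waves)
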