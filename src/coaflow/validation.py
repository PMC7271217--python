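"""Solver validation benchmarks against analytic oracles.

Each routine builds its fixture, runs the solver to a steady or periodic
state and returns the comparison metrics as a plain dict.  They are shared
by the test suite and by the reproduction script, and every problem size is
chosen to run in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .boundaries import BoundarySet
from .core import bgk_collide, mrt_collide, stream
from .engine import Simulation
from .geometry import (analytic_poiseuille, make_inclined_channel,
                       make_straight_tube)
from .les import LESParams
from .metrics import wall_shear_field
from .stencil import MRTOperator
from .units import LatticeSpec


def _tube_setup(r_nodes: int, length_nodes: int, nu_lat: float,
                u_mean_lat: float, dx: float = 1e-3):
    """Straight-tube fixture with acoustic scaling (dx = dt numerically)."""
    dt = 1e-3
    nu_phys = nu_lat * dx**2 / dt
    spec = LatticeSpec(nx=1, ny=1, nz=1, dx=dx, dt=dt, rho_phys=1050.0,
                       nu_phys=nu_phys)
    R0 = r_nodes * dx
    dom = make_straight_tube(R0, length_nodes * dx, spec)
    Q = u_mean_lat * (dx / dt) * np.pi * R0**2
    q_lat = dom.spec.q_to_lat(Q)
    bset = BoundarySet(domain=dom, Q_inlet=lambda t: q_lat,
                       rho_outlet=lambda t: 1.0, T_ramp=300 * dt)
    return dom, bset, Q, R0


def poiseuille_tube_benchmark(r_nodes: int = 12, length_nodes: int = 120,
                              nu_lat: float = 0.05,
                              u_mean_lat: float = 0.015,
                              les: bool = False,
                              max_steps: int = 12000) -> dict:
    """Steady laminar pipe flow vs the analytic parabola and wall shear.

    Returns the mid-tube velocity L2 error, the wall-WSS relative error
    against 4 mu u_mean / R0, and run metadata.
    """
    dom, bset, Q, R0 = _tube_setup(r_nodes, length_nodes, nu_lat, u_mean_lat)
    spec = dom.spec
    sim = Simulation(dom, boundaries=bset,
                     les=LESParams() if les else None)
    steady = sim.run_to_steady(max_steps, tol=1e-8)
    u = sim.velocity_phys()

    prof, _ = analytic_poiseuille(R0, Q, spec.nu_phys, spec.rho_phys)
    nx, ny, nz = dom.flags.shape
    c = (nx - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.hypot(ii - c, jj - c) * spec.dx
    zmid = nz // 2
    mask = dom.fluid_mask[:, :, zmid]
    ua = prof(r)
    du = u[:, :, zmid, 2][mask] - ua[mask]
    l2 = float(np.sqrt((du**2).sum() / (ua[mask] ** 2).sum()))

    mu = spec.rho_phys * spec.nu_phys
    u_mean = Q / (np.pi * R0**2)
    wss_true = 4.0 * mu * u_mean / R0
    wss = wall_shear_field(u, dom, mu, offset=2)
    interior = (dom.wall_nodes[:, 2] > nz // 4) & \
        (dom.wall_nodes[:, 2] < 3 * nz // 4)
    wss_err = float(abs(np.nanmean(wss[interior]) - wss_true) / wss_true)

    return {"l2_error": l2, "wss_error": wss_err, "steady": steady,
            "steps": sim.step_count, "n_fluid": dom.n_fluid,
            "grid": dom.flags.shape, "sim": sim, "domain": dom, "Q": Q}


def mrt_bgk_equivalence(n_steps: int = 100, tau: float = 0.8,
                        shape=(6, 6, 6), seed: int = 0) -> dict:
    """Uniform-rate MRT vs BGK over repeated collide-stream steps.

    With every non-conserved moment relaxed at 1/tau and the projection
    ghost equilibria, the MRT update is algebraically identical to BGK; the
    two trajectories from a common random initial field are compared after
    ``n_steps`` periodic steps.
    """
    rng = np.random.default_rng(seed)
    f0 = rng.uniform(0.05, 1.0, size=shape + (19,))
    op = MRTOperator.uniform(tau)
    fa = f0.copy()
    fb = f0.copy()
    for _ in range(n_steps):
        fa = stream(mrt_collide(fa, op))
        fb = stream(bgk_collide(fb, tau))
    return {"max_abs_diff": float(np.abs(fa - fb).max()),
            "n_steps": n_steps}


def inclined_channel_benchmark(h_nodes: float = 10.0,
                               theta_deg: float = 25.0,
                               length_nodes: int = 40,
                               nu_lat: float = 0.05,
                               u_mean_lat: float = 0.02,
                               max_steps: int = 6000) -> dict:
    """Bouzidi interpolated bounce-back vs staircase on a tilted channel.

    Plane Poiseuille flow in a channel whose walls are not grid aligned;
    the same flags are run twice, once with the exact wall distances and
    once with q = 1/2 everywhere (simple bounce-back), and both steady
    fields are compared with the analytic parabola across the gap.
    """
    dx = dt = 1e-3
    theta = np.radians(theta_deg)
    spec = LatticeSpec(nx=1, ny=1, nz=1, dx=dx, dt=dt, rho_phys=1050.0,
                       nu_phys=nu_lat * dx**2 / dt)
    H = h_nodes * dx
    dom = make_inclined_channel(H, theta, length_nodes * dx, spec)
    sd = dom.signed_distance
    ehat = np.array([np.sin(theta), 0.0, np.cos(theta)])
    u_max = 1.5 * u_mean_lat

    def profile_at(nodes):
        d = sd(nodes[:, 0], nodes[:, 1], nodes[:, 2]) / dom.gap_vox * 2.0
        mag = u_max * np.maximum(1.0 - d**2, 0.0)
        return mag[:, None] * ehat[None, :]

    def run(dom_k):
        inlet_nodes = np.argwhere(dom_k.patch_mask(2))
        u_in = profile_at(inlet_nodes)
        bset = BoundarySet(domain=dom_k, Q_inlet=lambda t: 0.0,
                           rho_outlet=lambda t: 1.0, T_ramp=300 * dt,
                           inlet_velocity=lambda t: u_in)
        sim = Simulation(dom_k, boundaries=bset, les=None)
        sim.run_to_steady(max_steps, tol=1e-8)
        _, u = sim.macroscopics()
        nz = dom_k.flags.shape[2]
        sl = (dom_k.flags[:, :, nz // 2] != 0)
        nodes = np.argwhere(dom_k.flags != 0)
        nodes = nodes[nodes[:, 2] == nz // 2]
        ua = profile_at(nodes)
        got = u[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
        return float(np.sqrt(((got - ua) ** 2).sum()
                             / (ua**2).sum()))

    err_bouzidi = run(dom)

    import copy
    dom_stair = copy.copy(dom)
    dom_stair.link_q = np.full_like(dom.link_q, 0.5)
    err_stair = run(dom_stair)

    return {"bouzidi_error": err_bouzidi, "staircase_error": err_stair,
            "ratio": err_bouzidi / err_stair, "theta_deg": theta_deg,
            "h_nodes": h_nodes}


def les_laminar_benchmark(r_nodes: int = 8, length_nodes: int = 40,
                          nu_lat: float = 0.05, u_mean_lat: float = 0.015,
                          max_steps: int = 8000) -> dict:
    """LES vs no-LES on a resolved laminar tube flow.

    In a resolved laminar flow the non-equilibrium stress is tiny and the
    Smagorinsky eddy viscosity must vanish, so the two steady fields should
    agree to a fraction of a percent.
    """
    results = []
    for les in (False, True):
        dom, bset, Q, R0 = _tube_setup(r_nodes, length_nodes, nu_lat,
                                       u_mean_lat)
        sim = Simulation(dom, boundaries=bset,
                         les=LESParams() if les else None)
        sim.run_to_steady(max_steps, tol=1e-8)
        _, u = sim.macroscopics()
        results.append((u, dom, sim))
    (u0, dom, sim0), (u1, _, sim1) = results
    mask = dom.fluid_mask
    scale = np.abs(u0[mask]).max()
    diff = float(np.abs(u1[mask] - u0[mask]).max() / scale)
    return {"relative_difference": diff,
            "tau_max_les": sim1.step().tau_max,
            "tau_mol": dom.spec.tau_mol}
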