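"""Boundary conditions: curved-wall bounce-back, inlet velocity, outlet
pressure and branch outflow split.

Walls use the interpolated bounce-back of Bouzidi: the reflected population
at a wall-adjacent fluid node A is built from post-collision populations at A
(and, for near-wall cuts q < 1/2, at the next fluid node E upstream),
weighted by the normalized wall distance q.  At q = 1/2 both branches reduce
to simple bounce-back.

The velocity inlet follows the Skordos approach: boundary-node density is
extrapolated from the bulk with a second-order one-sided difference and the
populations are set to equilibrium plus a non-equilibrium correction built
from the finite-difference velocity gradient.  The pressure outlet fixes the
density through the lattice equation of state and extrapolates velocity from
the interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import equilibrium
from .stencil import CS2, E, OPPOSITE, W
from .geometry import INLET, OUTLET, SOLID, VoxelDomain


def startup_ramp(t: float, T_ramp: float):
    """Sinusoidal start-up factor: sin^2(pi t / (2 T_ramp)) capped at 1.

    C1-continuous at t = T_ramp (zero slope on both sides).
    """
    if T_ramp <= 0:
        raise ValueError("T_ramp must be positive")
    t = np.asarray(t, dtype=np.float64)
    s = np.sin(np.pi * np.minimum(t, T_ramp) / (2.0 * T_ramp)) ** 2
    return s if s.ndim else float(s)


def branch_flow_split(Q_total, areas):
    """Distribute total branch flow in proportion to cross-sectional areas."""
    areas = np.asarray(areas, dtype=np.float64)
    if np.any(areas <= 0):
        raise ValueError("branch areas must be positive")
    frac = areas / areas.sum()
    Q_total = np.asarray(Q_total, dtype=np.float64)
    return np.multiply.outer(Q_total, frac) if Q_total.ndim else Q_total * frac


def bouzidi_reflect(f_c_A, f_c_E, f_c_rev_A, q, e_ok=None):
    """Reflected population(s) for cut links, vectorised over links.

    ``f_c_A``/``f_c_E``: post-collision populations travelling into the wall
    at the boundary node A and at the next fluid node E = A - e upstream;
    ``f_c_rev_A``: the reversed-direction post-collision population at A;
    ``q``: normalized wall distance per link; ``e_ok``: mask of links whose
    upstream node E is fluid (missing E degrades to simple bounce-back).
    """
    q = np.asarray(q, dtype=np.float64)
    near = q < 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        far_val = f_c_A / (2.0 * q) + f_c_rev_A * (2.0 * q - 1.0) / (2.0 * q)
    near_val = 2.0 * q * f_c_A + (1.0 - 2.0 * q) * f_c_E
    out = np.where(near, near_val, far_val)
    if e_ok is not None:
        out = np.where(near & ~np.asarray(e_ok), f_c_A, out)
    return out


def apply_bouzidi(f_new, f_post, domain: VoxelDomain):
    """Write reflected wall populations into the post-streaming field.

    ``f_post`` is the post-collision (pre-streaming) field; ``f_new`` the
    streamed field being completed in place.
    """
    A = domain.link_node
    a = domain.link_dir
    q = domain.link_q
    Eup = A - E[a]
    nx, ny, nz = domain.flags.shape
    in_box = ((Eup >= 0) & (Eup < [nx, ny, nz])).all(axis=1)
    Ec = np.clip(Eup, 0, [nx - 1, ny - 1, nz - 1])
    e_ok = in_box & (domain.flags[Ec[:, 0], Ec[:, 1], Ec[:, 2]] != SOLID)
    f_c_A = f_post[A[:, 0], A[:, 1], A[:, 2], a]
    f_c_E = f_post[Ec[:, 0], Ec[:, 1], Ec[:, 2], a]
    f_c_rev_A = f_post[A[:, 0], A[:, 1], A[:, 2], OPPOSITE[a]]
    vals = bouzidi_reflect(f_c_A, f_c_E, f_c_rev_A, q, e_ok)
    f_new[A[:, 0], A[:, 1], A[:, 2], OPPOSITE[a]] = vals
    return f_new


def _skordos_populations(rho, u, grad, tau):
    """Equilibrium plus gradient-based non-equilibrium populations.

    ``grad[n, i, j]`` = d u_j / d x_i (lattice units) at the patch nodes;
    the correction is the regularized Chapman-Enskog form
    f_neq_a = -w_a rho tau / cs2 * (e_ai e_aj - cs2 d_ij) S_ij with S the
    symmetrized strain rate.
    """
    feq = equilibrium(rho, u)
    S = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    Ef = E.astype(np.float64)
    Q = Ef[:, :, None] * Ef[:, None, :] - CS2 * np.eye(3)   # (19, 3, 3)
    contr = np.einsum("aij,nij->na", Q, S)
    fneq = -W[None, :] * rho[:, None] * tau / CS2 * contr
    return feq + fneq


def _patch_stencil(nodes, normal_axis):
    """Neighbour-index table for in-plane differences on a planar patch.

    Returns (taxes, ip, im): for each tangential axis, the patch index of
    the +1/-1 neighbour (or -1 where it is outside the patch).
    """
    taxes = [ax for ax in range(3) if ax != normal_axis]
    idx = {tuple(nd[taxes]): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    ip = np.full((2, n), -1, dtype=np.int64)
    im = np.full((2, n), -1, dtype=np.int64)
    for i, nd in enumerate(nodes):
        key = tuple(nd[taxes])
        for t_i in range(2):
            kp = list(key)
            km = list(key)
            kp[t_i] += 1
            km[t_i] -= 1
            ip[t_i, i] = idx.get(tuple(kp), -1)
            im[t_i, i] = idx.get(tuple(km), -1)
    return taxes, ip, im


def _patch_tangential_gradients(nodes, values, normal_axis, stencil=None):
    """In-plane first derivatives of a field defined on a planar patch.

    ``values``: (n, 3) vectors at the patch ``nodes``; returns (n, 3, 3)
    gradient tensors with only the two tangential rows filled (central
    differences inside the patch, one-sided toward its rim).
    """
    taxes, ip, im = stencil if stencil is not None \
        else _patch_stencil(nodes, normal_axis)
    n = len(nodes)
    grad = np.zeros((n, 3, 3))
    for t_i, ax in enumerate(taxes):
        p = ip[t_i]
        q = im[t_i]
        vp = np.where((p >= 0)[:, None], values[np.maximum(p, 0)], values)
        vm = np.where((q >= 0)[:, None], values[np.maximum(q, 0)], values)
        both = (p >= 0) & (q >= 0)
        one = (p >= 0) ^ (q >= 0)
        d = np.zeros((n, 3))
        d[both] = 0.5 * (vp[both] - vm[both])
        d[one] = vp[one] - vm[one]
        grad[:, ax, :] = d
    return grad


class PatchNotPlanarError(ValueError):
    pass


def inlet_velocity_bc(f, domain: VoxelDomain, u_patch, tau: float,
                      stencil=None):
    """Impose a prescribed velocity on the inlet patch (all 19 populations).

    ``u_patch``: (n_inlet, 3) prescribed lattice velocity at the inlet nodes
    (ordered as ``np.nonzero(domain.patch_mask(INLET))``).  Density is
    extrapolated from the two interior planes with a second-order one-sided
    difference; the non-equilibrium part uses the one-sided normal velocity
    gradient.
    """
    ax = domain.axis
    nodes = np.argwhere(domain.patch_mask(INLET))
    if len(nodes) == 0:
        return f
    if not (nodes[:, ax] == nodes[0, ax]).all():
        raise PatchNotPlanarError("inlet patch must be planar")
    step = np.zeros(3, dtype=np.int64)
    step[ax] = 1 if nodes[0, ax] == 0 else -1
    n1 = nodes + step
    n2 = nodes + 2 * step

    f1 = f[n1[:, 0], n1[:, 1], n1[:, 2], :]
    f2 = f[n2[:, 0], n2[:, 1], n2[:, 2], :]
    ok1 = domain.flags[n1[:, 0], n1[:, 1], n1[:, 2]] != SOLID
    ok2 = ok1 & (domain.flags[n2[:, 0], n2[:, 1], n2[:, 2]] != SOLID)
    rho1 = np.where(ok1, f1.sum(-1), 1.0)
    rho2 = np.where(ok2, f2.sum(-1), 1.0)
    # boundary density from the node's own known populations (in-plane and
    # incoming from the interior) and the prescribed normal velocity:
    # rho (1 - u_n) = sum_{e_n = 0} f + 2 sum_{e_n = -sign} f
    f0 = f[nodes[:, 0], nodes[:, 1], nodes[:, 2], :]
    en = E[:, ax] * step[ax]
    un = u_patch[:, ax] * step[ax]
    rho0 = (f0[:, en == 0].sum(-1) + 2.0 * f0[:, en == -1].sum(-1)) \
        / (1.0 - un)
    u1 = np.where(ok1[:, None], (f1 @ E.astype(np.float64))
                  / rho1[:, None], u_patch)
    u2 = np.where(ok2[:, None], (f2 @ E.astype(np.float64))
                  / rho2[:, None], u1)
    # second-order one-sided normal derivative plus in-plane derivatives of
    # the prescribed patch field (falls back to first order / zero where
    # the stencil exits the fluid)
    dudn = (-3.0 * u_patch + 4.0 * u1 - u2) / 2.0 * step[ax]
    dudn[~ok1] = 0.0
    grad = _patch_tangential_gradients(nodes, u_patch, ax, stencil)
    grad[:, ax, :] = dudn

    f[nodes[:, 0], nodes[:, 1], nodes[:, 2], :] = _skordos_populations(
        rho0, u_patch, grad, tau)
    return f


def outlet_pressure_bc(f, domain: VoxelDomain, rho_out: float, tau: float,
                       flag: int = OUTLET):
    """Impose lattice density ``rho_out`` on an outlet patch.

    The outlet plane copies the full population set of the neighbouring
    interior plane (zero normal gradient, so the velocity profile leaves
    undistorted) rescaled to the prescribed density, which anchors the
    pressure through the lattice equation of state.
    """
    ax = domain.axis
    nodes = np.argwhere(domain.patch_mask(flag))
    if len(nodes) == 0:
        return f
    if not (nodes[:, ax] == nodes[0, ax]).all():
        raise PatchNotPlanarError("outlet patch must be planar")
    nmax = domain.flags.shape[ax] - 1
    step = np.zeros(3, dtype=np.int64)
    step[ax] = -1 if nodes[0, ax] == nmax else 1
    n1 = nodes + step

    f1 = f[n1[:, 0], n1[:, 1], n1[:, 2], :]
    ok1 = domain.flags[n1[:, 0], n1[:, 1], n1[:, 2]] != SOLID
    rho1 = f1.sum(-1)
    scale = float(rho_out) / np.where(rho1 > 0, rho1, 1.0)
    vals = f1 * scale[:, None]
    # nodes with no interior neighbour behind them rest at the set density
    vals[~ok1] = equilibrium(np.float64(rho_out), np.zeros(3))
    f[nodes[:, 0], nodes[:, 1], nodes[:, 2], :] = vals
    return f


def poiseuille_patch_profile(domain: VoxelDomain, flag: int = INLET):
    """Parabolic axial profile weights on a circular patch.

    Returns ``(nodes, weights)`` where weights sum to 1, so the axial
    velocity realising a lattice flow rate Q is ``u_z = Q * weights / 1``
    per node... weights are normalized so that ``sum(u_z) = Q`` when
    ``u_z = Q * weights``; the discrete flux then equals Q exactly.
    """
    nodes = np.argwhere(domain.patch_mask(flag))
    cx, cy = domain.center
    r = np.hypot(nodes[:, 0] - cx, nodes[:, 1] - cy)
    R = domain.inlet_radius_vox
    w = np.maximum(1.0 - (r / R) ** 2, 0.0)
    s = w.sum()
    if s <= 0:
        raise ValueError("degenerate inlet patch")
    return nodes, w / s


@dataclass
class BoundarySet:
    """Everything the solver needs to close the domain.

    ``Q_inlet(t)``: lattice flow rate through the inlet patch;
    ``rho_outlet(t)``: lattice density at the pressure outlet;
    ``Q_branches(t)``: total lattice branch flow, split by area over branch
    patches (prescribed-velocity outflow).  ``T_ramp`` scales the inlet
    during start-up.
    """

    domain: VoxelDomain
    Q_inlet: object                   # callable t -> lattice flow rate
    rho_outlet: object                # callable t -> lattice density
    T_ramp: float = 0.0
    Q_branches: Optional[object] = None
    branch_flags: tuple = ()
    branch_areas: tuple = ()
    inlet_velocity: Optional[object] = None  # callable t -> (n, 3) override

    def __post_init__(self):
        if self.inlet_velocity is None:
            self._inlet_nodes, self._inlet_w = poiseuille_patch_profile(
                self.domain, INLET)
        else:
            self._inlet_nodes = np.argwhere(self.domain.patch_mask(INLET))
            self._inlet_w = None
        self._inlet_stencil = _patch_stencil(self._inlet_nodes,
                                             self.domain.axis)

    def apply(self, f, t: float, tau: float):
        scale = startup_ramp(t, self.T_ramp) if self.T_ramp > 0 else 1.0
        ax = self.domain.axis
        if self.inlet_velocity is not None:
            u_patch = np.asarray(self.inlet_velocity(t)) * scale
        else:
            Q = float(self.Q_inlet(t)) * scale
            u_patch = np.zeros((len(self._inlet_nodes), 3))
            sign = 1.0 if self._inlet_nodes[0, ax] == 0 else -1.0
            u_patch[:, ax] = sign * Q * self._inlet_w
        inlet_velocity_bc(f, self.domain, u_patch, tau,
                          stencil=self._inlet_stencil)
        outlet_pressure_bc(f, self.domain, float(self.rho_outlet(t)), tau)
        if self.Q_branches is not None and self.branch_flags:
            Qk = branch_flow_split(float(self.Q_branches(t)) * scale,
                                   self.branch_areas)
            for fl, q_k in zip(self.branch_flags, Qk):
                _branch_outflow(f, self.domain, fl, q_k, tau)
        return f


def _branch_outflow(f, domain, flag, Q, tau):
    """Prescribed-velocity (plug) outflow on a branch patch.

    The patch normal is taken as the lattice axis on which the patch is
    planar; density is extrapolated from the nearest interior plane.
    """
    nodes = np.argwhere(domain.patch_mask(flag))
    if len(nodes) == 0:
        return f
    planar = [ax for ax in range(3) if (nodes[:, ax] == nodes[0, ax]).all()]
    if not planar:
        raise PatchNotPlanarError("branch patch must be planar")
    ax = planar[0]
    nmax = domain.flags.shape[ax] - 1
    step = np.zeros(3, dtype=np.int64)
    step[ax] = 1 if nodes[0, ax] == 0 else -1
    n1 = nodes + step
    rho1 = f[n1[:, 0], n1[:, 1], n1[:, 2], :].sum(-1)
    u_patch = np.zeros((len(nodes), 3))
    u_patch[:, ax] = -step[ax] * Q / len(nodes)  # outflow points off-domain
    feq = equilibrium(rho1, u_patch)
    f[nodes[:, 0], nodes[:, 1], nodes[:, 2], :] = feq
    return f
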