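"""Hemodynamic indices: WSS, TAWSS, TKE, Reynolds number, pressure drop.

Wall shear stress is evaluated a configurable number of lattice nodes away
from the staircase wall: the velocity gradient is formed there by first-order
finite differences, the viscous stress sigma = 2 mu eps follows, and the
wall traction is the tangential projection tau = sigma.n - (n.sigma.n) n.
The pressure part of the total stress drops out of the tangential
projection.  TAWSS is the cycle average of |tau|; TKE uses the
phase-ensemble decomposition of velocity over repeated cycles.
"""

from __future__ import annotations

import numpy as np

from .geometry import VoxelDomain
from .units import pa_to_mmhg


class IncompleteCycleError(ValueError):
    pass


class MismatchedPhaseGridError(ValueError):
    pass


class ZeroBaselineError(ZeroDivisionError):
    pass


def velocity_gradient_offwall(u, domain: VoxelDomain, offset: int = 2):
    """Velocity gradient tensors on a shell ``offset`` nodes off the wall.

    ``u``: physical velocity (nx, ny, nz, 3) in m/s.  Returns
    ``(samples, grad, valid)`` where ``samples`` are the (m, 3) lattice
    coordinates of the sampling shell (one per wall-adjacent node, moved
    ``offset`` links inward along the surface normal), ``grad[m, i, j]`` is
    d u_j / d x_i (1/s) by first-order differences, and ``valid`` flags
    samples whose difference stencils stayed inside the fluid.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    dx = domain.spec.dx
    fluid = domain.fluid_mask
    nx, ny, nz = fluid.shape
    n = domain.wall_normals
    samples = np.rint(domain.wall_nodes - offset * n).astype(np.int64)
    samples = np.clip(samples, 0, [nx - 1, ny - 1, nz - 1])

    m = len(samples)
    grad = np.zeros((m, 3, 3))
    valid = np.ones(m, dtype=bool)
    for idx in range(m):
        p = samples[idx]
        if not fluid[p[0], p[1], p[2]]:
            valid[idx] = False
            continue
        for ax in range(3):
            fwd = p.copy()
            bwd = p.copy()
            fwd[ax] = min(fwd[ax] + 1, [nx, ny, nz][ax] - 1)
            bwd[ax] = max(bwd[ax] - 1, 0)
            f_ok = fluid[fwd[0], fwd[1], fwd[2]] and not (fwd == p).all()
            b_ok = fluid[bwd[0], bwd[1], bwd[2]] and not (bwd == p).all()
            if f_ok and b_ok:
                d = (u[fwd[0], fwd[1], fwd[2]] - u[bwd[0], bwd[1], bwd[2]]) \
                    / (2.0 * dx)
            elif f_ok:
                d = (u[fwd[0], fwd[1], fwd[2]] - u[p[0], p[1], p[2]]) / dx
            elif b_ok:
                d = (u[p[0], p[1], p[2]] - u[bwd[0], bwd[1], bwd[2]]) / dx
            else:
                valid[idx] = False
                d = np.zeros(3)
            grad[idx, ax, :] = d
    return samples, grad, valid


def wss_traction(grad, n, mu: float):
    """Wall traction vector(s) and magnitude from velocity gradient(s).

    ``grad[..., i, j]`` = d u_j / d x_i; ``n``: unit outward normal(s).
    sigma = 2 mu eps with eps the symmetric strain rate; the traction is the
    tangential projection tau = sigma.n - (n.sigma.n) n, so tau.n = 0.
    Returns ``(tau, |tau|)`` in Pa.
    """
    grad = np.asarray(grad, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    eps = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    sigma = 2.0 * mu * eps
    t = np.einsum("...ij,...j->...i", sigma, n)
    tn = np.einsum("...i,...i->...", t, n)
    tau = t - tn[..., None] * n
    return tau, np.linalg.norm(tau, axis=-1)


def wall_shear_field(u, domain: VoxelDomain, mu: float, offset: int = 2,
                     extrapolate: bool = True):
    """|tau| (Pa) per wall-adjacent node; invalid samples are NaN.

    The gradient is formed on a shell ``offset`` nodes inside the fluid,
    clear of the staircase layer.  With ``extrapolate`` (default) the
    traction is sampled on two shells (``offset`` and ``offset + 1``) and
    extrapolated linearly along the normal to the wall itself, which removes
    the O(offset/R) bias of off-wall sampling in shear flows.
    """
    s1, grad, valid = velocity_gradient_offwall(u, domain, offset)
    _, mag = wss_traction(grad, domain.wall_normals, mu)
    if extrapolate:
        s2, grad2, valid2 = velocity_gradient_offwall(u, domain, offset + 1)
        _, mag2 = wss_traction(grad2, domain.wall_normals, mu)
        both = valid & valid2
        n = domain.wall_normals
        delta = domain.wall_dist if domain.wall_dist is not None \
            else np.full(len(n), 0.5)
        # true normal distances of the two sampling shells from the surface
        d1 = ((domain.wall_nodes - s1) * n).sum(-1) + delta
        d2 = ((domain.wall_nodes - s2) * n).sum(-1) + delta
        sep = np.where(np.abs(d2 - d1) > 1e-9, d2 - d1, 1.0)
        mag = np.where(both, mag + (mag - mag2) * d1 / sep, mag)
    mag = np.where(valid, mag, np.nan)
    return mag


def tawss(tau_series, times, T_cycle: float):
    """Time-averaged WSS over the final full cycle (trapezoid rule).

    ``tau_series``: |tau| sampled at ``times`` (first axis time); raises if
    the series does not span at least one full cycle.
    """
    times = np.asarray(times, dtype=np.float64)
    tau_series = np.asarray(tau_series, dtype=np.float64)
    span = times[-1] - times[0]
    if span < T_cycle * (1.0 - 1e-9):
        raise IncompleteCycleError(
            f"series spans {span:.4g} s < one cycle ({T_cycle:.4g} s)")
    t0 = times[-1] - T_cycle
    sel = times >= t0 - 1e-12
    t = times[sel]
    y = tau_series[sel]
    return np.trapezoid(y, t, axis=0) / (t[-1] - t[0])


def tke(snapshots, rho: float):
    """Turbulent kinetic energy from phase-resolved velocity snapshots.

    ``snapshots``: shape (n_cycles, n_phases, ..., 3), the velocity at
    matching phases of successive cycles.  The phase-ensemble mean is
    removed; TKE per point = mean over phases of 1/2 rho (u'^2+v'^2+w'^2)
    (N/m^2).  Returns ``(tke_field, peak)``.
    """
    snaps = np.asarray(snapshots, dtype=np.float64)
    if snaps.ndim < 3 or snaps.shape[-1] != 3:
        raise MismatchedPhaseGridError(
            "snapshots must be (n_cycles, n_phases, ..., 3)")
    if snaps.shape[0] < 2:
        raise MismatchedPhaseGridError("need at least 2 cycles")
    mean = snaps.mean(axis=0, keepdims=True)
    fluct = snaps - mean
    # variance over cycles, summed over components, averaged over phases
    k = 0.5 * rho * (fluct**2).sum(axis=-1).mean(axis=(0, 1))
    peak = float(np.nanmax(k)) if k.size else 0.0
    return k, peak


def reynolds_number(U_peak: float, D: float, nu: float) -> float:
    """Re = U D / nu with D the local diameter at the sampling station."""
    if min(D, nu) <= 0 or U_peak < 0:
        raise ValueError("require U_peak >= 0, D > 0, nu > 0")
    return U_peak * D / nu


def pressure_drop(p, fluid_mask, z_prox: int, z_dist: int, axis: int = 2):
    """Area-averaged pressure difference between two stations, in mmHg.

    ``p``: pressure field (Pa), optionally with a leading time axis;
    ``fluid_mask``: spatial mask for the area averages.
    """
    p = np.asarray(p, dtype=np.float64)
    spatial = p.ndim - 3
    mask = np.asarray(fluid_mask, dtype=bool)

    def plane_mean(z):
        sl = [slice(None)] * 3
        sl[axis] = z
        msk = mask[tuple(sl)]
        sub = p[(Ellipsis,) + tuple(sl)]
        return sub[..., msk].mean(axis=-1) if spatial == 0 \
            else sub[..., msk].mean(axis=-1)

    dp = plane_mean(z_prox) - plane_mean(z_dist)
    return pa_to_mmhg(dp)


def percent_change(pre, post):
    """Signed percent change 100 (post - pre) / pre."""
    pre = np.asarray(pre, dtype=np.float64)
    if np.any(pre == 0):
        raise ZeroBaselineError("pre-intervention value must be nonzero")
    return float(100.0 * (np.asarray(post, dtype=np.float64) - pre) / pre) \
        if pre.ndim == 0 else 100.0 * (post - pre) / pre


def format_change(pct) -> str:
    """Report text with the magnitude rounded to the nearest integer percent."""
    mag = int(round(abs(pct)))
    word = "decrease" if pct < 0 else ("increase" if pct > 0 else "change")
    return f"{mag}% {word}"
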