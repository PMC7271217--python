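"""Core lattice-Boltzmann operations on D3Q19 population fields.

Population arrays have shape ``(..., 19)`` with the direction index last;
grid fields are ``(nx, ny, nz, 19)``.  These reference implementations are
fully vectorised numpy and are the semantics the compiled solver kernels in
:mod:`coaflow.engine` are checked against.
"""

from __future__ import annotations

import numpy as np

from .stencil import CS2, E, MRTOperator, W


class NonPositiveDensityError(ValueError):
    pass


def equilibrium(rho, u):
    """Second-order Maxwell-Boltzmann equilibrium populations.

    ``rho``: density, shape ``(...)``; ``u``: velocity, shape ``(..., 3)``.
    Returns populations of shape ``(..., 19)`` satisfying sum f = rho and
    sum f e = rho u exactly.
    """
    rho = np.asarray(rho, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    eu = u @ E.T.astype(np.float64)               # (..., 19)
    u2 = np.sum(u * u, axis=-1)[..., None]
    feq = W * rho[..., None] * (
        1.0 + eu / CS2 + eu**2 / (2.0 * CS2**2) - u2 / (2.0 * CS2)
    )
    return feq


def macroscopics(f, check: bool = True):
    """Density, velocity and momentum moments of a population field.

    Returns ``(rho, u, j)`` with ``j = rho*u``.
    """
    f = np.asarray(f, dtype=np.float64)
    rho = f.sum(axis=-1)
    j = f @ E.astype(np.float64)
    if check and np.any(rho <= 0):
        raise NonPositiveDensityError("non-positive density encountered")
    u = j / rho[..., None]
    return rho, u, j


def bgk_collide(f, tau: float):
    """Single-relaxation-time collision: relax toward local equilibrium."""
    if tau <= 0.5:
        raise ValueError("tau must exceed 1/2")
    rho, u, _ = macroscopics(f)
    feq = equilibrium(rho, u)
    return f - (f - feq) / tau


def mrt_collide(f, op: MRTOperator):
    """Multiple-relaxation-time collision in moment space.

    m = M f; the non-conserved moments relax toward their equilibria at the
    operator's rates; conserved moments (mass, momentum) have rate zero and
    are preserved to round-off.
    """
    from .stencil import equilibrium_moments

    f = np.asarray(f, dtype=np.float64)
    rho = f.sum(axis=-1)
    j = f @ E.astype(np.float64)
    m = f @ op.M.T
    meq = equilibrium_moments(rho, j, op.moment_set)
    return f - ((m - meq) * op.s) @ op.Minv.T


def stream(f, flags=None):
    """Advect each population one link along its velocity (periodic wrap).

    Populations that would enter solid nodes are simply carried there; the
    boundary module rewrites the affected fluid-node populations afterwards,
    so solid-node contents are never read back.  ``flags`` is accepted for
    interface symmetry and unused here.
    """
    f = np.asarray(f)
    out = np.empty_like(f)
    for a in range(19):
        out[..., a] = np.roll(f[..., a], shift=tuple(E[a]), axis=(0, 1, 2))
    return out
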