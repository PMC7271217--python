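"""D3Q19 lattice stencil and multiple-relaxation-time (MRT) operator.

The stencil is the classic three-dimensional nineteen-velocity set: one rest
vector, six face links of squared length 1 and twelve edge links of squared
length 2.  The MRT transform matrix ``M`` maps populations onto the
orthogonal moment basis (density, kinetic energy, energy squared, momentum,
energy flux, stress tensor components and third-order "ghost" moments); its
rows are the standard Gram-Schmidt moment polynomials of the velocity set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CS2 = 1.0 / 3.0  # lattice sound speed squared

# Velocity vectors, grouped rest / face / edge.  Ordering pairs each
# direction alpha with its reverse so that opposite[] is easy to read off.
E = np.array(
    [
        (0, 0, 0),
        (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1),
        (1, 1, 0), (-1, 1, 0), (1, -1, 0), (-1, -1, 0),
        (1, 0, 1), (-1, 0, 1), (1, 0, -1), (-1, 0, -1),
        (0, 1, 1), (0, -1, 1), (0, 1, -1), (0, -1, -1),
    ],
    dtype=np.int64,
)

W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)

#: index of the reversed direction for each alpha
OPPOSITE = np.array(
    [np.flatnonzero((E == -e).all(axis=1))[0] for e in E], dtype=np.int64
)


def _moment_matrix() -> np.ndarray:
    """Integer MRT transform matrix from the moment polynomials."""
    ex, ey, ez = E[:, 0], E[:, 1], E[:, 2]
    e2 = ex**2 + ey**2 + ez**2
    rows = [
        np.ones(19, dtype=np.int64),          # rho
        19 * e2 - 30,                          # e (kinetic energy)
        (21 * e2**2 - 53 * e2 + 24) // 2,      # e^2
        ex,                                    # j_x
        (5 * e2 - 9) * ex,                     # q_x (energy flux)
        ey,                                    # j_y
        (5 * e2 - 9) * ey,                     # q_y
        ez,                                    # j_z
        (5 * e2 - 9) * ez,                     # q_z
        3 * ex**2 - e2,                        # 3 p_xx
        (3 * e2 - 5) * (3 * ex**2 - e2),       # 3 pi_xx
        ey**2 - ez**2,                         # p_ww
        (3 * e2 - 5) * (ey**2 - ez**2),        # pi_ww
        ex * ey,                               # p_xy
        ey * ez,                               # p_yz
        ex * ez,                               # p_xz
        ex * (ey**2 - ez**2),                  # m_x
        ey * (ez**2 - ex**2),                  # m_y
        ez * (ex**2 - ey**2),                  # m_z
    ]
    return np.array(rows, dtype=np.int64)


M = _moment_matrix()
MINV = np.linalg.inv(M.astype(np.float64))

# Indices of conserved moments (density and the three momentum components).
CONSERVED_MOMENTS = (0, 3, 5, 7)
# Moments relaxed at the viscosity-linked rate 1/tau (the five stress modes).
VISCOUS_MOMENTS = (9, 11, 13, 14, 15)


def relaxation_rates(tau: float) -> np.ndarray:
    """19 MRT relaxation rates for a molecular relaxation time ``tau``.

    Conserved moments relax at 0; the five second-order stress moments at the
    viscosity-linked rate ``1/tau``; the remaining kinetic moments use the
    standard stability-optimised constants (1.19, 1.4, 1.2, 1.98).
    """
    s = np.zeros(19)
    s[1] = 1.19
    s[2] = 1.4
    s[4] = s[6] = s[8] = 1.2
    s[10] = s[12] = 1.4
    for i in VISCOUS_MOMENTS:
        s[i] = 1.0 / tau
    s[16] = s[17] = s[18] = 1.98
    return s


def equilibrium_moments(rho: np.ndarray, j: np.ndarray,
                        moment_set: str = "optimized") -> np.ndarray:
    """Equilibrium moment vector m_eq(rho, j), shape ``(..., 19)``.

    ``moment_set`` selects the ghost-moment equilibria:

    - ``"optimized"`` (default): the stability-optimised constants
      (energy-squared coefficient -475/63, zero pi_xx/pi_ww), the set the
      solver runs with;
    - ``"projection"``: m_eq = M . f_eq of the second-order BGK equilibrium
      (energy-squared 3*rho - 11/2 j^2/rho, pi = -1/2 p), for which MRT with
      uniform rates is algebraically identical to BGK.
    """
    rho = np.asarray(rho, dtype=np.float64)
    j = np.asarray(j, dtype=np.float64)
    jx, jy, jz = j[..., 0], j[..., 1], j[..., 2]
    j2 = jx**2 + jy**2 + jz**2
    m = np.zeros(rho.shape + (19,))
    m[..., 0] = rho
    m[..., 1] = -11.0 * rho + 19.0 * j2 / rho
    m[..., 3] = jx
    m[..., 4] = -2.0 / 3.0 * jx
    m[..., 5] = jy
    m[..., 6] = -2.0 / 3.0 * jy
    m[..., 7] = jz
    m[..., 8] = -2.0 / 3.0 * jz
    m[..., 9] = (2.0 * jx**2 - (jy**2 + jz**2)) / rho
    m[..., 11] = (jy**2 - jz**2) / rho
    m[..., 13] = jx * jy / rho
    m[..., 14] = jy * jz / rho
    m[..., 15] = jx * jz / rho
    if moment_set == "optimized":
        m[..., 2] = (-475.0 / 63.0) * j2 / rho
        # m10 = m12 = 0
    elif moment_set == "projection":
        m[..., 2] = 3.0 * rho - 5.5 * j2 / rho
        m[..., 10] = -0.5 * m[..., 9]
        m[..., 12] = -0.5 * m[..., 11]
    else:  # pragma: no cover - guarded by MRTOperator
        raise ValueError(f"unknown moment_set {moment_set!r}")
    return m


@dataclass(frozen=True)
class MRTOperator:
    """MRT collision operator: transform matrix, rates and ghost-moment set."""

    s: np.ndarray
    moment_set: str = "optimized"
    M: np.ndarray = field(default_factory=lambda: M.astype(np.float64))
    Minv: np.ndarray = field(default_factory=lambda: MINV.copy())

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=np.float64)
        if s.shape != (19,):
            raise ValueError("s must have 19 relaxation rates")
        if any(s[i] != 0.0 for i in CONSERVED_MOMENTS):
            raise ValueError("conserved moments (0,3,5,7) must have rate 0")
        if self.moment_set not in ("optimized", "projection"):
            raise ValueError(f"unknown moment_set {self.moment_set!r}")
        object.__setattr__(self, "s", s)

    @classmethod
    def for_tau(cls, tau: float, moment_set: str = "optimized") -> "MRTOperator":
        return cls(s=relaxation_rates(tau), moment_set=moment_set)

    @classmethod
    def uniform(cls, tau: float, moment_set: str = "projection") -> "MRTOperator":
        """All non-conserved rates equal to 1/tau (reduces MRT to BGK when
        used with the projection moment set)."""
        s = np.full(19, 1.0 / tau)
        s[list(CONSERVED_MOMENTS)] = 0.0
        return cls(s=s, moment_set=moment_set)
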