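"""Smagorinsky subgrid-scale closure for the lattice-Boltzmann solver.

The eddy viscosity is recovered locally from the second-order moment of the
non-equilibrium populations, which is proportional to the filtered strain
rate.  It enters the solver as a per-node addition ``tau_turb`` to the
molecular relaxation time, so the total viscosity obeys
``nu_total = (tau - 1/2)/3 = nu_mol + nu_turb`` in lattice units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stencil import CS2, E


@dataclass(frozen=True)
class LESParams:
    """Smagorinsky constant and filter width (= lattice spacing)."""

    Cs: float = 0.1
    dx: float = 1.0
    traceless: bool = False  # project out the trace of the neq stress

    def __post_init__(self) -> None:
        if self.Cs <= 0:
            raise ValueError("Cs must be positive")


# Outer products e_i e_j per direction, shape (19, 3, 3)
_EE = (E[:, :, None] * E[:, None, :]).astype(np.float64)


def noneq_moment(f, f_eq, traceless: bool = False):
    """Frobenius magnitude of the non-equilibrium momentum-flux tensor.

    Pi_bar = sqrt( sum_ij [ sum_a (f_a - feq_a) e_ai e_aj ]^2 ), per node.
    Zero exactly at equilibrium.
    """
    df = np.asarray(f, dtype=np.float64) - np.asarray(f_eq, dtype=np.float64)
    pi = np.einsum("...a,aij->...ij", df, _EE)
    if traceless:
        tr = np.trace(pi, axis1=-2, axis2=-1) / 3.0
        pi = pi - tr[..., None, None] * np.eye(3)
    return np.sqrt(np.sum(pi * pi, axis=(-2, -1)))


def effective_tau(tau_mol: float, Pi_bar, les: LESParams, rho=1.0):
    """Per-node total relaxation time tau_mol + tau_turb.

    tau_turb = 1/2*(sqrt(tau_mol^2 + 18*sqrt(2)*Cs^2*Pi_bar/(rho*cs^4))
               - tau_mol), the standard Smagorinsky-LBM closure in lattice
    units (dx = dt = 1).  Monotone non-decreasing in Pi_bar; equals tau_mol
    exactly in the laminar limit Pi_bar = 0.
    """
    if tau_mol <= 0.5:
        raise ValueError("tau_mol must exceed 1/2")
    Pi_bar = np.asarray(Pi_bar, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    rad = tau_mol**2 + 18.0 * np.sqrt(2.0) * les.Cs**2 * Pi_bar / (rho * CS2**2)
    return tau_mol + 0.5 * (np.sqrt(rad) - tau_mol)


def turbulent_viscosity(tau_mol: float, tau):
    """nu_turb = (tau - tau_mol)/3 in lattice units."""
    return (np.asarray(tau) - tau_mol) / 3.0
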