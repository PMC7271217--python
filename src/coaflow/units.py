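"""Lattice unit system and physical unit conversions.

Lattice units are defined by the grid spacing ``dx`` and time step ``dt``:
one lattice length is ``dx`` metres, one lattice time is ``dt`` seconds, and
lattice density 1 corresponds to the physical fluid density.  Pressure maps
through the lattice equation of state p = cs^2 * rho, so physical pressure is
recovered as ``p_ref + rho_phys*(dx/dt)^2*cs2*(rho_lat - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

MMHG_PA = 133.322
DYNCM2_PA = 0.1  # 1 dyn/cm^2 = 0.1 Pa; 1 Pa = 10 dyn/cm^2
CS2 = 1.0 / 3.0

# Blood properties used throughout: Newtonian, incompressible.
BLOOD_DENSITY = 1050.0          # kg/m^3
BLOOD_DYN_VISCOSITY = 0.0035    # Pa s
BLOOD_KIN_VISCOSITY = BLOOD_DYN_VISCOSITY / BLOOD_DENSITY


class UnstableUnitsError(ValueError):
    """Raised when the chosen dx/dt put the relaxation time outside (0.5, 2)."""


@dataclass(frozen=True)
class LatticeSpec:
    """Grid size and unit conversion for one lattice-Boltzmann run."""

    nx: int
    ny: int
    nz: int
    dx: float           # m
    dt: float           # s
    rho_phys: float = BLOOD_DENSITY     # kg/m^3
    nu_phys: float = BLOOD_KIN_VISCOSITY  # m^2/s
    cs2: float = CS2

    def __post_init__(self) -> None:
        if min(self.dx, self.dt, self.rho_phys, self.nu_phys) <= 0:
            raise ValueError("dx, dt, rho_phys and nu_phys must be positive")
        tau = self.tau_mol
        if not 0.5 < tau < 2.0:
            raise UnstableUnitsError(
                f"tau_mol = {tau:.4g} outside the stable interval (0.5, 2); "
                "adjust dx or dt"
            )

    # -- lattice-side quantities -------------------------------------------
    @property
    def nu_lat(self) -> float:
        """Kinematic viscosity in lattice units."""
        return self.nu_phys * self.dt / self.dx**2

    @property
    def tau_mol(self) -> float:
        """Molecular relaxation time, 3*nu_lat + 1/2."""
        return 3.0 * self.nu_lat + 0.5

    @property
    def u_scale(self) -> float:
        """Velocity scale dx/dt (m/s per lattice velocity unit)."""
        return self.dx / self.dt

    # -- conversions -------------------------------------------------------
    def u_to_lat(self, u_phys):
        return u_phys / self.u_scale

    def u_to_phys(self, u_lat):
        return u_lat * self.u_scale

    def q_to_lat(self, q_phys):
        """Volumetric flow rate m^3/s -> lattice units."""
        return q_phys * self.dt / self.dx**3

    def p_to_phys(self, rho_lat, p_ref: float = 0.0):
        """Lattice density -> physical pressure (Pa) about ``p_ref``."""
        return p_ref + self.rho_phys * self.u_scale**2 * self.cs2 * (rho_lat - 1.0)

    def p_to_lat_rho(self, p_phys, p_ref: float = 0.0):
        """Physical pressure (Pa) -> lattice density."""
        return 1.0 + (p_phys - p_ref) / (self.rho_phys * self.u_scale**2 * self.cs2)


def make_lattice_units(dx: float, dt: float, nu_phys: float,
                       rho_phys: float, nx: int = 1, ny: int = 1,
                       nz: int = 1) -> LatticeSpec:
    """Build a :class:`LatticeSpec`, rejecting unstable dx/dt combinations."""
    return LatticeSpec(nx=nx, ny=ny, nz=nz, dx=dx, dt=dt,
                       rho_phys=rho_phys, nu_phys=nu_phys)


def mmhg_to_pa(p):
    return p * MMHG_PA


def pa_to_mmhg(p):
    return p / MMHG_PA


def pa_to_dyncm2(p):
    return p / DYNCM2_PA


def dyncm2_to_pa(p):
    return p * DYNCM2_PA
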