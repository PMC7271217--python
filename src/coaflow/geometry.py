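"""Voxel domains: synthetic aorta-like tubes and surface-mesh voxelization.

The lattice is node-centred with 0-based indexing: node ``(i, j, k)`` sits at
physical position ``(i, j, k) * dx`` (plus an optional origin for meshes).
A link from a fluid node toward a solid neighbour is classified as *cut*; its
normalized wall distance ``q = |AC|/|AB|`` in ``(0, 1]`` is measured from the
fluid node A to the surface point C along the link AB.  Fixture tubes record
``q`` analytically from the exact surface; voxelized meshes record it from
segment-triangle intersections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import jv

from .stencil import E
from .units import LatticeSpec

SOLID, FLUID, INLET, OUTLET = 0, 1, 2, 3
BRANCH_OUTLET_BASE = 4  # branch k gets flag BRANCH_OUTLET_BASE + k


class ResolutionError(ValueError):
    """Raised when a fixture radius is too small for the lattice spacing."""


class NonWatertightMeshError(ValueError):
    pass


@dataclass
class VoxelDomain:
    """Flag field plus per-link wall distances for one geometry."""

    flags: np.ndarray                 # (nx, ny, nz) uint8
    spec: LatticeSpec
    link_node: np.ndarray             # (nL, 3) int, fluid node of each cut link
    link_dir: np.ndarray              # (nL,) int, direction alpha into the wall
    link_q: np.ndarray                # (nL,) float in (0, 1]
    wall_nodes: np.ndarray            # (m, 3) int, wall-adjacent fluid nodes
    wall_normals: np.ndarray          # (m, 3) float, outward unit normals
    wall_dist: np.ndarray = None      # (m,) float, node-to-surface distance
    #                                   along the normal (voxel units)
    # geometric metadata used by inlet/outlet boundary conditions
    axis: int = 2
    center: tuple = (0.0, 0.0)        # tube axis position in voxel units
    inlet_radius_vox: float = 0.0
    radius_profile: Optional[Callable] = field(default=None, repr=False)

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.flags != SOLID

    @property
    def n_fluid(self) -> int:
        return int(np.count_nonzero(self.fluid_mask))

    def patch_mask(self, flag: int) -> np.ndarray:
        return self.flags == flag


def _finalize_tube(inside, rvox_of_z, spec, cx, cy, r_inlet):
    """Build flags, analytic cut links and normals for an axisymmetric tube.

    ``inside(i, j, k)`` -> bool arrays; ``rvox_of_z(z)`` gives the local tube
    radius in voxels (vectorised), used for root-finding link cuts and
    normals.
    """
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    flags = np.where(inside(ii, jj, kk), FLUID, SOLID).astype(np.uint8)
    flags[:, :, 0][flags[:, :, 0] == FLUID] = INLET
    flags[:, :, -1][flags[:, :, -1] == FLUID] = OUTLET

    fluid = flags != SOLID
    # cut links: fluid node with solid neighbour inside the box
    link_node, link_dir, link_q = [], [], []
    wall_set = {}
    fi, fj, fk = np.nonzero(fluid)
    pos = np.stack([fi, fj, fk], axis=1)
    for a in range(1, 19):
        nbr = pos + E[a]
        ok = ((nbr >= 0) & (nbr < [nx, ny, nz])).all(axis=1)
        # neighbours beyond z ends are inlet/outlet planes, not walls
        idx = np.nonzero(ok)[0]
        nb = nbr[idx]
        solid = ~fluid[nb[:, 0], nb[:, 1], nb[:, 2]]
        for w in idx[solid]:
            p = pos[w]
            q = _tube_link_q(p, E[a], cx, cy, rvox_of_z)
            link_node.append(p)
            link_dir.append(a)
            link_q.append(q)
            wall_set[tuple(p)] = True
    link_node = np.array(link_node, dtype=np.int64).reshape(-1, 3)
    link_dir = np.array(link_dir, dtype=np.int64)
    link_q = np.array(link_q, dtype=np.float64)

    wall_nodes = np.array(sorted(wall_set), dtype=np.int64).reshape(-1, 3)
    wall_normals = _tube_normals(wall_nodes, cx, cy, rvox_of_z)
    wall_dist = _tube_wall_distance(wall_nodes, wall_normals, cx, cy,
                                    rvox_of_z)

    return VoxelDomain(
        flags=flags, spec=spec, link_node=link_node, link_dir=link_dir,
        link_q=link_q, wall_nodes=wall_nodes, wall_normals=wall_normals,
        wall_dist=wall_dist, axis=2, center=(cx, cy), inlet_radius_vox=r_inlet,
        radius_profile=rvox_of_z,
    )


def _tube_wall_distance(nodes, normals, cx, cy, rvox_of_z):
    """Distance from each wall-adjacent node to the surface along its
    outward normal (voxel units), by bisection on r - R(z)."""
    m = len(nodes)
    out = np.zeros(m)
    for i in range(m):
        px, py, pz = nodes[i, 0] - cx, nodes[i, 1] - cy, float(nodes[i, 2])
        nx_, ny_, nz_ = normals[i]

        def g(t):
            return np.hypot(px + t * nx_, py + t * ny_) \
                - rvox_of_z(pz + t * nz_)

        lo, hi = 0.0, 2.0
        if g(lo) >= 0:
            out[i] = 0.0
            continue
        while g(hi) < 0 and hi < 8.0:
            hi *= 2.0
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi)
    return out


def _tube_link_q(p, e, cx, cy, rvox_of_z):
    """Normalized distance along link p -> p+e to the surface r = R(z)."""
    px, py, pz = float(p[0]) - cx, float(p[1]) - cy, float(p[2])
    ex, ey, ez = float(e[0]), float(e[1]), float(e[2])

    def g(t):
        r = np.hypot(px + t * ex, py + t * ey)
        return r - rvox_of_z(pz + t * ez)

    # analytic quadratic when the radius is locally constant along the link
    if ez == 0.0 or rvox_of_z(pz) == rvox_of_z(pz + ez):
        R = rvox_of_z(pz)
        a = ex * ex + ey * ey
        b = 2.0 * (px * ex + py * ey)
        c = px * px + py * py - R * R
        disc = b * b - 4.0 * a * c
        if a > 0 and disc >= 0:
            t = (-b + np.sqrt(disc)) / (2.0 * a)
            if 0.0 < t <= 1.0:
                return t
    # general case: bisection (g(0) < 0 fluid side, g(1) >= 0 solid side)
    lo, hi = 0.0, 1.0
    if g(lo) >= 0 or g(hi) < 0:
        return 1.0  # degenerate (grazing) link: treat wall at the neighbour
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return max(0.5 * (lo + hi), 1e-9)


def _tube_normals(nodes, cx, cy, rvox_of_z, h: float = 1e-4):
    """Outward unit normals of the surface r = R(z) at wall-adjacent nodes."""
    if len(nodes) == 0:
        return np.zeros((0, 3))
    x = nodes[:, 0] - cx
    y = nodes[:, 1] - cy
    z = nodes[:, 2].astype(np.float64)
    r = np.hypot(x, y)
    r = np.where(r < 1e-12, 1e-12, r)
    dRdz = np.array([(rvox_of_z(zi + h) - rvox_of_z(zi - h)) / (2 * h)
                     for zi in z])
    n = np.stack([x / r, y / r, -dRdz], axis=1)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def make_straight_tube(R0: float, L: float, spec: LatticeSpec,
                       margin: int = 2) -> VoxelDomain:
    """Circular duct of radius ``R0`` and length ``L`` aligned with z.

    The returned domain carries an adjusted :class:`LatticeSpec` whose grid
    dimensions enclose the tube with ``margin`` solid voxels laterally.
    """
    if R0 < 8 * spec.dx:
        raise ResolutionError(f"R0 = {R0} m under-resolved: need >= 8 dx")
    rvox = R0 / spec.dx
    n_lat = int(np.ceil(2 * rvox)) + 1 + 2 * margin
    nz = int(round(L / spec.dx)) + 1
    spec = dataclasses.replace(spec, nx=n_lat, ny=n_lat, nz=nz)
    c = (n_lat - 1) / 2.0

    def rv(z):
        return rvox + 0.0 * np.asarray(z, dtype=np.float64)

    def inside(i, j, k):
        return (i - c) ** 2 + (j - c) ** 2 < rvox**2

    return _finalize_tube(inside, rv, spec, c, c, rvox)


@dataclass(frozen=True)
class StenosisShape:
    """Axisymmetric cosine-taper constriction of a straight tube."""

    L: float        # tube length (m)
    R0: float       # unobstructed radius (m)
    R_throat: float  # throat radius (m)
    z0: float       # throat centre (m)
    w: float        # constriction half-length (m)

    def __post_init__(self):
        if not 0 < self.R_throat <= self.R0:
            raise ValueError("need 0 < R_throat <= R0")

    def radius(self, z):
        """R(z) = R0 - (R0 - R_throat) * (1 + cos(pi (z - z0)/w)) / 2."""
        z = np.asarray(z, dtype=np.float64)
        taper = np.where(
            np.abs(z - self.z0) <= self.w,
            0.5 * (1.0 + np.cos(np.pi * (z - self.z0) / self.w)),
            0.0,
        )
        return self.R0 - (self.R0 - self.R_throat) * taper

    @property
    def throat_area(self):
        return np.pi * self.R_throat**2


def make_coarctation_tube(shape: StenosisShape, spec: LatticeSpec,
                          margin: int = 2) -> VoxelDomain:
    """Voxelized coarctation fixture: straight tube with a cosine throat."""
    if shape.R_throat < 5 * spec.dx:
        raise ResolutionError("throat under-resolved: need R_throat >= 5 dx")
    if shape.R0 < 8 * spec.dx:
        raise ResolutionError("R0 under-resolved: need >= 8 dx")
    rvox0 = shape.R0 / spec.dx
    n_lat = int(np.ceil(2 * rvox0)) + 1 + 2 * margin
    nz = int(round(shape.L / spec.dx)) + 1
    spec = dataclasses.replace(spec, nx=n_lat, ny=n_lat, nz=nz)
    c = (n_lat - 1) / 2.0
    dx = spec.dx

    def rv(z):
        return shape.radius(np.asarray(z, dtype=np.float64) * dx) / dx

    def inside(i, j, k):
        return (i - c) ** 2 + (j - c) ** 2 < rv(k) ** 2

    return _finalize_tube(inside, rv, spec, c, c, rvox0)


def _moller_trumbore(origins, dirs, v0, v1, v2, eps=1e-12):
    """Ray-triangle intersection parameters for one triangle vs many rays.

    Returns ``t`` (np.inf where missed) such that the hit point is
    ``origin + t * dir``.
    """
    e1 = v1 - v0
    e2 = v2 - v0
    p = np.cross(dirs, e2)
    det = p @ e1
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origins - v0
    u = (s * p).sum(-1) * inv
    qv = np.cross(s, e1)
    v = (dirs * qv).sum(-1) * inv
    t = (qv @ e2) * inv
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t > eps)
    return np.where(hit, t, np.inf)


def _inside_by_parity(verts, faces, pts):
    """Ray-parity containment: odd number of crossings along +x."""
    dirs = np.zeros_like(pts)
    dirs[:, 0] = 1.0
    # tiny direction jitter avoids edge-grazing degeneracies
    dirs[:, 1] = 1e-4
    dirs[:, 2] = 2.31e-4
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    count = np.zeros(len(pts), dtype=np.int64)
    for f in faces:
        t = _moller_trumbore(pts, dirs, verts[f[0]], verts[f[1]], verts[f[2]])
        count += np.isfinite(t)
    return (count % 2) == 1


def _segment_hits(verts, faces, normals, origins, dirs):
    """Smallest intersection parameter t in (0, 1] per segment, plus the
    normal of the triangle hit; t = inf where no hit."""
    best_t = np.full(len(origins), np.inf)
    best_n = np.zeros((len(origins), 3))
    for fi, f in enumerate(faces):
        t = _moller_trumbore(origins, dirs, verts[f[0]], verts[f[1]],
                             verts[f[2]])
        better = t < best_t
        best_t = np.where(better, t, best_t)
        best_n[better] = normals[fi]
    return best_t, best_n


def voxelize_surface(mesh, spec: LatticeSpec, origin=(0.0, 0.0, 0.0),
                     inlet_axis: int = 2) -> VoxelDomain:
    """Voxelize a watertight triangulated surface onto the lattice.

    Inside/outside classification uses ray-parity containment; ``q`` for each
    cut link comes from exact segment-triangle intersection
    (Moller-Trumbore).  Fluid patches touching the low/high face of
    ``inlet_axis`` become inlet/outlet.
    """
    import trimesh

    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.Trimesh(vertices=mesh[0], faces=mesh[1])
    if not mesh.is_watertight:
        raise NonWatertightMeshError("surface mesh must be watertight")
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    fnormals = np.asarray(mesh.face_normals, dtype=np.float64)

    nx, ny, nz = spec.nx, spec.ny, spec.nz
    origin = np.asarray(origin, dtype=np.float64)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spec.dx + origin
    inside = _inside_by_parity(verts, faces, pts).reshape(nx, ny, nz)
    flags = np.where(inside, FLUID, SOLID).astype(np.uint8)
    sl = [slice(None)] * 3
    for end, val in ((0, INLET), (-1, OUTLET)):
        sl_ = list(sl)
        sl_[inlet_axis] = end
        face = flags[tuple(sl_)]
        face[face == FLUID] = val
        flags[tuple(sl_)] = face

    fluid = flags != SOLID
    fi, fj, fk = np.nonzero(fluid)
    pos = np.stack([fi, fj, fk], axis=1)
    link_node, link_dir = [], []
    for a in range(1, 19):
        nbr = pos + E[a]
        ok = ((nbr >= 0) & (nbr < [nx, ny, nz])).all(axis=1)
        idx = np.nonzero(ok)[0]
        nb = nbr[idx]
        solid = ~fluid[nb[:, 0], nb[:, 1], nb[:, 2]]
        for w in idx[solid]:
            link_node.append(pos[w])
            link_dir.append(a)
    link_node = np.array(link_node, dtype=np.int64).reshape(-1, 3)
    link_dir = np.array(link_dir, dtype=np.int64)

    # exact segment-triangle intersection per cut link
    link_q = np.full(len(link_dir), 0.5)
    hit_normals = np.zeros((len(link_dir), 3))
    if len(link_dir):
        origins = link_node * spec.dx + origin
        dirs = E[link_dir].astype(np.float64) * spec.dx
        t, hit_normals = _segment_hits(verts, faces, fnormals, origins, dirs)
        got = np.isfinite(t) & (t <= 1.0)
        link_q[got] = t[got]
    link_q = np.clip(link_q, 1e-9, 1.0)

    # wall-adjacent nodes; normal = average of the hit-triangle normals of
    # the node's cut links (oriented outward, away from the fluid)
    wall_nodes, inverse = np.unique(link_node, axis=0, return_inverse=True)
    wall_normals = np.zeros((len(wall_nodes), 3))
    np.add.at(wall_normals, inverse, hit_normals)
    norms = np.linalg.norm(wall_normals, axis=1, keepdims=True)
    wall_normals = np.divide(wall_normals, norms,
                             out=np.zeros_like(wall_normals),
                             where=norms > 1e-12)
    # node-to-surface distance along the normal, by ray casting
    wall_dist = np.full(len(wall_nodes), 0.5)
    if len(wall_nodes):
        worigins = wall_nodes * spec.dx + origin
        wdirs = wall_normals * (4.0 * spec.dx)
        t, _ = _segment_hits(verts, faces, fnormals, worigins, wdirs)
        got = np.isfinite(t)
        wall_dist[got] = t[got] * 4.0   # back to voxel units

    return VoxelDomain(
        flags=flags, spec=spec, link_node=link_node, link_dir=link_dir,
        link_q=link_q, wall_nodes=wall_nodes, wall_normals=wall_normals,
        wall_dist=wall_dist, axis=inlet_axis,
    )


def make_inclined_channel(H: float, theta: float, L: float,
                          spec: LatticeSpec, ny: int = 4,
                          margin: int = 2) -> VoxelDomain:
    """Plane channel of gap ``H`` whose walls are tilted by ``theta`` in the
    x-z plane (periodic in y).

    The walls are genuinely off-lattice for ``theta != 0``: the exact wall
    distance q varies continuously along the channel, which is the fixture
    used to compare interpolated bounce-back against the staircase rule.
    """
    nz = int(round(L / spec.dx)) + 1
    h_vox = H / spec.dx
    span = h_vox / np.cos(theta) + abs(np.tan(theta)) * nz
    nx = int(np.ceil(span)) + 1 + 2 * margin
    spec = dataclasses.replace(spec, nx=nx, ny=ny, nz=nz)
    nhat = np.array([np.cos(theta), 0.0, -np.sin(theta)])
    c0 = np.array([(nx - 1) / 2.0, 0.0, (nz - 1) / 2.0])

    def sdist(i, j, k):
        return (i - c0[0]) * nhat[0] + (k - c0[2]) * nhat[2]

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    d = sdist(ii, jj, kk)
    flags = np.where(np.abs(d) < h_vox / 2.0, FLUID, SOLID).astype(np.uint8)
    flags[:, :, 0][flags[:, :, 0] == FLUID] = INLET
    flags[:, :, -1][flags[:, :, -1] == FLUID] = OUTLET

    fluid = flags != SOLID
    fi, fj, fk = np.nonzero(fluid)
    pos = np.stack([fi, fj, fk], axis=1)
    link_node, link_dir, link_q = [], [], []
    wall_set = {}
    for a in range(1, 19):
        nbr = pos + E[a]
        ok = (nbr[:, 0] >= 0) & (nbr[:, 0] < nx) & \
            (nbr[:, 2] >= 0) & (nbr[:, 2] < nz)
        nbr[:, 1] %= ny
        idx = np.nonzero(ok)[0]
        nb = nbr[idx]
        solid = ~fluid[nb[:, 0], nb[:, 1], nb[:, 2]]
        dn = E[a, 0] * nhat[0] + E[a, 2] * nhat[2]
        for w in idx[solid]:
            p = pos[w]
            dp = sdist(p[0], p[1], p[2])
            target = h_vox / 2.0 if dn > 0 else -h_vox / 2.0
            t = (target - dp) / dn if dn != 0 else 1.0
            link_node.append(p)
            link_dir.append(a)
            link_q.append(min(max(t, 1e-9), 1.0))
            wall_set[tuple(p)] = True
    link_node = np.array(link_node, dtype=np.int64).reshape(-1, 3)
    link_dir = np.array(link_dir, dtype=np.int64)
    link_q = np.array(link_q, dtype=np.float64)
    wall_nodes = np.array(sorted(wall_set), dtype=np.int64).reshape(-1, 3)
    dwall = sdist(wall_nodes[:, 0], wall_nodes[:, 1], wall_nodes[:, 2])
    wall_normals = np.sign(dwall)[:, None] * nhat[None, :]
    wall_dist = h_vox / 2.0 - np.abs(dwall)

    dom = VoxelDomain(
        flags=flags, spec=spec, link_node=link_node, link_dir=link_dir,
        link_q=link_q, wall_nodes=wall_nodes, wall_normals=wall_normals,
        wall_dist=wall_dist, axis=2, center=(c0[0], 0.0),
        inlet_radius_vox=h_vox / 2.0,
    )
    dom.signed_distance = sdist
    dom.gap_vox = h_vox
    dom.theta = theta
    return dom


# ---------------------------------------------------------------------------
# analytic oracles


def analytic_poiseuille(R0: float, Q: float, nu: float, rho: float):
    """Steady laminar pipe flow: profile u_z(r) and pressure gradient.

    u_z(r) = 2 Q / (pi R0^2) * (1 - (r/R0)^2);  dp/dz = -8 mu Q / (pi R0^4).
    """
    mu = rho * nu
    u_mean = Q / (np.pi * R0**2)

    def profile(r):
        r = np.asarray(r, dtype=np.float64)
        return np.where(r <= R0, 2.0 * u_mean * (1.0 - (r / R0) ** 2), 0.0)

    dpdz = -8.0 * mu * Q / (np.pi * R0**4)
    return profile, dpdz


def analytic_womersley(R0: float, K: float, freq: float, nu: float,
                       rho: float):
    """Oscillatory pipe flow driven by -dp/dz = K cos(omega t).

    Returns ``u(r, t)`` evaluated from the classical Bessel-function series
    (single harmonic); reduces to the Poiseuille parabola as ``freq -> 0``.
    """
    omega = 2.0 * np.pi * freq
    if omega == 0.0:
        profile, _ = analytic_poiseuille(
            R0, K * np.pi * R0**4 / (8.0 * rho * nu), nu, rho)

        def u0(r, t):
            return profile(r)

        return u0
    alpha = R0 * np.sqrt(omega / nu)      # Womersley number
    lam = 1j ** 1.5 * alpha

    def u(r, t):
        r = np.asarray(r, dtype=np.float64)
        shape = 1.0 - jv(0, lam * r / R0) / jv(0, lam)
        phasor = (K / (1j * rho * omega)) * shape
        return np.real(phasor * np.exp(1j * omega * np.asarray(t)))

    u.alpha = alpha
    return u
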