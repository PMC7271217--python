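"""Synthetic tube fixtures, mesh voxelization and analytic flow oracles."""

import numpy as np
import pytest

from coaflow.geometry import (FLUID, INLET, OUTLET, SOLID,
                              NonWatertightMeshError, ResolutionError,
                              StenosisShape, analytic_poiseuille,
                              analytic_womersley, make_coarctation_tube,
                              make_straight_tube, voxelize_surface)
from coaflow.units import LatticeSpec


def spec_dx(dx):
    return LatticeSpec(nx=1, ny=1, nz=1, dx=dx, dt=1e-3, rho_phys=1050.0,
                       nu_phys=5e-5)


@pytest.fixture(scope="module")
def tube10():
    dx = 1e-3
    return make_straight_tube(10 * dx, 30 * dx, spec_dx(dx)), dx


class TestStraightTube:
    def test_cross_section_node_count(self, tube10):
        dom, dx = tube10
        area = np.count_nonzero(dom.fluid_mask[:, :, 5])
        assert area == pytest.approx(np.pi * 10**2, rel=0.05)

    def test_axis_nodes_have_no_cut_links(self, tube10):
        dom, dx = tube10
        c = (dom.flags.shape[0] - 1) // 2
        on_axis = (dom.link_node[:, 0] == c) & (dom.link_node[:, 1] == c)
        assert not on_axis.any()
        assert dom.flags[c, c, 10] == FLUID

    def test_q_values_in_unit_interval(self, tube10):
        dom, _ = tube10
        assert np.all(dom.link_q > 0) and np.all(dom.link_q <= 1.0)

    def test_radial_link_q_analytic(self):
        # node at radius 9.5 dx, radial link, R0 = 10 dx -> q = 0.5
        from coaflow.geometry import _tube_link_q

        q = _tube_link_q(np.array([9, 0, 5]), np.array([1, 0, 0]),
                         -0.5, 0.0, lambda z: 10.0)
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_under_resolved_rejected(self):
        with pytest.raises(ResolutionError):
            make_straight_tube(5e-3, 3e-2, spec_dx(1e-3))

    def test_inlet_outlet_flags(self, tube10):
        dom, _ = tube10
        assert (dom.flags[:, :, 0][dom.flags[:, :, 0] != SOLID]
                == INLET).all()
        assert (dom.flags[:, :, -1][dom.flags[:, :, -1] != SOLID]
                == OUTLET).all()


class TestCoarctationTube:
    def test_degenerate_stenosis_matches_straight(self):
        dx = 1e-3
        shape = StenosisShape(L=0.03, R0=0.01, R_throat=0.01, z0=0.015,
                              w=0.008)
        a = make_coarctation_tube(shape, spec_dx(dx))
        b = make_straight_tube(0.01, 0.03, spec_dx(dx))
        assert np.array_equal(a.flags, b.flags)

    def test_cosine_taper_endpoints(self):
        shape = StenosisShape(L=0.1, R0=0.012, R_throat=0.006, z0=0.05,
                              w=0.02)
        assert shape.radius(0.05) == pytest.approx(0.006)
        assert shape.radius(0.03) == pytest.approx(0.012)
        assert shape.radius(0.07) == pytest.approx(0.012)
        assert shape.radius(0.0) == pytest.approx(0.012)

    def test_75pct_area_stenosis_voxel_ratio(self):
        dx = 5e-4
        shape = StenosisShape(L=0.05, R0=0.012, R_throat=0.006, z0=0.025,
                              w=0.012)
        dom = make_coarctation_tube(shape, spec_dx(dx))
        zt = int(round(0.025 / dx))
        throat = np.count_nonzero(dom.fluid_mask[:, :, zt])
        inlet = np.count_nonzero(dom.fluid_mask[:, :, 2])
        assert throat / inlet == pytest.approx(0.25, abs=0.02)

    def test_throat_under_resolved_rejected(self):
        shape = StenosisShape(L=0.05, R0=0.012, R_throat=0.003, z0=0.025,
                              w=0.012)
        with pytest.raises(ResolutionError):
            make_coarctation_tube(shape, spec_dx(1e-3))


class TestVoxelizeSurface:
    @pytest.fixture(scope="class")
    def cylinder_mesh(self):
        trimesh = pytest.importorskip("trimesh")
        dx = 1e-3
        ref = make_straight_tube(10 * dx, 20 * dx, spec_dx(dx))
        c = (ref.flags.shape[0] - 1) / 2.0 * dx
        L = (ref.flags.shape[2] - 1) * dx
        mesh = trimesh.creation.cylinder(radius=10 * dx, height=3 * L,
                                         sections=256)
        mesh.apply_translation([c, c, L / 2.0])
        return mesh, ref, dx

    def test_matches_analytic_tube_flags(self, cylinder_mesh):
        mesh, ref, dx = cylinder_mesh
        dom = voxelize_surface(mesh, ref.spec)
        # interior agreement (mesh is a closed cylinder; compare fluid vs
        # solid classification away from the z ends)
        agree = (dom.fluid_mask == ref.fluid_mask)[:, :, 1:-1]
        assert agree.mean() >= 0.99

    def test_translation_equivariance(self, cylinder_mesh):
        mesh, ref, dx = cylinder_mesh
        dom0 = voxelize_surface(mesh, ref.spec)
        moved = mesh.copy()
        moved.apply_translation([3 * dx, -2 * dx, 0.0])
        dom1 = voxelize_surface(moved, ref.spec,
                                origin=(3 * dx, -2 * dx, 0.0))
        assert np.array_equal(dom0.flags, dom1.flags)

    def test_open_mesh_rejected(self, cylinder_mesh):
        trimesh = pytest.importorskip("trimesh")
        mesh, ref, _ = cylinder_mesh
        open_mesh = trimesh.Trimesh(vertices=mesh.vertices,
                                    faces=mesh.faces[:-10])
        with pytest.raises(NonWatertightMeshError):
            voxelize_surface(open_mesh, ref.spec)


class TestAnalyticPoiseuille:
    def test_centerline_is_twice_mean(self):
        prof, _ = analytic_poiseuille(0.01, 1e-5, 3.33e-6, 1050.0)
        u_mean = 1e-5 / (np.pi * 0.01**2)
        assert prof(0.0) == pytest.approx(2 * u_mean, rel=1e-12)
        assert u_mean == pytest.approx(0.0318, rel=1e-2)

    def test_no_slip_at_wall(self):
        prof, _ = analytic_poiseuille(0.01, 1e-5, 3.33e-6, 1050.0)
        assert prof(0.01) == pytest.approx(0.0, abs=1e-15)

    def test_pressure_gradient(self):
        _, dpdz = analytic_poiseuille(0.01, 1e-5, 3.33e-6, 1050.0)
        mu = 1050.0 * 3.33e-6
        assert dpdz == pytest.approx(-8 * mu * 1e-5 / (np.pi * 0.01**4))


class TestAnalyticWomersley:
    def test_low_frequency_limit_is_poiseuille(self):
        R0, nu, rho = 0.01, 3.33e-6, 1050.0
        K = 100.0
        u = analytic_womersley(R0, K, freq=1e-4, nu=nu, rho=rho)
        Q = K * np.pi * R0**4 / (8 * rho * nu)
        prof, _ = analytic_poiseuille(R0, Q, nu, rho)
        r = np.linspace(0, R0, 30)
        # at the phase of peak pressure gradient
        assert np.allclose(u(r, 0.0), prof(r), rtol=0.01, atol=1e-9)

    def test_high_womersley_profile_is_flattened(self):
        R0, rho = 0.01, 1050.0
        freq = 1.0
        # alpha = 10 -> nu = R0^2 * omega / alpha^2
        nu = R0**2 * 2 * np.pi * freq / 100.0
        u = analytic_womersley(R0, 1000.0, freq, nu, rho)
        assert u.alpha == pytest.approx(10.0, rel=1e-12)
        r = np.linspace(0, R0 * 0.999, 200)
        t = np.linspace(0, 1.0, 50)
        U = np.array([u(r, tk) for tk in t])
        # amplitude of centerline vs cross-sectional mean (area weighted)
        amp_center = np.abs(U[:, 0]).max()
        w = r / r.sum()
        amp_mean = np.abs(U @ w).max()
        assert amp_center / amp_mean < 2.0

    def test_no_slip_all_phases(self):
        u = analytic_womersley(0.01, 500.0, 1.2, 3.33e-6, 1050.0)
        for t in np.linspace(0, 1 / 1.2, 7):
            assert abs(u(0.01, t)) < 1e-10
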