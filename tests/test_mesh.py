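"""Mesh engine: geometry, timestep, boundary motion, remap."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagosim.errors import ConfigurationError, GeometryError, NumericalError
from phagosim.mesh import (
    AXIS,
    CONTACT,
    FREE,
    REAR,
    Mesh,
    TargetSphere,
    advect_boundary,
    build_initial_mesh,
    correct_volume,
    courant_timestep,
    relayout,
    remap_fields,
    reposition_interior,
)
from phagosim.state import FieldState


class TestBuild:
    def test_target_radius_from_diameter(self, contact_mesh):
        _, target = contact_mesh
        assert target.radius == pytest.approx(1.6)

    def test_zero_contact_angle_gives_empty_patch(self, sphere_mesh):
        mesh, _ = sphere_mesh
        assert np.sum(mesh.seg_tags == CONTACT) == 0

    def test_axis_nodes_pinned_exactly(self, contact_mesh):
        mesh, _ = contact_mesh
        tags = mesh.node_tags()
        assert np.all(mesh.coords[tags == AXIS, 0] == 0.0)

    def test_all_jacobians_positive(self, contact_mesh):
        mesh, _ = contact_mesh
        assert mesh.corner_jacobians().min() > 0.0

    def test_contact_nodes_within_gap_tolerance(self, contact_mesh):
        mesh, target = contact_mesh
        tags = mesh.node_tags()
        gaps = np.abs(target.signed_gap(*mesh.coords[tags == CONTACT].T))
        assert gaps.max() <= target.gap_tol

    def test_boundary_tags_partition_closed_loop(self, contact_mesh):
        mesh, _ = contact_mesh
        assert len(mesh.seg_tags) == mesh.n_perimeter
        assert set(np.unique(mesh.seg_tags)) == {AXIS, CONTACT, FREE, REAR}

    def test_resolution_doubling_volume_change_below_1pct(self):
        m1, _ = build_initial_mesh(4.25, TargetSphere(1.6), 0.25, 1.0)
        m2, _ = build_initial_mesh(4.25, TargetSphere(1.6), 0.25, 2.0)
        v1, v2 = m1.enclosed_volume(), m2.enclosed_volume()
        assert m2.n_elements == pytest.approx(4 * m1.n_elements, rel=0.05)
        assert abs(v2 - v1) / v1 < 0.01

    def test_element_volumes_sum_to_enclosed(self, contact_mesh):
        mesh, _ = contact_mesh
        assert mesh.element_volumes().sum() == pytest.approx(
            mesh.enclosed_volume(), rel=1e-12
        )

    def test_resolution_below_minimum_rejected(self):
        with pytest.raises(ConfigurationError):
            build_initial_mesh(4.25, TargetSphere(1.6), 0.25, 0.5)

    def test_cell_smaller_than_target_rejected(self):
        with pytest.raises(GeometryError):
            build_initial_mesh(1.5, TargetSphere(1.6), 0.25, 1.0)


class TestCourant:
    def test_zero_velocity_gives_dt_max(self, contact_mesh):
        mesh, _ = contact_mesh
        v = np.zeros((mesh.n_nodes, 2))
        assert courant_timestep(mesh, v, 0.5, 2.5) == 2.5

    def test_uniform_speed_matches_min_edge(self, contact_mesh):
        mesh, _ = contact_mesh
        v = np.full((mesh.n_nodes, 2), [0.3, 0.4])   # speed 0.5
        q, x = mesh.quads, mesh.coords
        hmin = min(
            np.linalg.norm(x[q[:, (e + 1) % 4]] - x[q[:, e]], axis=1).min()
            for e in range(4)
        )
        assert courant_timestep(mesh, v, 0.5, 1e9) == pytest.approx(0.5 * hmin / 0.5)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_per_element_minimum(self, contact_mesh, seed):
        mesh, _ = contact_mesh
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 0.2, (mesh.n_nodes, 2))
        dt = courant_timestep(mesh, v, 0.4, 10.0)
        # independent brute-force loop over all elements
        best = 10.0
        for quad in mesh.quads:
            h = min(
                np.linalg.norm(mesh.coords[quad[(e + 1) % 4]] - mesh.coords[quad[e]])
                for e in range(4)
            )
            s = max(np.linalg.norm(v[n]) for n in quad)
            if s > 1e-14:
                best = min(best, 0.4 * h / s)
        assert dt == pytest.approx(best, rel=1e-12)

    def test_nonfinite_velocity_raises(self, contact_mesh):
        mesh, _ = contact_mesh
        v = np.zeros((mesh.n_nodes, 2))
        v[3, 0] = np.nan
        with pytest.raises(NumericalError):
            courant_timestep(mesh, v, 0.4, 1.0)


class TestAdvect:
    def test_zero_velocity_identity(self, contact_mesh):
        mesh, _ = contact_mesh
        out = advect_boundary(mesh, np.zeros((mesh.n_nodes, 2)), 0.5)
        assert np.array_equal(out.coords, mesh.coords)
        assert np.array_equal(out.seg_tags, mesh.seg_tags)

    def test_rear_nodes_pinned_axis_stays_on_axis(self, contact_mesh):
        mesh, _ = contact_mesh
        v = np.full((mesh.n_nodes, 2), [0.05, 0.1])
        out = advect_boundary(mesh, v, 1.0)
        tags = mesh.node_tags()
        assert np.array_equal(out.coords[tags == REAR], mesh.coords[tags == REAR])
        assert np.all(out.coords[tags == AXIS, 0] == 0.0)
        free = tags == FREE
        assert np.allclose(out.coords[free], mesh.coords[free] + [0.05, 0.1])

    def test_boundary_normal_motion_changes_volume_by_flux(self, sphere_mesh):
        mesh, _ = sphere_mesh
        # radial outward velocity on the free membrane: dV/dt = flux integral
        tags = mesh.node_tags()
        v = np.zeros((mesh.n_nodes, 2))
        eps = 1e-4
        free = tags == FREE
        norms = np.linalg.norm(mesh.coords[free], axis=1)
        v[free] = eps * mesh.coords[free] / norms[:, None]
        from phagosim.mesh import volume_gradient

        flux = float(np.sum(volume_gradient(mesh) * v))
        out = advect_boundary(mesh, v, 1.0)
        dv = out.enclosed_volume() - mesh.enclosed_volume()
        assert dv == pytest.approx(flux, rel=0.01)


class TestReposition:
    def test_min_quality_never_decreased(self, contact_mesh):
        mesh, _ = contact_mesh
        q0 = mesh.min_scaled_jacobian()
        out = reposition_interior(mesh)
        assert out.min_scaled_jacobian() >= q0 - 1e-12

    def test_boundary_and_tags_unchanged(self, contact_mesh):
        mesh, _ = contact_mesh
        out = reposition_interior(mesh)
        loop = mesh.perimeter_nodes
        assert np.allclose(out.coords[loop], mesh.coords[loop])
        assert np.array_equal(out.seg_tags, mesh.seg_tags)

    def test_perturbed_interior_restored(self, contact_mesh):
        mesh, _ = contact_mesh
        bad = mesh.copy()
        tags = mesh.node_tags()
        interior = np.where(tags == -1)[0]
        rng = np.random.default_rng(0)
        bad.coords[interior] += rng.normal(0, 0.05, (len(interior), 2))
        out = reposition_interior(bad)
        assert out.min_scaled_jacobian() >= bad.min_scaled_jacobian()


class TestRemap:
    def _fields(self, mesh, rng=None):
        st_ = FieldState.resting(mesh.n_nodes, mesh.n_elements, 0.02)
        if rng is not None:
            st_.theta = 0.02 + 0.1 * rng.random(mesh.n_elements)
            st_.messenger = rng.random(mesh.n_nodes)
        return st_

    def test_identity_remap_preserves_fields(self, contact_mesh):
        mesh, _ = contact_mesh
        rng = np.random.default_rng(1)
        st_ = self._fields(mesh, rng)
        out = remap_fields(mesh, mesh.copy(), st_)
        assert np.allclose(out.theta, st_.theta, atol=1e-12)
        assert np.allclose(out.messenger, st_.messenger, atol=1e-12)

    def test_uniform_field_stays_uniform(self, contact_mesh):
        mesh, target = contact_mesh
        st_ = self._fields(mesh)
        st_.theta[:] = 0.07
        st_.messenger[:] = 1.3
        new = relayout(mesh, target, 0)
        out = remap_fields(mesh, new, st_)
        # boundary resampling perturbs element volumes at the 1e-5 level;
        # constancy holds to that discretization tolerance
        assert np.allclose(out.theta, 0.07, atol=5e-5)
        assert np.allclose(out.messenger, 1.3, atol=1e-6)

    def test_gaussian_blob_mass_conserved_within_half_percent(self, contact_mesh):
        from phagosim.mesh import _nodal_mass

        mesh, target = contact_mesh
        st_ = self._fields(mesh)
        # messenger blob on the axis, a few elements wide
        c = np.array([0.9, 0.0])
        d2 = np.sum((mesh.coords - c) ** 2, axis=1)
        st_.messenger = np.exp(-d2 / (2 * 0.8**2))
        st_.theta = 0.02 + 0.1 * np.exp(
            -np.sum((mesh.coords[mesh.quads].mean(axis=1) - c) ** 2, axis=1) / (2 * 0.8**2)
        )
        # shift interior nodes by about half an element
        new = mesh.copy()
        tags = mesh.node_tags()
        interior = tags == -1
        new.coords[interior, 1] += 0.25
        new = reposition_interior(new)
        out = remap_fields(mesh, new, st_)
        m0 = _nodal_mass(mesh, st_.messenger)
        m1 = _nodal_mass(new, out.messenger)
        assert abs(m1 - m0) / m0 < 0.005
        th0 = np.sum(mesh.element_volumes() * st_.theta)
        th1 = np.sum(new.element_volumes() * out.theta)
        assert abs(th1 - th0) / th0 < 0.005

    def test_remap_is_monotone_no_new_extrema(self, contact_mesh):
        mesh, target = contact_mesh
        rng = np.random.default_rng(2)
        st_ = self._fields(mesh, rng)
        new = relayout(mesh, target, 0)
        out = remap_fields(mesh, new, st_)
        tol = 1e-9
        assert out.messenger.min() >= st_.messenger.min() - tol
        assert out.messenger.max() <= st_.messenger.max() + tol
        assert out.theta.min() >= -tol

    def test_topology_mismatch_rejected(self, contact_mesh, sphere_mesh):
        meshA, _ = contact_mesh
        st_ = self._fields(meshA)
        meshB = Mesh(
            coords=np.zeros((10, 2)), nxi=2, neta=2,
            seg_tags=np.zeros(8, dtype=int),
        )
        with pytest.raises(ConfigurationError):
            remap_fields(meshA, meshB, st_)


class TestVolumeCorrection:
    def test_correct_volume_restores_target(self, contact_mesh):
        mesh, _ = contact_mesh
        V0 = mesh.enclosed_volume()
        out = correct_volume(mesh, V0 * 1.001)
        assert out.enclosed_volume() == pytest.approx(V0 * 1.001, rel=5e-4)
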