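"""Cell-target interface: adhesion, stresses, tension timeline, target motion."""
import math

import numpy as np
import pytest

from phagosim.errors import ConfigurationError
from phagosim.interface import (
    EffectorState,
    attraction_stress,
    cortical_tension,
    messenger_source,
    protrusive_stress,
    stimulation_factor,
    target_force_balance,
    update_adhesion,
)
from phagosim.mesh import CONTACT, TargetSphere
from phagosim.scenarios import make_scenario


@pytest.fixture
def zym():
    return make_scenario("zymosan")


@pytest.fixture
def ab():
    return make_scenario("antibody")


class TestCorticalTension:
    def test_resting_value_25_pn_per_um(self, zym):
        assert cortical_tension(0.0, zym) == pytest.approx(25.0)

    def test_zymosan_plateau_300(self, zym):
        assert cortical_tension(1e4, zym) == pytest.approx(300.0)

    def test_antibody_plateau_150(self, ab):
        assert cortical_tension(1e4, ab) == pytest.approx(150.0)

    def test_linear_ramp_midpoint(self, zym):
        t_mid = zym.ramp_onset + 0.5 * zym.ramp_duration
        assert cortical_tension(t_mid, zym) == pytest.approx(0.5 * (25 + 300))

    def test_viscosity_factor_ramps_with_tension(self, zym, ab):
        t_end = zym.ramp_onset + zym.ramp_duration
        assert stimulation_factor(0.0, zym) == 1.0
        assert stimulation_factor(t_end + 1, zym) == pytest.approx(5.0)
        assert stimulation_factor(t_end + 1, ab) == pytest.approx(1.0)


class TestEffectorStresses:
    def test_contact_zone_scaling_between_scenarios(self, zym, ab, params):
        th = np.array([0.1, 0.2])
        free_z = protrusive_stress(th, "free", zym, params)
        free_a = protrusive_stress(th, "free", ab, params)
        assert np.allclose(free_z, free_a)                      # same law at free membrane
        assert np.allclose(protrusive_stress(th, "contact", ab, params), 0.0)
        assert np.allclose(
            protrusive_stress(th, "contact", zym, params), 0.5 * free_z
        )

    def test_zero_theta_zero_stress(self, zym, params):
        assert protrusive_stress(np.zeros(4), "free", zym, params).max() == 0.0

    def test_unknown_zone_rejected(self, zym, params):
        with pytest.raises(ConfigurationError):
            protrusive_stress(np.array([0.1]), "apex", zym, params)

    def test_attraction_only_antibody_contact(self, zym, ab, params):
        assert attraction_stress("contact", ab, params) == params.sigma_attract
        assert attraction_stress("contact", zym, params) == 0.0
        assert attraction_stress("free", ab, params) == 0.0


class TestAdhesion:
    def test_distant_target_leaves_tags_unchanged(self, contact_mesh):
        mesh, target = contact_mesh
        far = TargetSphere(1.6, center_z=target.center_z + 5.0, phi_max=target.phi_max)
        m = mesh.copy()
        out, n_adh = update_adhesion(m, far)
        assert n_adh == 0
        assert out.phi_max == far.phi_max

    def test_touching_node_adjacent_to_patch_joins(self, contact_mesh):
        mesh, target = contact_mesh
        m = mesh.copy()
        # push the first free node onto the sphere surface
        from phagosim.mesh import leading_free_nodes

        nd = leading_free_nodes(m)[0]
        phi = float(target.polar_angle(*m.coords[nd]))
        m.coords[nd] = target.surface_point(phi)
        out, n_adh = update_adhesion(m, target)
        assert n_adh >= 1
        assert out.phi_max > target.phi_max

    def test_penetrating_node_projected_to_surface(self, contact_mesh):
        mesh, target = contact_mesh
        from phagosim.mesh import leading_free_nodes

        m = mesh.copy()
        nd = leading_free_nodes(m)[3]
        # move the node inside the rigid sphere
        m.coords[nd] = (0.3, target.center_z)
        update_adhesion(m, target)
        assert target.signed_gap(*m.coords[nd]) >= -1e-9

    def test_arc_never_shrinks(self, contact_mesh):
        mesh, target = contact_mesh
        eff = EffectorState()
        eff.record(0.0, target.phi_max)
        out, _ = update_adhesion(mesh.copy(), target, eff, 1.0)
        assert out.phi_max >= target.phi_max
        with pytest.raises(Exception):
            eff.record(2.0, target.phi_max - 0.1)


class TestMessengerSource:
    def test_stimulus_scales_match_scenarios(self, contact_mesh, zym, ab, params):
        mesh, target = contact_mesh
        eff = EffectorState()
        eff.record(0.0, target.phi_max)
        f_z = messenger_source(mesh, target, eff, zym, params, 1.0)
        f_a = messenger_source(mesh, target, eff, ab, params, 1.0)
        assert f_z.max() == pytest.approx(0.75 * params.source_strength)
        assert f_a.max() == pytest.approx(1.0 * params.source_strength)

    def test_production_limited_to_fresh_patch_and_annulus(self, contact_mesh, zym, params):
        mesh, target = contact_mesh
        eff = EffectorState()
        eff.record(0.0, target.phi_max)
        flux = messenger_source(mesh, target, eff, zym, params, 1.0)
        active = np.nonzero(flux)[0]
        contact = set(np.where(mesh.seg_tags == CONTACT)[0])
        from phagosim.mesh import FREE

        free = np.where(mesh.seg_tags == FREE)[0][: zym.annulus_segments]
        assert set(active) <= contact | set(free)

    def test_engulfed_target_produces_nothing(self, contact_mesh, zym, params):
        mesh, target = contact_mesh
        eff = EffectorState()
        eff.record(0.0, math.radians(170.0))
        flux = messenger_source(mesh, target, eff, zym, params, 5.0)
        assert flux.max() == 0.0


class TestTargetForceBalance:
    def test_zero_traction_no_motion(self):
        t = TargetSphere(1.6, center_z=5.0)
        out = target_force_balance(t, 0.0, target_velocity=0.0, dt=1.0)
        assert out.center_z == 5.0

    def test_outward_velocity_moves_target_outward(self):
        t = TargetSphere(1.6, center_z=5.0)
        out = target_force_balance(t, 100.0, target_velocity=0.02, dt=2.0)
        assert out.center_z == pytest.approx(5.04)

    def test_mobility_fallback(self):
        t = TargetSphere(1.6, center_z=5.0)
        out = target_force_balance(t, 50.0, target_velocity=None, dt=1.0, mobility=1e-3)
        assert out.center_z == pytest.approx(5.05)
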