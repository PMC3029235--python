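import math

import numpy as np
import pytest

from phagosim.biphasic import ConstitutiveParams
from phagosim.mesh import TargetSphere, build_initial_mesh
from phagosim.state import FieldState


@pytest.fixture(scope="session")
def sphere_mesh():
    """Target-free spherical cell (no contact patch): the Laplace-law geometry."""
    mesh, target = build_initial_mesh(4.25, TargetSphere(1.6), 0.0, 1.0)
    return mesh, target


@pytest.fixture(scope="session")
def contact_mesh():
    """Cell with a small initial adhesion patch on the target sphere."""
    mesh, target = build_initial_mesh(4.25, TargetSphere(1.6), 0.25, 1.0)
    return mesh, target


@pytest.fixture
def params():
    return ConstitutiveParams()


@pytest.fixture
def resting_state(contact_mesh, params):
    mesh, _ = contact_mesh
    return FieldState.resting(mesh.n_nodes, mesh.n_elements, params.theta_base)


def make_linear_trace(d_star=1.0, t_peak=30.0, T_star=150.0, v_star_nm=33.0,
                      completion=0.95, dt=1.0):
    """Piecewise-linear trajectory fixture with known peak/speed/completion."""
    from phagosim.scenarios import Trajectory

    v = v_star_nm / 1000.0
    t_end = T_star * 1.2
    t = np.unique(np.concatenate([np.arange(0.0, t_end + 1e-9, dt),
                                  [t_peak, T_star, t_end]]))
    pos = np.where(
        t <= t_peak, d_star * t / t_peak,
        np.where(t <= T_star, d_star - v * (t - t_peak),
                 d_star - v * (T_star - t_peak)),
    )
    frac = np.clip(t / T_star, 1e-9, 1.0) * completion
    frac[t >= T_star] = np.minimum(completion + (t[t >= T_star] - T_star) * 1e-4, 1.0)
    return Trajectory(
        time=t, target_position=pos,
        tension=np.full_like(t, 0.025), engulfed_fraction=frac,
    )


@pytest.fixture
def linear_trace():
    return make_linear_trace()
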