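"""Scenario presets and the full simulation loop.

The four presets encode the target-specific mechanoeffector switchboard:

=====================================  ==========  =========
effector                               antibody    zymosan
=====================================  ==========  =========
local stimulus (polymerization)        100%        75%
protrusive force at free membrane      same        same
protrusive force at contact region     none        50%
membrane-cytoskeleton attraction       100%        none
cortical tension (mN/m)                0.025->0.15 0.025->0.3
cytoplasmic viscosity                  constant    x5 ramp
=====================================  ==========  =========

plus the two counterfactual variants used to eliminate alternative
mechanisms: the antibody force set without attraction, and zymosan with a
full-strength contact-zone protrusive force.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import interface as itf
from . import mesh as msh
from .biphasic import (
    ConstitutiveParams,
    interconvert_phases,
    messenger_element_mean,
    solve_momentum,
    step_messenger,
)
from .errors import ConfigurationError, RemeshError, SimulationError
from .interface import (
    EffectorState,
    PHI_COMPLETE,
    boundary_stress_fields,
    cortical_tension,
    messenger_source,
    stimulation_factor,
    target_force_balance,
    update_adhesion,
)
from .mesh import (
    Mesh,
    TargetSphere,
    advect_boundary,
    build_initial_mesh,
    courant_timestep,
    relayout,
    remap_fields,
)
from .state import FieldState


@dataclass
class ScenarioConfig:
    """Effector switchboard plus run controls for one simulation."""

    name: str = "zymosan"
    stimulus_scale: float = 0.75
    contact_protrusion_scale: float = 0.5
    attraction_on: bool = False
    tension_rest: float = 0.025          # mN/m
    tension_plateau: float = 0.3         # mN/m
    ramp_onset: float = 10.0             # s after first contact
    ramp_duration: float = 60.0          # s
    viscosity_ramp_factor: float = 5.0
    t_end: float = 400.0                 # s
    resolution: float = 1.25
    seed: int = 0                        # reserved; the core loop is deterministic
    # geometry / numerics
    cell_radius: float = 4.25            # µm
    target_radius: float = 1.6           # µm
    initial_contact_angle: float = 0.25  # rad
    tau_transient: float = 10.0          # s of messenger production per patch segment
    annulus_segments: int = 2            # leading-edge annulus width, in boundary segments
    cfl: float = 0.4
    dt_max: float = 0.5                  # s
    completion_margin: float = 20.0      # s to continue past completion
    activation_time: float = 5.0         # s; build-up of interface forces after contact

    def validate(self):
        for nm in ("stimulus_scale", "contact_protrusion_scale"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{nm} must be in [0, 1], got {v}")
        if self.viscosity_ramp_factor < 1.0:
            raise ConfigurationError("viscosity_ramp_factor must be >= 1")
        if self.tension_plateau < self.tension_rest:
            raise ConfigurationError("tension_plateau must be >= tension_rest")
        if self.t_end <= 0 or self.dt_max <= 0:
            raise ConfigurationError("t_end and dt_max must be positive")


_PRESETS = {
    "zymosan": dict(
        stimulus_scale=0.75, contact_protrusion_scale=0.5, attraction_on=False,
        tension_plateau=0.3, viscosity_ramp_factor=5.0, t_end=400.0,
    ),
    "antibody": dict(
        stimulus_scale=1.0, contact_protrusion_scale=0.0, attraction_on=True,
        tension_plateau=0.15, viscosity_ramp_factor=1.0, t_end=170.0,
    ),
    "fcgamma_no_attraction": dict(
        stimulus_scale=1.0, contact_protrusion_scale=0.0, attraction_on=False,
        tension_plateau=0.3, viscosity_ramp_factor=5.0, t_end=400.0,
    ),
    "zymosan_full_contact_protrusion": dict(
        stimulus_scale=0.75, contact_protrusion_scale=1.0, attraction_on=False,
        tension_plateau=0.3, viscosity_ramp_factor=5.0, t_end=400.0,
    ),
}


def make_scenario(name: str, **overrides) -> ScenarioConfig:
    """Build one of the named scenario presets (with optional field overrides)."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; known: {sorted(_PRESETS)}"
        )
    cfg = ScenarioConfig(name=name, **_PRESETS[name])
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


@dataclass
class Trajectory:
    """Time series of the engulfment run (outward target motion positive)."""

    time: np.ndarray
    target_position: np.ndarray     # µm, target-center z relative to the held rear edge
    tension: np.ndarray             # mN/m
    engulfed_fraction: np.ndarray   # target-surface area fraction covered
    completion_time: float | None = None
    volume_drift: float = 0.0       # relative cell-volume drift over the run
    diagnostics: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "position_um": self.target_position,
                "tension_mN_per_m": self.tension,
                "engulfed_fraction": self.engulfed_fraction,
            }
        )

    def validate(self):
        if np.any(np.diff(self.time) <= 0):
            raise SimulationError("trajectory times not strictly increasing")
        if np.any(np.diff(self.engulfed_fraction) < -1e-12):
            raise SimulationError("engulfed fraction decreased")


def engulfed_fraction_of(phi_max: float) -> float:
    """Fraction of the target surface covered by the adhered arc [0, phi]."""
    return 0.5 * (1.0 - math.cos(phi_max))


def run_relaxation(
    params: ConstitutiveParams,
    tension: float,
    t_end: float,
    stretch: float = 1.15,
    resolution: float = 1.0,
    dt_max: float = 0.5,
    cell_radius: float = 4.25,
):
    """Tension-driven rounding of a prolate-perturbed free cell.

    Builds a target-free cell, stretches it along the axis by ``stretch``
    (volume-preserving), and lets cortical tension round it up.  Returns
    (times, asphericity) where asphericity is the relative excess of the
    axial over the equatorial extent; its decay time scales with
    viscosity/tension and is used to verify the viscous rounding timescale.
    """
    mesh, target = build_initial_mesh(
        cell_radius, TargetSphere(radius=cell_radius / 2.65), 0.0, resolution
    )
    # prolate perturbation anchored at the held rear (clamped plug nodes kept)
    tags = mesh.node_tags()
    z0 = mesh.coords[mesh.perimeter_nodes[0], 1]
    free_nodes = tags != msh.REAR
    mesh.coords[free_nodes, 1] = z0 + (mesh.coords[free_nodes, 1] - z0) * stretch
    mesh.coords[free_nodes, 0] /= math.sqrt(stretch)
    mesh = msh.reposition_interior(mesh, init_tfi=True)
    V0 = mesh.enclosed_volume()

    state = FieldState.resting(mesh.n_nodes, mesh.n_elements, params.theta_base)
    t = 0.0
    times, asph = [], []

    def asphericity(m):
        loop = m.perimeter_nodes
        pts = m.coords[loop]
        z_ext = pts[:, 1].max() - pts[:, 1].min()
        r_ext = 2.0 * pts[:, 0].max()
        return z_ext / r_ext - 1.0

    times.append(0.0)
    asph.append(asphericity(mesh))
    while t < t_end:
        sol = solve_momentum(mesh, state, params, None, tension=tension)
        dt = courant_timestep(mesh, sol.v_network, 0.4, dt_max)
        moved = advect_boundary(mesh, sol.v_network, dt)
        new_mesh = relayout(moved, target, 0)
        new_mesh = msh.correct_volume(new_mesh, V0)
        new_mesh.check_valid()
        state = remap_fields(mesh, new_mesh, state, sol.v_network, sol.v_solvent,
                             dt, include_velocities=False)
        mesh = new_mesh
        t += dt
        times.append(t)
        asph.append(asphericity(mesh))
    return np.asarray(times), np.asarray(asph)


def run_simulation(
    config: ScenarioConfig,
    params: ConstitutiveParams | None = None,
    snapshot_every: float | None = None,
    progress: bool = False,
    callback=None,
) -> Trajectory:
    """Advance the five-stage cycle (momentum solve -> boundary advection and
    repositioning -> conservative remap -> messenger step -> interconversion)
    until ``t_end`` or engulfment completion plus margin.

    Deterministic for fixed config, parameters and resolution.
    """
    config.validate()
    params = params or ConstitutiveParams()
    params.validate()

    mesh, target = build_initial_mesh(
        config.cell_radius,
        TargetSphere(radius=config.target_radius),
        config.initial_contact_angle,
        config.resolution,
    )
    state = FieldState.resting(mesh.n_nodes, mesh.n_elements, params.theta_base)
    effector = EffectorState()
    effector.record(0.0, target.phi_max)

    z_rear = mesh.coords[mesh.perimeter_nodes[0], 1]
    V0 = mesh.enclosed_volume()

    t = 0.0
    times = [0.0]
    positions = [target.center_z - z_rear]
    tensions = [cortical_tension(0.0, config) / itf.MN_PER_M_TO_PN_PER_UM]
    fractions = [engulfed_fraction_of(target.phi_max)]
    snapshots = []
    completion_time = None
    max_resid = 0.0
    theta_lo, theta_hi = float(state.theta.min()), float(state.theta.max())
    mess_lo = 0.0
    next_snap = 0.0

    while t < config.t_end:
        if completion_time is not None and t >= completion_time + config.completion_margin:
            break

        gamma = cortical_tension(t, config)
        stim = stimulation_factor(t, config)
        effector.tension_now = gamma
        effector.stimulation_factor_now = stim

        # receptor engagement and downstream signaling build up over a few
        # seconds after first contact; ramping the interface forces avoids an
        # unphysical step-function shock at t=0
        act = min(t / config.activation_time, 1.0) if config.activation_time > 0 else 1.0
        prot, attr = boundary_stress_fields(mesh, state.theta, config, params)
        zf_nodal, zf_target = itf.adhesion_capture_forces(mesh, target, params)
        sol = solve_momentum(
            mesh, state, params,
            {
                "protrusive": act * prot,
                "attraction": act * attr,
                "zip_forces": (act * zf_nodal, act * zf_target),
            },
            tension=gamma, stimulation_factor=stim,
        )
        max_resid = max(max_resid, sol.residual)
        theta_lo = min(theta_lo, float(state.theta.min()))
        theta_hi = max(theta_hi, float(state.theta.max()))
        mess_lo = min(mess_lo, float(state.messenger.min()))
        state.v_network = sol.v_network
        state.v_solvent = sol.v_solvent
        state.pressure = sol.pressure

        # step limited by mesh distortion (relative edge velocities) and by
        # the target's travel per step (capture resolution), not by the pure
        # advective Courant bound, which thin near-rigidly-moving cup-wall
        # elements would make needlessly severe
        dt = msh.distortion_timestep(mesh, sol.v_network, config.cfl, config.dt_max)
        if sol.target_velocity:
            dt = min(dt, 0.08 / abs(sol.target_velocity))

        # mesh motion with an escalating retry ladder: halve the step, then
        # smooth the free membrane (standing in for tension-driven smoothing
        # of sub-element kinks that the coarse solve under-resolves), then
        # defer new adhesion captures by one step if their relayout cannot
        # be meshed yet
        _ladder = [
            (1.0, 0, True), (0.5, 0, True), (0.25, 0, True),
            (0.25, 4, True), (0.25, 12, True),
            (0.25, 4, False), (0.25, 12, False), (0.25, 36, False),
        ]
        for attempt, (dt_fac, n_sm, allow_capture) in enumerate(_ladder):
            try:
                dt_try = dt * dt_fac
                moved = advect_boundary(mesh, sol.v_network, dt_try)
                if n_sm:
                    moved = msh.smooth_free_boundary(moved, passes=n_sm)
                tgt_new = target_force_balance(
                    target, sol.target_applied_force, sol.target_velocity, dt_try
                )
                if allow_capture:
                    tgt_new, n_adh = update_adhesion(moved, tgt_new, None, t + dt_try)
                else:
                    update_adhesion(moved, tgt_new, None, t + dt_try)  # projection only
                    tgt_new = replace(tgt_new, phi_max=target.phi_max)
                    n_adh = 0
                new_mesh = relayout(moved, tgt_new, n_adh)
                new_mesh = msh.correct_volume(new_mesh, V0)
                new_mesh.check_valid()
                dt = dt_try
                if tgt_new.phi_max > target.phi_max:
                    effector.record(t + dt, tgt_new.phi_max)
                break
            except RemeshError:
                if attempt == len(_ladder) - 1:
                    raise SimulationError(
                        f"remesh failed at t={t:.1f}s after retries"
                    ) from None

        state = remap_fields(
            mesh, new_mesh, state, sol.v_network, sol.v_solvent, dt,
            include_velocities=False,
        )
        mesh, target = new_mesh, tgt_new
        t += dt

        flux = messenger_source(mesh, target, effector, config, params, t)
        state.messenger = step_messenger(
            mesh, state.messenger, params.D_m, params.k_decay, flux, dt
        )
        m_elem = messenger_element_mean(mesh, state.messenger)
        state.theta = interconvert_phases(state.theta, m_elem, params, dt)

        if callback is not None:
            callback(t, mesh, target, state, sol)
        times.append(t)
        positions.append(target.center_z - z_rear)
        tensions.append(gamma / itf.MN_PER_M_TO_PN_PER_UM)
        fractions.append(engulfed_fraction_of(target.phi_max))

        if completion_time is None and target.phi_max >= PHI_COMPLETE:
            completion_time = t
        if snapshot_every is not None and t >= next_snap:
            snapshots.append((t, mesh.copy(), state.copy()))
            next_snap += snapshot_every
        if progress and len(times) % 50 == 0:
            print(
                f"t={t:7.2f}s phi={math.degrees(target.phi_max):6.1f} "
                f"z={positions[-1]:7.3f} dt={dt:.3f}"
            )

    drift = abs(mesh.enclosed_volume() - V0) / V0
    traj = Trajectory(
        time=np.asarray(times),
        target_position=np.asarray(positions),
        tension=np.asarray(tensions),
        engulfed_fraction=np.asarray(fractions),
        completion_time=completion_time,
        volume_drift=drift,
        diagnostics={
            "max_residual": max_resid,
            "n_steps": len(times) - 1,
            "theta_min": theta_lo,
            "theta_max": theta_hi,
            "messenger_min": mess_lo,
        },
        snapshots=snapshots,
    )
    traj.validate()
    return traj
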