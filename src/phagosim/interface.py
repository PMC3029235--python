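"""Cell-target interface mechanics.

Adhesion between the membrane and the target is irreversible: boundary
segments that come within the gap tolerance of the sphere and are contiguous
with the existing patch join it and never detach, so the adhered polar arc
[0, phi_max] only grows.  The leading edge of the patch transiently produces
a diffusible signaling messenger that drives local actin polymerization; the
polymerized network exerts a disjoining (protrusive) stress on the membrane,
and - for antibody-coated targets - the adherent membrane additionally pulls
the cytoskeleton onto the bead (attraction).  The cortical tension follows
the measured, prescribed piecewise-linear timeline.
"""
from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import mesh as msh
from .errors import ConfigurationError, SimulationError
from .mesh import AXIS, CONTACT, FREE, REAR, Mesh, TargetSphere

MN_PER_M_TO_PN_PER_UM = 1000.0   # 1 mN/m = 10^3 pN/µm
# adhered arc at which engulfment counts as complete: 95% surface coverage
PHI_COMPLETE = math.acos(1.0 - 2.0 * 0.95)


@dataclass
class EffectorState:
    """Time course of the adhered arc and current effector values.

    ``phi_history`` stores (time, phi_max) breakpoints; since adhesion is
    irreversible, phi_max(t) is non-decreasing, and the age of the patch at
    polar angle phi is ``t - adhesion_time(phi)``.
    """

    phi_history: list = field(default_factory=list)
    contact_time: float = 0.0
    tension_now: float = 0.0             # pN/µm
    stimulation_factor_now: float = 1.0

    def record(self, t: float, phi_max: float):
        if self.phi_history and phi_max < self.phi_history[-1][1] - 1e-12:
            raise SimulationError("adhered arc tried to shrink (detachment is proscribed)")
        if not self.phi_history or phi_max > self.phi_history[-1][1]:
            self.phi_history.append((t, phi_max))

    def phi_at(self, t: float) -> float:
        """Adhered arc at time t (staircase interpolation of the history)."""
        if not self.phi_history:
            return 0.0
        times = [h[0] for h in self.phi_history]
        i = bisect.bisect_right(times, t) - 1
        if i < 0:
            return 0.0
        return self.phi_history[i][1]

    def adhesion_time(self, phi: float) -> float:
        """First time at which the patch covered polar angle phi."""
        for t, p in self.phi_history:
            if p >= phi - 1e-12:
                return t
        return math.inf


# ---------------------------------------------------------------------------
# adhesion
# ---------------------------------------------------------------------------

def update_adhesion(
    mesh: Mesh, target: TargetSphere, effector: EffectorState | None = None,
    t: float = 0.0,
) -> tuple[TargetSphere, int]:
    """Grow the contact patch: free-membrane nodes within the gap tolerance of
    the target and contiguous with the patch adhere (and are projected onto
    the sphere); any other free node that penetrated the rigid sphere is
    pushed back to its surface.  Returns the updated target and the number of
    newly adhered leading free nodes (contiguous from the rim).

    Adhesion is irreversible: phi_max never decreases.
    """
    tol = target.gap_tol
    phi_max = target.phi_max

    # free nodes in order of increasing distance from the rim along the membrane
    free_idx = msh.leading_free_nodes(mesh)

    # non-penetration of the rigid target: any free node inside the sphere is
    # projected back to its surface (before the adhesion walk, so that nodes
    # pressed onto the target can join the patch this step)
    for nd in free_idx:
        r, z = mesh.coords[nd]
        if target.signed_gap(r, z) < 0.0:
            phi = float(target.polar_angle(r, z))
            pr, pz = target.surface_point(phi)
            mesh.coords[nd] = (pr, pz)

    # contiguous capture walk with bridging: the patch grows to the furthest
    # node inside the gap tolerance, capturing (and projecting) any shallow
    # "bridge" nodes in between - membrane hugging the sphere just outside
    # the strict tolerance would otherwise stall the zipper and collapse the
    # material wedge at the rim into a cusp
    bridge_tol = max(3.0 * tol, 0.1)
    gaps = np.array([target.signed_gap(*mesh.coords[nd]) for nd in free_idx[:12]])
    k_capture = 0
    for k in range(len(gaps)):
        if gaps[k] > bridge_tol:
            break
        if gaps[k] <= tol:
            k_capture = k + 1
    n_adhered = k_capture
    for nd in free_idx[:k_capture]:
        r, z = mesh.coords[nd]
        phi = float(target.polar_angle(r, z))
        if phi <= phi_max:
            # node folded back onto already-adhered arc; treat as rim contact
            phi = phi_max
        phi_max = min(max(phi_max, phi), math.radians(179.0))

    new_target = replace(target, phi_max=phi_max)
    if effector is not None and phi_max > target.phi_max:
        effector.record(t, phi_max)
    return new_target, n_adhered


# ---------------------------------------------------------------------------
# effector stresses and sources
# ---------------------------------------------------------------------------

def messenger_source(
    mesh: Mesh,
    target: TargetSphere,
    effector: EffectorState,
    scenario,
    params,
    t: float,
) -> np.ndarray:
    """Per-perimeter-segment messenger influx (a.u. µm/s).

    Segments of the adhered patch younger than ``tau_transient`` produce at
    ``stimulus_scale * source_strength``; so does a fixed-width annulus of
    free membrane just ahead of the rim.  A fully engulfed target (no leading
    edge left on the free membrane) produces nothing.
    """
    P = mesh.n_perimeter
    flux = np.zeros(P)
    phi_now = effector.phi_at(t)
    if phi_now >= PHI_COMPLETE:
        return flux
    phi_old = effector.phi_at(t - scenario.tau_transient)
    amp = scenario.stimulus_scale * params.source_strength

    segs = mesh.perimeter_segments()
    mid = 0.5 * (mesh.coords[segs[:, 0]] + mesh.coords[segs[:, 1]])
    contact = np.where(mesh.seg_tags == CONTACT)[0]
    if len(contact):
        phis = target.polar_angle(mid[contact, 0], mid[contact, 1])
        flux[contact[phis > phi_old]] = amp

    n_ann = max(1, int(scenario.annulus_segments))
    free_segs = np.where(mesh.seg_tags == FREE)[0]
    flux[free_segs[:n_ann]] = amp
    return flux


def protrusive_stress(theta_at_membrane, zone: str, scenario, params) -> np.ndarray:
    """Outward disjoining stress sigma = zone_scale * sigma_protrude * theta.

    zone_scale is 1 on the free membrane in both scenarios; on the contact
    patch it is the scenario's contact_protrusion_scale (0 for antibody, 0.5
    for zymosan).
    """
    th = np.asarray(theta_at_membrane, float)
    if np.any(th < 0):
        raise ConfigurationError("negative membrane network fraction")
    if zone == "free":
        scale = 1.0
    elif zone == "contact":
        scale = scenario.contact_protrusion_scale
    else:
        raise ConfigurationError(f"unknown membrane zone {zone!r}")
    return scale * params.sigma_protrude * th


def attraction_stress(zone: str, scenario, params, gap_normal_distance: float = 0.0):
    """Inward membrane-cytoskeleton attraction: only on the adhered patch and
    only when the scenario enables it (antibody-coated targets)."""
    if zone == "contact" and scenario.attraction_on:
        return params.sigma_attract
    return 0.0


def boundary_stress_fields(mesh: Mesh, theta_elem: np.ndarray, scenario, params):
    """Assemble per-perimeter-segment protrusive and attraction stresses."""
    P = mesh.n_perimeter
    prot = np.zeros(P)
    attr = np.zeros(P)
    adj = adjacent_elements(mesh)
    th = np.clip(theta_elem[adj], 0.0, None)
    free = mesh.seg_tags == FREE
    contact = mesh.seg_tags == CONTACT
    prot[free] = protrusive_stress(th[free], "free", scenario, params)
    prot[contact] = protrusive_stress(th[contact], "contact", scenario, params)
    attr[contact] = attraction_stress("contact", scenario, params)
    return prot, attr


def adhesion_capture_forces(mesh: Mesh, target: TargetSphere, params):
    """Contact-line (zipper) traction: free-membrane segments just ahead of
    the rim whose gap to the rigid target lies within the capture range are
    pulled onto the sphere at ``sigma_adhesion``.  This is the continuum
    realization of "adhesion upon contact" common to both scenarios; it is
    self-limiting because captured membrane adheres irreversibly and the
    traction only ever acts on the advancing fringe.

    Returns (nodal force field (N, 2) on the membrane, axial reaction force
    on the target in pN).
    """
    f = np.zeros_like(mesh.coords)
    reaction_z = 0.0
    free_segs = np.where(mesh.seg_tags == FREE)[0]
    if len(free_segs) == 0:
        return f, reaction_z
    segs = mesh.perimeter_segments()
    for p in free_segs[:8]:          # only the fringe adjacent to the rim
        a = mesh.coords[segs[p, 0]]
        b = mesh.coords[segs[p, 1]]
        mid = 0.5 * (a + b)
        gap = float(target.signed_gap(mid[0], mid[1]))
        if gap > params.capture_range:
            break
        if gap <= 0.0:
            continue
        # taper with distance: full strength at contact, zero at range
        s = params.sigma_adhesion * (1.0 - gap / params.capture_range)
        L = float(np.hypot(*(b - a)))
        area = 2 * math.pi * 0.5 * (a[0] + b[0]) * L
        # pull toward the sphere surface slightly ahead of the fringe: the
        # zipper advances the contact line, not just the normal approach
        phi_mid = float(target.polar_angle(mid[0], mid[1]))
        pr, pz = target.surface_point(min(phi_mid + 0.15, math.radians(179.0)))
        to_sphere = np.array([pr, pz]) - mid
        to_sphere /= max(np.linalg.norm(to_sphere), 1e-300)
        fv = 0.5 * s * area * to_sphere
        f[segs[p, 0]] += fv
        f[segs[p, 1]] += fv
        reaction_z -= 2 * fv[1]
    return f, reaction_z


def adjacent_elements(mesh: Mesh) -> np.ndarray:
    """Flat element index adjacent to each perimeter segment."""
    nxi, neta = mesh.nxi, mesh.neta
    P = mesh.n_perimeter
    out = np.empty(P, dtype=int)
    for p in range(P):
        if p < nxi:
            i, j = p, 0
        elif p < nxi + neta:
            i, j = nxi - 1, p - nxi
        elif p < 2 * nxi + neta:
            i, j = nxi - 1 - (p - nxi - neta), neta - 1
        else:
            i, j = 0, neta - 1 - (p - 2 * nxi - neta)
        out[p] = i * neta + j
    return out


# ---------------------------------------------------------------------------
# cortical tension timeline
# ---------------------------------------------------------------------------

def cortical_tension(t: float, scenario) -> float:
    """Prescribed cortical tension in pN/µm: resting value until ramp onset,
    linear rise over the ramp duration, then plateau."""
    rest = scenario.tension_rest * MN_PER_M_TO_PN_PER_UM
    plateau = scenario.tension_plateau * MN_PER_M_TO_PN_PER_UM
    if t <= scenario.ramp_onset:
        return rest
    frac = min((t - scenario.ramp_onset) / max(scenario.ramp_duration, 1e-12), 1.0)
    return rest + (plateau - rest) * frac


def stimulation_factor(t: float, scenario) -> float:
    """Global viscosity stimulation factor, ramping linearly in lockstep with
    the cortical tension (1 -> viscosity_ramp_factor)."""
    if t <= scenario.ramp_onset:
        return 1.0
    frac = min((t - scenario.ramp_onset) / max(scenario.ramp_duration, 1e-12), 1.0)
    return 1.0 + (scenario.viscosity_ramp_factor - 1.0) * frac


# ---------------------------------------------------------------------------
# rigid-target kinematics
# ---------------------------------------------------------------------------

def target_force_balance(
    target: TargetSphere,
    axial_traction_force: float,
    target_velocity: float | None = None,
    dt: float = 0.0,
    mobility: float = 0.0,
) -> TargetSphere:
    """Advance the rigid target along the axis.

    In the coupled solve the target's axial velocity is an unknown whose
    equation is the zero-net-force condition (quasi-static balance with the
    membrane tractions transmitted through the irreversible adhesion); the
    solved ``target_velocity`` is applied here.  When no coupled velocity is
    available a mobility relaxation ``dz = mobility * F * dt`` is used.
    """
    if target_velocity is not None:
        dz = target_velocity * dt
    else:
        dz = mobility * axial_traction_force * dt
    return replace(target, center_z=target.center_z + dz)
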