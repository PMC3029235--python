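"""Axisymmetric moving quadrilateral mesh of the cell body.

The cell cross-section in the (r, z) half-plane is covered by a single
structured block of quadrilaterals (logical grid ``(nxi+1) x (neta+1)``).
The block's inner edge (logical row j=0) runs along the symmetry axis from
the held rear pole to the contact pole and then along the adhered arc of the
target sphere; the outer edge and the two short side edges cover the free
membrane and the rear holding band.  Boundary tags partition the closed
perimeter polyline into {axis | contact_patch | free_membrane | rear_hold}.

Coordinates are cylindrical (r, z) with z along the symmetry axis and the
target at larger z.  Units: µm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, GeometryError, NumericalError, RemeshError
from .state import FieldState

# boundary segment tags
AXIS = 0
CONTACT = 1
FREE = 2
REAR = 3

TAG_NAMES = {AXIS: "axis", CONTACT: "contact_patch", FREE: "free_membrane", REAR: "rear_hold"}

_MIN_ETA = 8          # minimum elements across the cell radius (radial spokes)
_XI_PER_ETA = 5       # membrane (meridian) resolution relative to radial
GAP_TOL_FRACTION = 0.02   # contact detection gap: fraction of target radius


@dataclass
class TargetSphere:
    """Rigid spherical phagocytic target on the symmetry axis.

    ``phi_max`` is the polar half-angle of the adhered arc, measured from the
    contact pole (the target point nearest the cell).  It is non-decreasing:
    adhesion is irreversible.
    """

    radius: float = 1.6
    center_z: float = 0.0
    phi_max: float = 0.0

    @property
    def contact_pole_z(self) -> float:
        return self.center_z - self.radius

    def surface_point(self, phi: float | np.ndarray):
        """(r, z) of the surface point at polar angle ``phi`` from the contact pole."""
        return self.radius * np.sin(phi), self.center_z - self.radius * np.cos(phi)

    def polar_angle(self, r: float | np.ndarray, z: float | np.ndarray):
        """Polar angle from the contact pole of the direction to (r, z)."""
        return np.arctan2(r, self.center_z - np.asarray(z))

    def signed_gap(self, r, z):
        """Distance from (r, z) to the sphere surface (negative inside)."""
        d = np.hypot(np.asarray(r, float), np.asarray(z, float) - self.center_z)
        return d - self.radius

    @property
    def gap_tol(self) -> float:
        return GAP_TOL_FRACTION * self.radius


@dataclass
class Mesh:
    """Structured axisymmetric quad mesh with tagged boundary."""

    coords: np.ndarray          # (N, 2) node positions, columns (r, z)
    nxi: int
    neta: int
    seg_tags: np.ndarray        # (P,) int tag per perimeter segment
    generation: int = 0
    # rigid pipette plug holding the cell rear: (radius, junction z, bore depth)
    plug: tuple = (0.9, -4.15, 0.8)
    # logical layout: "fan" (spokes from the plug; robust for shallow cups)
    # or "shell" (rings between axis+contact arc and the membrane; robust
    # for deeply wrapped cups)
    layout: str = "shell"

    # ---- structured-topology helpers -------------------------------------
    def node(self, i, j) -> int:
        return j * (self.nxi + 1) + i

    @property
    def n_nodes(self) -> int:
        return (self.nxi + 1) * (self.neta + 1)

    @property
    def n_elements(self) -> int:
        return self.nxi * self.neta

    @property
    def quads(self) -> np.ndarray:
        """(M, 4) node indices per quad, counter-clockwise in the (r, z) plane."""
        i = np.arange(self.nxi)
        j = np.arange(self.neta)
        ii, jj = np.meshgrid(i, j, indexing="ij")
        n = lambda a, b: b * (self.nxi + 1) + a
        q = np.stack(
            [n(ii, jj), n(ii, jj + 1), n(ii + 1, jj + 1), n(ii + 1, jj)], axis=-1
        )
        return q.reshape(-1, 4)

    def elem_index(self, i, j) -> int:
        """Flat element index used by :pyattr:`quads` (i-major)."""
        return i * self.neta + j

    @property
    def perimeter_nodes(self) -> np.ndarray:
        """Ordered closed loop of boundary node indices (length P)."""
        nxi, neta = self.nxi, self.neta
        bot = [self.node(i, 0) for i in range(nxi + 1)]
        right = [self.node(nxi, j) for j in range(1, neta + 1)]
        top = [self.node(i, neta) for i in range(nxi - 1, -1, -1)]
        left = [self.node(0, j) for j in range(neta - 1, 0, -1)]
        return np.array(bot + right + top + left, dtype=int)

    @property
    def n_perimeter(self) -> int:
        return 2 * (self.nxi + self.neta)

    def perimeter_segments(self) -> np.ndarray:
        """(P, 2) node-index pairs of consecutive perimeter segments."""
        loop = self.perimeter_nodes
        return np.stack([loop, np.roll(loop, -1)], axis=1)

    def node_tags(self) -> np.ndarray:
        """Per-node tag (-1 interior).  Junction priority: rear > contact > axis > free."""
        tags = np.full(self.n_nodes, -1, dtype=int)
        loop = self.perimeter_nodes
        segs = self.seg_tags
        prio = {REAR: 3, CONTACT: 2, AXIS: 1, FREE: 0}
        P = len(loop)
        for p in range(P):
            for nd, tg in ((loop[p], segs[p]), (loop[(p + 1) % P], segs[p])):
                if tags[nd] == -1 or prio[tg] > prio[tags[nd]]:
                    tags[nd] = tg
        return tags

    def copy(self) -> "Mesh":
        return Mesh(
            coords=self.coords.copy(),
            nxi=self.nxi,
            neta=self.neta,
            seg_tags=self.seg_tags.copy(),
            generation=self.generation,
            plug=self.plug,
            layout=self.layout,
        )

    # ---- geometry --------------------------------------------------------
    def enclosed_volume(self) -> float:
        """Cell volume by Pappus quadrature over the boundary polyline, µm³."""
        loop = self.perimeter_nodes
        pts = self.coords[loop]
        nxt = np.roll(pts, -1, axis=0)
        # perimeter loop is clockwise in the (r, z) plane -> negate contour integral
        return -_revolved_contour(pts, nxt)

    def element_volumes(self) -> np.ndarray:
        q = self.quads
        v = np.zeros(len(q))
        for e in range(4):
            a = self.coords[q[:, e]]
            b = self.coords[q[:, (e + 1) % 4]]
            v += _revolved_contour_vec(a, b)
        return v

    def corner_jacobians(self) -> np.ndarray:
        """(M, 4) corner cross-products; all must be > 0 for a valid mesh."""
        q = self.quads
        x = self.coords
        out = np.empty((len(q), 4))
        for c in range(4):
            e1 = x[q[:, (c + 1) % 4]] - x[q[:, c]]
            e2 = x[q[:, (c + 3) % 4]] - x[q[:, c]]
            out[:, c] = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        return out

    def min_scaled_jacobian(self) -> float:
        q = self.quads
        x = self.coords
        worst = np.inf
        for c in range(4):
            e1 = x[q[:, (c + 1) % 4]] - x[q[:, c]]
            e2 = x[q[:, (c + 3) % 4]] - x[q[:, c]]
            cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
            denom = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
            worst = min(worst, np.min(cross / np.maximum(denom, 1e-300)))
        return float(worst)

    def check_valid(self):
        if not np.all(np.isfinite(self.coords)):
            raise RemeshError("non-finite node coordinates")
        if np.any(self.coords[:, 0] < -1e-12):
            raise RemeshError("node with negative radius")
        if np.min(self.corner_jacobians()) <= 0.0:
            raise RemeshError("inverted element (non-positive corner Jacobian)")


def volume_gradient(mesh: Mesh) -> np.ndarray:
    """(N, 2) gradient of the enclosed cell volume with respect to node
    positions (nonzero only on the boundary).  Pairs with node velocities to
    give dV/dt exactly."""
    g = np.zeros_like(mesh.coords)
    segs = mesh.perimeter_segments()
    a, b = segs[:, 0], segs[:, 1]
    ra, za = mesh.coords[a, 0], mesh.coords[a, 1]
    rb, zb = mesh.coords[b, 0], mesh.coords[b, 1]
    c = math.pi / 3.0
    # V = -sum c (ra^2 + ra rb + rb^2)(zb - za) over the (clockwise) loop
    np.add.at(g[:, 0], a, -c * (2 * ra + rb) * (zb - za))
    np.add.at(g[:, 0], b, -c * (ra + 2 * rb) * (zb - za))
    np.add.at(g[:, 1], a, c * (ra * ra + ra * rb + rb * rb))
    np.add.at(g[:, 1], b, -c * (ra * ra + ra * rb + rb * rb))
    return g


def _revolved_contour(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(_revolved_contour_vec(a, b)))


def _revolved_contour_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-segment contribution pi/3 (ra^2 + ra rb + rb^2)(zb - za).

    Summed over a counter-clockwise closed contour in the (r, z) plane this
    yields the volume of the solid of revolution.
    """
    ra, za = a[..., 0], a[..., 1]
    rb, zb = b[..., 0], b[..., 1]
    return (math.pi / 3.0) * (ra * ra + ra * rb + rb * rb) * (zb - za)


# ---------------------------------------------------------------------------
# boundary layout
# ---------------------------------------------------------------------------

def _arclength_param(pts: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


def _resample_polyline(pts: np.ndarray, s_targets: np.ndarray) -> np.ndarray:
    """Points at given arclengths along a curve through the polyline vertices.

    Uses shape-preserving (PCHIP) interpolation of r(s), z(s) so that
    repeated resampling at shifted arclengths does not progressively erode
    convex regions the way chord-cutting linear resampling would (which
    would leak cell volume every remesh)."""
    s = _arclength_param(pts)
    s_targets = np.clip(s_targets, 0.0, s[-1])
    if len(pts) < 3:
        r = np.interp(s_targets, s, pts[:, 0])
        z = np.interp(s_targets, s, pts[:, 1])
        return np.stack([r, z], axis=1)
    from scipy.interpolate import PchipInterpolator

    # guard against coincident vertices (zero-length chords)
    keep = np.concatenate([[True], np.diff(s) > 1e-12])
    s_k, p_k = s[keep], pts[keep]
    r = PchipInterpolator(s_k, p_k[:, 0])(s_targets)
    z = PchipInterpolator(s_k, p_k[:, 1])(s_targets)
    return np.stack([r, z], axis=1)


def _plug_points(plug: tuple[float, float, float]):
    """Key points of the rigid pipette plug holding the cell rear.

    The plug surface runs from the membrane junction E up the bore, over a
    chamfered notch (the chamfer splits what would be a 270-degree reflex
    corner into two mild turns the grid can wrap), then across a bi-conical
    cap face through the bend C4 to the apex A on the axis.  The shallow
    bend at C4 gives the logical grid a genuine (clamped, never-degrading)
    fourth corner.
    """
    r_plug, z_j, depth = plug
    z_F = z_j + depth
    c = 0.3 * depth
    E = np.array([r_plug, z_j])
    F1 = np.array([r_plug, z_F - c])
    F2 = np.array([r_plug - 0.6 * c, z_F])
    C4 = np.array([0.45 * r_plug, z_F + 0.125 * depth])
    A = np.array([0.0, z_F + 0.45 * depth])
    return E, F1, F2, C4, A


def _layout_perimeter(
    nxi: int,
    neta: int,
    target: TargetSphere,
    phi_max: float,
    membrane: np.ndarray,
    plug: tuple[float, float, float],
    min_contact_segments: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute perimeter nodes along the boundary curve.

    Logical mapping (the cell is held on a rigid pipette plug at the rear):
    bottom edge = symmetry axis (plug apex A -> contact pole B); right edge =
    the whole membrane (contact arc from the pole to the rim at ``phi_max``,
    then the free membrane polyline ``membrane`` from the rim to the plug
    junction E); top edge = plug bore + outer cap face (E -> F -> C4); left
    edge = inner cap face (C4 -> A).  All four logical corners are genuine
    convex corners of the geometry, so the cup rim (a reflex vertex once the
    cell wraps the target) always lies mid-edge, shared between elements.

    Returns (perimeter positions in loop order, per-segment tags).
    """
    P = 2 * (nxi + neta)
    E, F1, F2, C4, A = _plug_points(plug)
    z_cp = target.contact_pole_z

    # --- bottom edge: axis from plug apex to contact pole (nxi segments) ---
    bottom = np.zeros((nxi + 1, 2))
    bottom[:, 1] = np.linspace(A[1], z_cp, nxi + 1)

    # --- right edge: membrane = contact arc + free polyline (neta segments) ---
    s = _arclength_param(membrane)
    S = s[-1]
    L_contact = target.radius * phi_max
    if phi_max <= 0.0:
        n_c = 0
    else:
        # the cup region (contact arc + near-rim membrane) gets ~double weight
        n_c = int(round(neta * 2.0 * L_contact / (2.0 * L_contact + S)))
        n_c = int(np.clip(max(n_c, min_contact_segments, 1), 1, neta - 6))
    n_f = neta - n_c

    memb_pts = np.zeros((neta + 1, 2))
    if n_c > 0:
        # grade the adhered arc toward the rim: the reflex fold at the rim
        # needs short boundary segments on both sides
        u = np.linspace(0.0, 1.0, n_c + 1)
        phis = phi_max * (1.0 - (1.0 - u) ** 1.5)
        r, z = target.surface_point(phis)
        memb_pts[: n_c + 1, 0] = r
        memb_pts[: n_c + 1, 1] = z
    else:
        memb_pts[0] = membrane[0]
    # free membrane: graded segment-size density — fine at the rim (s=0)
    # where the adhesion zipper needs resolution below the gap-closure
    # length scale, coarse mid-membrane, and fine again approaching the plug
    # junction to match the bore spacing there
    if phi_max > 0.0:
        xk = (np.arange(n_f) + 0.5) / n_f
        dens = np.interp(xk, [0.0, 0.45, 1.0], [0.6, 1.35, 0.6])
    else:
        dens = np.ones(n_f)
    s_free = np.concatenate([[0.0], np.cumsum(dens)])
    s_free *= S / s_free[-1]
    memb_pts[n_c:] = _resample_polyline(membrane, s_free)
    memb_pts[-1] = E

    # --- top edge: E -> bore -> chamfer -> C4 (outer cap face), nxi
    #     segments at uniform arclength over the rigid plug surface ---
    plug_line = np.array([E, F1, F2, C4])
    s_plug = _arclength_param(plug_line)
    s_tgt = np.linspace(0.0, s_plug[-1], nxi + 1)
    pts = np.stack(
        [np.interp(s_tgt, s_plug, plug_line[:, 0]), np.interp(s_tgt, s_plug, plug_line[:, 1])],
        axis=1,
    )
    top = pts[::-1].copy()         # top[i] at logical i; top[nxi] = E, top[0] = C4

    # --- left edge: inner cap face C4 -> apex A (neta segments) ---
    cap = np.linspace(0, 1, neta + 1)[:, None] * (C4 - A)[None, :] + A  # cap[j]

    # assemble in loop order: bottom(i=0..nxi), right(j=1..neta),
    # top(i=nxi-1..0), left(j=neta-1..1)
    pos = np.zeros((P, 2))
    pos[: nxi + 1] = bottom
    pos[nxi + 1 : nxi + 1 + neta] = memb_pts[1:]
    pos[nxi + 1 + neta : 2 * nxi + neta + 1] = top[nxi - 1 :: -1]
    pos[2 * nxi + neta + 1 :] = cap[neta - 1 : 0 : -1]

    tags = np.empty(P, dtype=int)
    tags[:nxi] = AXIS
    tags[nxi : nxi + n_c] = CONTACT
    tags[nxi + n_c : nxi + neta] = FREE
    tags[nxi + neta :] = REAR
    return pos, tags


def _layout_perimeter_shell(
    nxi: int,
    neta: int,
    target: TargetSphere,
    phi_max: float,
    membrane: np.ndarray,
    plug: tuple[float, float, float],
    min_contact_segments: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shell-layout node distribution: rings between the inner spine and the
    outer membrane.

    Logical mapping: bottom edge = axis + adhered arc + a short free "lip"
    past the rim (so the reflex rim vertex is shared by two elements);
    right + top edges = the remaining free membrane; left edge = the plug
    surface (junction -> chamfered notch -> cap apex).  Grid lines j=const
    are rings hugging the cup; this stays valid however deeply the cell
    wraps the target.
    """
    P = 2 * (nxi + neta)
    E, F1, F2, C4, A = _plug_points(plug)
    z_cp = target.contact_pole_z

    s = _arclength_param(membrane)
    S = s[-1]
    # the lip must reach past the fold-over collar so that the weak logical
    # corner at its end sits on gently curved membrane
    s_lip = min(1.0, 0.25 * S)
    n_lip = 3 if phi_max > 0.0 else 0

    # --- bottom edge: axis + contact arc + lip (nxi segments) ---
    L_axis = max(z_cp - A[1], 1e-9)
    L_contact = target.radius * phi_max
    if phi_max <= 0.0:
        n_c = 0
    else:
        n_avail = nxi - n_lip
        n_c = int(round(n_avail * 1.6 * L_contact / (1.6 * L_contact + L_axis)))
        n_c = int(np.clip(max(n_c, min_contact_segments, 1), 1, n_avail - 4))
    k = nxi - n_c - n_lip

    bottom = np.zeros((nxi + 1, 2))
    bottom[: k + 1, 0] = 0.0
    bottom[: k + 1, 1] = np.linspace(A[1], z_cp, k + 1)
    if n_c > 0:
        u = np.linspace(0.0, 1.0, n_c + 1)
        phis = phi_max * (1.0 - (1.0 - u) ** 1.3)
        r, z = target.surface_point(phis)
        bottom[k : k + n_c + 1, 0] = r
        bottom[k : k + n_c + 1, 1] = z
    if n_lip:
        lu = np.linspace(0.0, 1.0, n_lip + 1)[1:]
        bottom[k + n_c + 1 :] = _resample_polyline(membrane, s_lip * lu)

    # --- right + top edges: remaining free membrane (neta + nxi segments) ---
    n_free = neta + nxi
    xk = (np.arange(n_free) + 0.5) / n_free
    dens = np.interp(xk, [0.0, 0.5, 1.0], [0.55, 1.4, 0.55])
    s_free = np.concatenate([[0.0], np.cumsum(dens)])
    s_free = s_lip + (S - s_lip) * s_free / s_free[-1]
    free_pts = _resample_polyline(membrane, s_free)
    free_pts[-1] = E

    # --- left edge: plug surface E -> chamfer -> C4 -> apex A (neta segs) ---
    plug_line = np.array([E, F1, F2, C4, A])
    sp = _arclength_param(plug_line)
    st = np.linspace(0.0, sp[-1], neta + 1)
    left_pts = np.stack(
        [np.interp(st, sp, plug_line[:, 0]), np.interp(st, sp, plug_line[:, 1])], axis=1
    )  # left_pts[0] = E ... left_pts[neta] = A
    left_pts[-1, 0] = 0.0

    # assemble loop order: bottom(i=0..nxi), right(j=1..neta),
    # top(i=nxi-1..0), left(j=neta-1..1)
    pos = np.zeros((P, 2))
    pos[: nxi + 1] = bottom
    pos[nxi + 1 : nxi + 1 + neta] = free_pts[1 : neta + 1]
    pos[nxi + 1 + neta : 2 * nxi + neta + 1] = free_pts[neta + 1 :]
    # left column j=neta-1..1 -> plug surface points between E and A
    pos[2 * nxi + neta + 1 :] = left_pts[1:neta]

    tags = np.empty(P, dtype=int)
    tags[:k] = AXIS
    tags[k : k + n_c] = CONTACT
    tags[k + n_c : 2 * nxi + neta] = FREE
    tags[2 * nxi + neta :] = REAR
    return pos, tags


def _layout_dispatch(mesh_layout: str):
    return _layout_perimeter_shell if mesh_layout == "shell" else _layout_perimeter


def smooth_free_boundary(mesh: Mesh, passes: int = 2, lam: float = 0.35) -> Mesh:
    """Gentle Laplacian smoothing of the free-membrane polyline.

    Used only as a remesh-failure fallback: it stands in for the
    tension-driven smoothing of sub-element membrane kinks that the coarse
    quasi-static solve cannot resolve.  Junction nodes (rim, plug) and all
    non-free nodes stay fixed; the subsequent global volume correction
    absorbs the (tiny) enclosed-volume change.
    """
    out = mesh.copy()
    loop = out.perimeter_nodes
    tags = out.node_tags()
    P = len(loop)
    for _ in range(max(1, passes)):
        coords = out.coords
        new = coords.copy()
        for p in range(P):
            nd = loop[p]
            if tags[nd] != FREE:
                continue
            prev_nd = loop[p - 1]
            next_nd = loop[(p + 1) % P]
            mid = 0.5 * (coords[prev_nd] + coords[next_nd])
            new[nd] = (1.0 - lam) * coords[nd] + lam * mid
        out.coords = new
    return out


def _apply_perimeter(mesh: Mesh, pos: np.ndarray, tags: np.ndarray):
    mesh.coords[mesh.perimeter_nodes] = pos
    mesh.seg_tags = tags


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_initial_mesh(
    cell_radius: float,
    target: TargetSphere,
    initial_contact_angle: float,
    resolution: float = 1.0,
    plug_radius: float = 0.9,
    plug_depth: float = 0.8,
    layout: str = "shell",
) -> tuple[Mesh, TargetSphere]:
    """Construct a near-spherical cell touching the target on the axis.

    The cell is a sphere of ``cell_radius`` centred at the origin, held at
    the rear on a rigid pipette plug (radius ``plug_radius``, reaching
    ``plug_depth`` into the cell); the target sphere is placed on the +z
    axis so that the rim of the initial contact patch (polar extent
    ``initial_contact_angle``) lies on the cell surface.
    """
    R_c, R_t = float(cell_radius), float(target.radius)
    if not (R_c > R_t > 0.0):
        raise GeometryError(f"need cell_radius > target radius > 0, got {R_c}, {R_t}")
    n_rad = int(round(_MIN_ETA * resolution))
    if n_rad < _MIN_ETA:
        raise ConfigurationError(
            f"resolution {resolution} gives {n_rad} elements across the radius; minimum is {_MIN_ETA}"
        )
    if layout == "shell":
        nxi, neta = _XI_PER_ETA * n_rad, n_rad
    else:
        nxi, neta = n_rad, _XI_PER_ETA * n_rad
    phi0 = float(initial_contact_angle)
    if phi0 < 0 or phi0 > math.pi / 2:
        raise ConfigurationError("initial contact angle must be in [0, pi/2]")
    if not (0.0 < plug_radius < 0.5 * R_c):
        raise ConfigurationError("plug radius must be positive and well below the cell radius")

    z_t = R_t * math.cos(phi0) + math.sqrt(R_c**2 - (R_t * math.sin(phi0)) ** 2)
    tgt = replace(target, center_z=z_t, phi_max=phi0)
    if tgt.contact_pole_z <= 0.0:
        raise GeometryError("target overlaps the cell center")

    z_junction = -math.sqrt(R_c**2 - plug_radius**2)
    plug = (plug_radius, z_junction, plug_depth)

    # free membrane: cell-sphere arc from the contact rim to the plug junction
    if phi0 > 0:
        rim_r, rim_z = tgt.surface_point(phi0)
        psi_rim = math.atan2(rim_r, rim_z)
    else:
        psi_rim = 0.0
    psi_junction = math.pi - math.asin(plug_radius / R_c)
    psi = np.linspace(psi_rim, psi_junction, 200 * max(1, int(resolution)))
    membrane = np.stack([R_c * np.sin(psi), R_c * np.cos(psi)], axis=1)

    mesh = Mesh(
        coords=np.zeros(((nxi + 1) * (neta + 1), 2)),
        nxi=nxi,
        neta=neta,
        seg_tags=np.zeros(2 * (nxi + neta), dtype=int),
        plug=plug,
        layout=layout,
    )
    pos, tags = _layout_dispatch(layout)(nxi, neta, tgt, phi0, membrane, plug)
    _apply_perimeter(mesh, pos, tags)
    mesh = reposition_interior(mesh, init_tfi=True)
    mesh.check_valid()
    return mesh, tgt


def courant_timestep(mesh: Mesh, v_network: np.ndarray, cfl: float, dt_max: float) -> float:
    """Advective timestep bound: min over elements of edge length / local speed."""
    if not (0.0 < cfl <= 1.0):
        raise ConfigurationError("cfl must be in (0, 1]")
    if dt_max <= 0.0:
        raise ConfigurationError("dt_max must be positive")
    v = np.asarray(v_network, float)
    if not np.all(np.isfinite(v)):
        raise NumericalError("non-finite velocities in Courant estimate")
    q = mesh.quads
    x = mesh.coords
    hmin = np.full(len(q), np.inf)
    for e in range(4):
        hmin = np.minimum(hmin, np.linalg.norm(x[q[:, (e + 1) % 4]] - x[q[:, e]], axis=1))
    speed = np.max(np.linalg.norm(v[q], axis=2), axis=1)
    mask = speed > 1e-14
    if not np.any(mask):
        return float(dt_max)
    return float(min(dt_max, cfl * np.min(hmin[mask] / speed[mask])))


def distortion_timestep(mesh: Mesh, v_network: np.ndarray, cfl: float, dt_max: float) -> float:
    """Mesh-distortion timestep bound: min over element edges of
    edge length / relative edge velocity.

    Rigid translation does not distort elements, so this bound is much less
    restrictive than the advective Courant bound when thin elements move
    fast but nearly rigidly (the cup wall); the simulation loop uses it
    together with a cap on target travel per step.
    """
    v = np.asarray(v_network, float)
    if not np.all(np.isfinite(v)):
        raise NumericalError("non-finite velocities in distortion estimate")
    q = mesh.quads
    x = mesh.coords
    dt_best = dt_max
    for e in range(4):
        a, b = q[:, e], q[:, (e + 1) % 4]
        L = np.linalg.norm(x[b] - x[a], axis=1)
        dv = np.linalg.norm(v[b] - v[a], axis=1)
        mask = dv > 1e-14
        if np.any(mask):
            dt_best = min(dt_best, float(cfl * np.min(L[mask] / dv[mask])))
    return dt_best


def advect_boundary(mesh: Mesh, v_network: np.ndarray, dt: float) -> Mesh:
    """Advect boundary nodes with the network flow.

    Axis nodes keep r=0 (they slide along the axis), rear-hold nodes are
    pinned, and tags are preserved.  Interior nodes are left untouched; the
    caller repositions them afterwards.
    """
    out = mesh.copy()
    tags = mesh.node_tags()
    loop = mesh.perimeter_nodes
    for nd in loop:
        tg = tags[nd]
        if tg == REAR:
            continue
        out.coords[nd] = mesh.coords[nd] + dt * v_network[nd]
        if tg == AXIS:
            out.coords[nd, 0] = 0.0
    out.coords[:, 0] = np.maximum(out.coords[:, 0], 0.0)
    return out


_harmonic_cache: dict = {}


def _harmonic_factor(nxi: int, neta: int):
    """Cached factorization of the interior 5-point Laplacian (logical grid)."""
    key = (nxi, neta)
    if key not in _harmonic_cache:
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        ni, nj = nxi - 1, neta - 1          # interior grid
        n = ni * nj
        idx = lambda i, j: (j - 1) * ni + (i - 1)
        rows, cols, vals = [], [], []
        bnd = []                            # (interior_idx, boundary node (i,j))
        for j in range(1, neta):
            for i in range(1, nxi):
                me = idx(i, j)
                rows.append(me); cols.append(me); vals.append(4.0)
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 1 <= ii <= nxi - 1 and 1 <= jj <= neta - 1:
                        rows.append(me); cols.append(idx(ii, jj)); vals.append(-1.0)
                    else:
                        bnd.append((me, ii, jj))
        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        _harmonic_cache[key] = (spla.factorized(A), bnd)
    return _harmonic_cache[key]


def _tfi_interior(grid: np.ndarray, nxi: int, neta: int) -> np.ndarray:
    """Transfinite interpolation of the interior from the four logical edges."""
    s = (np.arange(nxi + 1) / nxi)[None, :, None]
    t = (np.arange(neta + 1) / neta)[:, None, None]
    B = grid[0, :, :][None, :, :]
    T = grid[neta, :, :][None, :, :]
    L = grid[:, 0, :][:, None, :]
    R = grid[:, nxi, :][:, None, :]
    out = (
        (1 - t) * B + t * T + (1 - s) * L + s * R
        - ((1 - s) * (1 - t) * grid[0, 0] + s * (1 - t) * grid[0, nxi]
           + (1 - s) * t * grid[neta, 0] + s * t * grid[neta, nxi])
    )
    out[0, :] = grid[0, :]
    out[neta, :] = grid[neta, :]
    out[:, 0] = grid[:, 0]
    out[:, nxi] = grid[:, nxi]
    return out


def reposition_interior(mesh: Mesh, init_tfi: bool = False, n_smooth: int = 8) -> Mesh:
    """Rebuild interior nodes from the boundary.

    Two interior constructions are attempted - transfinite interpolation
    (which respects the edge parameterizations and threads thin channels)
    and discrete-harmonic coordinates (a direct sparse solve, robust on
    smoothly-varying regions) - each polished by under-relaxed smoothing
    with a fold guard; the best-quality configuration wins.  Topology,
    boundary geometry and tags are unchanged; the minimum element quality is
    never decreased relative to the input (the input interior is kept if
    nothing better is found).
    """
    out = mesh.copy()
    nxi, neta = mesh.nxi, mesh.neta
    grid0 = out.coords.reshape(neta + 1, nxi + 1, 2)

    candidates = []
    if not init_tfi:
        candidates.append((mesh.min_scaled_jacobian(), mesh.coords.copy()))

    def record(w):
        out.coords = w.reshape(-1, 2).copy()
        candidates.append((out.min_scaled_jacobian(), out.coords.copy()))

    def polish(init):
        work = init.copy()
        record(work)
        for _ in range(n_smooth):
            nb = (
                work[:-2, 1:-1] + work[2:, 1:-1] + work[1:-1, :-2] + work[1:-1, 2:]
            ) / 6.0 + (
                work[:-2, :-2] + work[:-2, 2:] + work[2:, :-2] + work[2:, 2:]
            ) / 12.0
            work[1:-1, 1:-1] = 0.5 * work[1:-1, 1:-1] + 0.5 * nb
            record(work)

    # candidate 1: transfinite interpolation
    polish(_tfi_interior(grid0, nxi, neta))
    # candidate 2: discrete-harmonic coordinates (only worth the solve if
    # the TFI-based interior is marginal)
    if max(c[0] for c in candidates) < 0.08:
        solve, bnd = _harmonic_factor(nxi, neta)
        b = np.zeros(((nxi - 1) * (neta - 1), 2))
        for me, ii, jj in bnd:
            b[me] += grid0[jj, ii]
        harm = grid0.copy()
        harm[1:neta, 1:nxi] = np.stack(
            [solve(b[:, 0]), solve(b[:, 1])], axis=1
        ).reshape(neta - 1, nxi - 1, 2)
        polish(harm)

    # Winslow (inverse-harmonic) relaxation from the best configuration so
    # far: the continuum Winslow map of a convex logical domain is fold-free,
    # and its grids bend around concave obstacles (the engulfed target)
    # where plain harmonic/TFI interiors fold
    best_q, best_c = max(candidates, key=lambda c: c[0])
    work = best_c.reshape(neta + 1, nxi + 1, 2).copy()
    for _ in range(150):
        xE, xW = work[1:-1, 2:], work[1:-1, :-2]
        xN, xS = work[2:, 1:-1], work[:-2, 1:-1]
        xNE, xNW = work[2:, 2:], work[2:, :-2]
        xSE, xSW = work[:-2, 2:], work[:-2, :-2]
        x_xi = 0.5 * (xE - xW)
        x_eta = 0.5 * (xN - xS)
        al = np.sum(x_eta * x_eta, axis=-1, keepdims=True)
        ga = np.sum(x_xi * x_xi, axis=-1, keepdims=True)
        be = np.sum(x_xi * x_eta, axis=-1, keepdims=True)
        rhs = al * (xE + xW) + ga * (xN + xS) - 0.5 * be * (xNE - xNW - xSE + xSW)
        upd = rhs / np.maximum(2.0 * (al + ga), 1e-300)
        work[1:-1, 1:-1] = 0.2 * work[1:-1, 1:-1] + 0.8 * upd
    record(work)

    best_q, best_c = max(candidates, key=lambda c: c[0])
    if best_q <= 0.0:
        # targeted local untangling: Gauss-Seidel sweeps restricted to the
        # neighbourhood of folded elements
        out.coords = best_c
        fixed = _untangle_local(out)
        if fixed is not None:
            best_c = fixed
            out.coords = fixed
            best_q = out.min_scaled_jacobian()
    out.coords = best_c
    out.generation = mesh.generation + 1
    if best_q <= 0.0:
        raise RemeshError(f"smoothing could not untangle mesh (min quality {best_q:.3g})")
    return out


def _untangle_local(mesh: Mesh, max_sweeps: int = 120) -> np.ndarray | None:
    """Local fold repair: repeatedly replace interior nodes of inverted
    elements (and their logical neighbours) by their 8-neighbour centroid.
    Returns repaired coordinates or None if the fold persists."""
    nxi, neta = mesh.nxi, mesh.neta
    grid = mesh.coords.reshape(neta + 1, nxi + 1, 2).copy()
    work = Mesh(coords=grid.reshape(-1, 2), nxi=nxi, neta=neta,
                seg_tags=mesh.seg_tags, plug=mesh.plug)
    for _ in range(max_sweeps):
        cj = work.corner_jacobians().min(axis=1)
        bad = np.where(cj <= 0.0)[0]
        if len(bad) == 0:
            return grid.reshape(-1, 2)
        nodes = set()
        for e in bad:
            i, j = divmod(e, neta)
            for di in range(-1, 3):
                for dj in range(-1, 3):
                    ii, jj = i + di, j + dj
                    if 1 <= ii <= nxi - 1 and 1 <= jj <= neta - 1:
                        nodes.add((ii, jj))
        for (ii, jj) in nodes:
            nb = (
                grid[jj - 1, ii] + grid[jj + 1, ii] + grid[jj, ii - 1] + grid[jj, ii + 1]
            ) / 6.0 + (
                grid[jj - 1, ii - 1] + grid[jj - 1, ii + 1]
                + grid[jj + 1, ii - 1] + grid[jj + 1, ii + 1]
            ) / 12.0
            grid[jj, ii] = 0.3 * grid[jj, ii] + 0.7 * nb
        work.coords = grid.reshape(-1, 2)
    return None


def correct_volume(mesh: Mesh, V_target: float, max_step: float = 0.01) -> Mesh:
    """Nudge free-membrane nodes along their outward normals by a uniform
    distance (capped at ``max_step`` µm) to pull the enclosed volume back
    toward ``V_target``, compensating the slow geometric drift of boundary
    resampling.  Rebuilds the interior afterwards."""
    V = mesh.enclosed_volume()
    segs = mesh.perimeter_segments()
    free = np.where(mesh.seg_tags == FREE)[0]
    if len(free) == 0:
        return mesh
    a = mesh.coords[segs[free, 0]]
    b = mesh.coords[segs[free, 1]]
    d = b - a
    L = np.maximum(np.linalg.norm(d, axis=1), 1e-300)
    area = 2 * math.pi * 0.5 * (a[:, 0] + b[:, 0]) * L
    A_free = float(np.sum(area))
    delta = float(np.clip((V_target - V) / max(A_free, 1e-12), -max_step, max_step))
    if abs(delta) < 1e-9:
        return mesh
    out = mesh.copy()
    tags = mesh.node_tags()
    n_out = np.stack([-d[:, 1] / L, d[:, 0] / L], axis=1)
    disp = np.zeros_like(mesh.coords)
    cnt = np.zeros(mesh.n_nodes)
    for kk in range(2):
        np.add.at(disp, segs[free, kk], n_out)
        np.add.at(cnt, segs[free, kk], 1.0)
    sel = (cnt > 0) & (tags == FREE)
    disp[sel] /= cnt[sel, None]
    norm = np.maximum(np.linalg.norm(disp[sel], axis=1), 1e-300)
    out.coords[sel] += delta * disp[sel] / norm[:, None]
    out.coords[:, 0] = np.maximum(out.coords[:, 0], 0.0)
    return reposition_interior(out, init_tfi=False)


def leading_free_nodes(mesh: Mesh) -> np.ndarray:
    """Free-membrane boundary nodes in walk order from just past the cup rim
    toward the rear band (node after the rim first)."""
    free_segs = np.where(mesh.seg_tags == FREE)[0]
    loop = mesh.perimeter_nodes
    nodes = loop[(free_segs + 1) % len(loop)]
    tags = mesh.node_tags()
    return nodes[tags[nodes] == FREE]


def relayout(mesh: Mesh, target: TargetSphere, n_adhered_free: int = 0) -> Mesh:
    """Redistribute boundary nodes for the current adhered arc and rebuild the
    interior.  ``n_adhered_free`` leading free-membrane nodes (counted from the
    rim) have newly adhered and are absorbed into the contact arc.
    """
    loop = mesh.perimeter_nodes
    # free-membrane polyline from just past the rim to the pipette junction
    free_segs = np.where(mesh.seg_tags == FREE)[0]
    first_free = free_segs[0] if len(free_segs) else mesh.nxi
    last_free = free_segs[-1] if len(free_segs) else mesh.nxi + mesh.neta - 1
    memb_idx = loop[first_free + 1 : last_free + 2]
    membrane = mesh.coords[memb_idx]
    if n_adhered_free > 0:
        membrane = membrane[n_adhered_free:]
    rim_r, rim_z = target.surface_point(target.phi_max)
    membrane = np.vstack([[rim_r, rim_z], membrane])

    prev_nc = int(np.sum(mesh.seg_tags == CONTACT))
    out = mesh.copy()

    # staged redistribution: a large capture event (several degrees of arc
    # adhering in one step) moves every boundary node at once; walking the
    # rim over intermediate arcs lets the interior smoother keep up
    phi_prev = target.phi_max
    contact_segs = np.where(mesh.seg_tags == CONTACT)[0]
    if len(contact_segs):
        rim_old = mesh.coords[loop[contact_segs[-1] + 1]]
        phi_prev = float(target.polar_angle(rim_old[0], rim_old[1]))
    dphi = target.phi_max - phi_prev
    n_stage = max(1, int(math.ceil(dphi / 0.06)))
    for k in range(1, n_stage):
        phi_k = phi_prev + dphi * k / n_stage
        arc = np.linspace(phi_k, target.phi_max, 8)
        ar, az = target.surface_point(arc)
        memb_k = np.vstack([np.stack([ar, az], axis=1), membrane[1:]])
        tgt_k = replace(target, phi_max=phi_k)
        pos, tags = _layout_dispatch(mesh.layout)(
            mesh.nxi, mesh.neta, tgt_k, phi_k, memb_k, mesh.plug,
            min_contact_segments=prev_nc,
        )
        _apply_perimeter(out, pos, tags)
        out = reposition_interior(out, init_tfi=False)
        prev_nc = int(np.sum(out.seg_tags == CONTACT))

    pos, tags = _layout_dispatch(mesh.layout)(
        mesh.nxi,
        mesh.neta,
        target,
        target.phi_max,
        membrane,
        mesh.plug,
        min_contact_segments=prev_nc,
    )
    _apply_perimeter(out, pos, tags)
    out = reposition_interior(out, init_tfi=False if n_stage > 1 else True)
    return out


# ---------------------------------------------------------------------------
# field remap (Eulerian-Lagrangian, upwind)
# ---------------------------------------------------------------------------

def remap_fields(
    old_mesh: Mesh,
    new_mesh: Mesh,
    fields: FieldState,
    v_network: np.ndarray | None = None,
    v_solvent: np.ndarray | None = None,
    dt: float = 0.0,
    include_velocities: bool = True,
) -> FieldState:
    """Transfer fields from ``old_mesh`` to ``new_mesh`` (same topology).

    The element-wise network fraction is remapped with a conservative,
    monotone first-order upwind flux scheme built from exact swept volumes
    (so that network mass is conserved to round-off when no material crosses
    the membrane).  Nodal fields use monotone bilinear interpolation with a
    semi-Lagrangian backtrack for material advection and a mass fix-up for
    the messenger.
    """
    if old_mesh.nxi != new_mesh.nxi or old_mesh.neta != new_mesh.neta:
        raise ConfigurationError("remap requires meshes of identical topology")

    out = fields.copy()
    out.theta = _remap_theta(old_mesh, new_mesh, fields.theta, v_network, dt)

    # nodal messenger: interpolate at (possibly backtracked) new node positions
    pts = new_mesh.coords.copy()
    if v_solvent is not None and dt > 0.0:
        pts = pts - dt * v_solvent
    m_old = fields.messenger
    m_new = _interp_nodal(old_mesh, m_old, pts)
    # conservative fix-up: restore total messenger mass, staying within bounds
    lo, hi = float(m_old.min()), float(m_old.max())
    M_old = _nodal_mass(old_mesh, m_old)
    for _ in range(2):
        M_new = _nodal_mass(new_mesh, m_new)
        if M_new <= 1e-300 or abs(M_new - M_old) < 1e-12 * max(M_old, 1.0):
            break
        m_new = np.clip(m_new * (M_old / M_new), lo, hi)
    out.messenger = m_new

    if include_velocities:
        out.v_network = _interp_nodal(old_mesh, fields.v_network, new_mesh.coords)
        out.v_solvent = _interp_nodal(old_mesh, fields.v_solvent, new_mesh.coords)
    return out


def _nodal_mass(mesh: Mesh, m: np.ndarray) -> float:
    """∫ m dV with element-averaged nodal values (consistent with P0 volumes)."""
    q = mesh.quads
    return float(np.sum(mesh.element_volumes() * np.mean(m[q], axis=1)))


def _remap_theta(old_mesh, new_mesh, theta, v_network, dt) -> np.ndarray:
    nxi, neta = old_mesh.nxi, old_mesh.neta
    th = theta.reshape(nxi, neta)          # element (i, j) at flat index i*neta+j
    V_old = old_mesh.element_volumes().reshape(nxi, neta)
    V_new = new_mesh.element_volumes().reshape(nxi, neta)
    M = th * V_old

    xo, xn = old_mesh.coords, new_mesh.coords
    if v_network is None or dt == 0.0:
        v = np.zeros_like(xo)
        dt_eff = 1.0
    else:
        v = np.asarray(v_network, float)
        dt_eff = dt

    def face_flux(a_idx, b_idx):
        """Outward (owner-side) material-minus-mesh volume flux through the
        directed face a->b (direction as traversed in the owner's CCW loop)."""
        ao, bo = xo[a_idx], xo[b_idx]
        an, bn = xn[a_idx], xn[b_idx]
        # mesh sweep outward = -(signed revolved volume of the closed path
        # a_old -> b_old -> b_new -> a_new)
        sweep = (
            _revolved_contour_vec(ao, bo)
            + _revolved_contour_vec(bo, bn)
            + _revolved_contour_vec(bn, an)
            + _revolved_contour_vec(an, ao)
        )
        mesh_out = -sweep
        # material flux through mid-step face geometry
        am, bm = 0.5 * (ao + an), 0.5 * (bo + bn)
        d = bm - am
        L = np.linalg.norm(d, axis=-1)
        n_r = d[..., 1] / np.maximum(L, 1e-300)
        n_z = -d[..., 0] / np.maximum(L, 1e-300)
        rbar = 0.5 * (am[..., 0] + bm[..., 0])
        vbar = 0.5 * (v[a_idx] + v[b_idx])
        mat_out = dt_eff * (vbar[..., 0] * n_r + vbar[..., 1] * n_z) * 2 * math.pi * rbar * L
        return mat_out - mesh_out

    node = lambda i, j: j * (nxi + 1) + i

    # faces in the i-direction: owner (i, j), neighbour (i+1, j); owner edge is
    # node(i+1, j+1) -> node(i+1, j)
    i = np.arange(nxi - 1)
    j = np.arange(neta)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    a = node(ii + 1, jj + 1)
    b = node(ii + 1, jj)
    F = face_flux(a.ravel(), b.ravel()).reshape(nxi - 1, neta)
    up = np.where(F > 0, th[:-1, :], th[1:, :])
    M[:-1, :] -= up * F
    M[1:, :] += up * F

    # faces in the j-direction: owner (i, j), neighbour (i, j+1); owner edge is
    # node(i, j+1) -> node(i+1, j+1)
    i = np.arange(nxi)
    j = np.arange(neta - 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    a = node(ii, jj + 1)
    b = node(ii + 1, jj + 1)
    F = face_flux(a.ravel(), b.ravel()).reshape(nxi, neta - 1)
    up = np.where(F > 0, th[:, :-1], th[:, 1:])
    M[:, :-1] -= up * F
    M[:, 1:] += up * F

    th_new = M / np.maximum(V_new, 1e-300)
    return np.clip(th_new, 0.0, None).reshape(-1)


def _interp_nodal(old_mesh: Mesh, values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Monotone bilinear interpolation of nodal values at arbitrary points.

    Vectorized Newton inversion of the bilinear map over candidate elements
    (nearest centroids); falls back to the nearest-node value outside the
    mesh.  Reference coordinates are clipped to the element, so every result
    is a convex combination of nodal values (no new extrema).
    """
    from scipy.spatial import cKDTree

    x = old_mesh.coords
    q = old_mesh.quads
    centroids = x[q].mean(axis=1)
    k = min(6, len(q))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = cand.reshape(len(points), k)
    _, nearest = cKDTree(x).query(points)

    vals = values if values.ndim > 1 else values[:, None]
    out = vals[nearest].astype(float).copy()      # fallback: nearest node
    P = len(points)
    todo = np.arange(P)

    for c in range(k):
        if len(todo) == 0:
            break
        e = cand[todo, c]
        xe = x[q[e]]                              # (n, 4, 2)
        pt = points[todo]
        xi = np.zeros((len(todo), 2))
        for _ in range(8):
            om, op = 1 - xi[:, 0], 1 + xi[:, 0]
            em, ep = 1 - xi[:, 1], 1 + xi[:, 1]
            N = 0.25 * np.stack([om * em, op * em, op * ep, om * ep], axis=1)
            dNdx = 0.25 * np.stack([-em, em, ep, -ep], axis=1)
            dNdy = 0.25 * np.stack([-om, -op, op, om], axis=1)
            resid = np.einsum("na,nai->ni", N, xe) - pt
            J00 = np.einsum("na,na->n", dNdx, xe[:, :, 0])
            J01 = np.einsum("na,na->n", dNdy, xe[:, :, 0])
            J10 = np.einsum("na,na->n", dNdx, xe[:, :, 1])
            J11 = np.einsum("na,na->n", dNdy, xe[:, :, 1])
            det = J00 * J11 - J01 * J10
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            xi[:, 0] -= (J11 * resid[:, 0] - J01 * resid[:, 1]) / det
            xi[:, 1] -= (-J10 * resid[:, 0] + J00 * resid[:, 1]) / det
        ok = np.max(np.abs(xi), axis=1) <= 1.05
        if np.any(ok):
            sel = todo[ok]
            xic = np.clip(xi[ok], -1.0, 1.0)
            om, op = 1 - xic[:, 0], 1 + xic[:, 0]
            em, ep = 1 - xic[:, 1], 1 + xic[:, 1]
            N = 0.25 * np.stack([om * em, op * em, op * ep, om * ep], axis=1)
            out[sel] = np.einsum("na,nak->nk", N, vals[q[e[ok]]])
        todo = todo[~ok]
    return out if values.ndim > 1 else out[:, 0]


def _q1_shape(xi, eta):
    return 0.25 * np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )


def _inverse_bilinear(xe: np.ndarray, pt: np.ndarray, tol: float = 1.05):
    """Reference coordinates of ``pt`` in quad ``xe`` (4x2), or None if outside."""
    xi = np.zeros(2)
    for _ in range(12):
        N = _q1_shape(xi[0], xi[1])
        resid = N @ xe - pt
        dN_dxi = 0.25 * np.array(
            [-(1 - xi[1]), (1 - xi[1]), (1 + xi[1]), -(1 + xi[1])]
        )
        dN_deta = 0.25 * np.array(
            [-(1 - xi[0]), -(1 + xi[0]), (1 + xi[0]), (1 - xi[0])]
        )
        J = np.array([dN_dxi @ xe, dN_deta @ xe]).T
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        if abs(det) < 1e-300:
            return None
        step = np.array(
            [J[1, 1] * resid[0] - J[0, 1] * resid[1], -J[1, 0] * resid[0] + J[0, 0] * resid[1]]
        ) / det
        xi -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    if np.max(np.abs(xi)) <= tol:
        return xi
    return None
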