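"""Two-phase (cytoskeleton + cytosol) Stokes solver and messenger transport.

The cytoplasm is an interpenetrating mixture of a viscous cytoskeletal
network (volume fraction theta) and a low-viscosity cytosol.  In the creeping
flow regime the momentum balances are

    0 = div(2 mu_n e(v_n) + lam_n div v_n I) - theta grad p - H (v_n - v_s) + f_n
    0 = div(2 mu_s e(v_s) + lam_s div v_s I) - (1-theta) grad p + H (v_n - v_s)

with mixture incompressibility div(theta v_n + (1-theta) v_s) = 0.  The
network viscosity is linear in theta and scaled by a global stimulation
factor; the cytosol is a near-inviscid filler.  Discretization: bilinear
(Q1) velocities for both phases, piecewise-constant (P0) pressure with
inter-element jump stabilization, axisymmetric (r, z) weak forms.  Membrane
tension enters as the exact gradient of the discrete free-surface energy;
disjoining (protrusive) and membrane-cytoskeleton attraction stresses enter
as equal-and-opposite normal traction pairs across the membrane-adjacent
element layer.  Adhered boundary nodes move rigidly with the target; the
axial target velocity is an extra unknown whose equation is the axial force
balance on the (massless) target.

Units: µm, s, pN; stresses pN/µm² (= Pa), tensions pN/µm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, NumericalError
from .mesh import AXIS, CONTACT, FREE, REAR, Mesh
from .state import FieldState

__all__ = [
    "ConstitutiveParams",
    "FieldState",
    "MomentumSolution",
    "viscosity_of",
    "solve_momentum",
    "step_messenger",
    "interconvert_phases",
]

_GP = 1.0 / math.sqrt(3.0)
_GAUSS = [(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)]


@dataclass
class ConstitutiveParams:
    """Material and kinetic parameters of the two-phase cytoplasm.

    The absolute magnitudes are calibration targets (fixed so that the
    antibody scenario reproduces its observed engulfment duration); the
    scenario switchboard then only toggles effectors, never these values.
    """

    mu_solvent: float = 10.0          # cytosol viscosity, pN s/µm²
    mu_network_0: float = 2.5e4       # network viscosity per unit theta, pN s/µm²
    bulk_ratio: float = 1.0           # network bulk/shear viscosity ratio
    drag_coeff: float = 1.0e5         # interphase friction scale, pN s/µm⁴
    k_poly: float = 0.7               # polymerization rate per messenger unit, 1/(a.u. s)
    k_depoly: float = 1.0             # depolymerization rate, 1/s
    theta_base: float = 0.02          # resting network fraction
    theta_max: float = 0.5            # maximum packing fraction
    D_m: float = 1.0                  # messenger diffusivity, µm²/s
    k_decay: float = 2.0              # messenger decay, 1/s
    source_strength: float = 2.0      # messenger production flux, a.u. µm/s
    sigma_protrude: float = 6.0e3     # disjoining stress per unit theta, pN/µm²
    sigma_attract: float = 1.0e3      # membrane-cytoskeleton attraction stress, pN/µm²
    sigma_adhesion: float = 6.0e3     # contact-line capture stress, pN/µm²
    capture_range: float = 0.65       # adhesion capture range ahead of the rim, µm
    stab_alpha: float = 0.2           # pressure jump-stabilization coefficient

    def validate(self):
        for name in (
            "mu_solvent", "mu_network_0", "drag_coeff", "k_poly", "k_depoly",
            "theta_base", "D_m", "k_decay", "source_strength",
            "sigma_protrude", "sigma_attract",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"parameter {name} must be non-negative")
        if not (0.0 <= self.theta_base < self.theta_max < 1.0):
            raise ConfigurationError("need 0 <= theta_base < theta_max < 1")
        if self.mu_solvent >= self.mu_network_0 * self.theta_base:
            raise ConfigurationError(
                "network must dominate dissipation (mu_solvent << mu_network_0*theta_base)"
            )


def viscosity_of(theta: np.ndarray, stimulation_factor: float, params: ConstitutiveParams) -> np.ndarray:
    """Network shear viscosity, linear in theta and in the stimulation factor."""
    th = np.asarray(theta, float)
    if np.any(th < 0):
        raise ConfigurationError("negative network fraction")
    if stimulation_factor < 1.0:
        raise ConfigurationError("stimulation_factor must be >= 1")
    return stimulation_factor * params.mu_network_0 * th


@dataclass
class MomentumSolution:
    v_network: np.ndarray
    v_solvent: np.ndarray
    pressure: np.ndarray
    target_velocity: float | None
    residual: float
    target_applied_force: float = 0.0   # axial force from applied interface stresses, pN


# ---------------------------------------------------------------------------
# element operators (geometry-dependent, rebuilt per mesh)
# ---------------------------------------------------------------------------

def element_operators(mesh: Mesh) -> dict:
    xe = mesh.coords[mesh.quads]  # (M, 4, 2)
    M = len(xe)
    K_shear = np.zeros((M, 8, 8))
    K_bulk = np.zeros((M, 8, 8))
    Me = np.zeros((M, 4, 4))
    dvec = np.zeros((M, 8))
    Kdiff = np.zeros((M, 4, 4))
    Mlump = np.zeros((M, 4))
    vol = np.zeros(M)

    for (gx, gy) in _GAUSS:
        N = 0.25 * np.array(
            [(1 - gx) * (1 - gy), (1 + gx) * (1 - gy), (1 + gx) * (1 + gy), (1 - gx) * (1 + gy)]
        )
        dNdxi = 0.25 * np.array([-(1 - gy), (1 - gy), (1 + gy), -(1 + gy)])
        dNdeta = 0.25 * np.array([-(1 - gx), -(1 + gx), (1 + gx), (1 - gx)])
        J11 = xe[:, :, 0] @ dNdxi
        J12 = xe[:, :, 0] @ dNdeta
        J21 = xe[:, :, 1] @ dNdxi
        J22 = xe[:, :, 1] @ dNdeta
        det = J11 * J22 - J12 * J21
        inv11 = J22 / det
        inv12 = -J12 / det
        inv21 = -J21 / det
        inv22 = J11 / det
        # dN/dr, dN/dz  (M, 4)
        dNdr = np.outer(inv11, dNdxi).reshape(len(xe), 4) + np.outer(inv21, dNdeta).reshape(len(xe), 4)
        dNdz = np.outer(inv12, dNdxi).reshape(len(xe), 4) + np.outer(inv22, dNdeta).reshape(len(xe), 4)
        r_g = xe[:, :, 0] @ N
        wdet = det * 2 * math.pi * r_g
        Nr = N[None, :] / np.maximum(r_g[:, None], 1e-12)

        zero = np.zeros_like(dNdr)
        B_rr = np.concatenate([dNdr, zero], axis=1)
        B_zz = np.concatenate([zero, dNdz], axis=1)
        B_tt = np.concatenate([Nr, zero], axis=1)
        B_rz = np.concatenate([dNdz, dNdr], axis=1)
        Bdiv = np.concatenate([dNdr + Nr, dNdz], axis=1)

        w = wdet[:, None, None]
        K_shear += w * (
            2 * np.einsum("mi,mj->mij", B_rr, B_rr)
            + 2 * np.einsum("mi,mj->mij", B_zz, B_zz)
            + 2 * np.einsum("mi,mj->mij", B_tt, B_tt)
            + np.einsum("mi,mj->mij", B_rz, B_rz)
        )
        K_bulk += w * np.einsum("mi,mj->mij", Bdiv, Bdiv)
        Me += w * np.einsum("i,j->ij", N, N)[None, :, :]
        dvec += wdet[:, None] * Bdiv
        Kdiff += w * (
            np.einsum("mi,mj->mij", dNdr, dNdr) + np.einsum("mi,mj->mij", dNdz, dNdz)
        )
        Mlump += wdet[:, None] * N[None, :]
        vol += wdet

    return dict(
        K_shear=K_shear, K_bulk=K_bulk, Me=Me, dvec=dvec,
        Kdiff=Kdiff, Mlump=Mlump, vol=vol,
    )


# ---------------------------------------------------------------------------
# boundary force assembly helpers
# ---------------------------------------------------------------------------

def _segment_geometry(mesh: Mesh, reaction_depth: int = 2):
    """Per perimeter segment: node pair, length, mean radius, outward normal,
    lateral (revolved) area, and the two element nodes opposite the segment."""
    segs = mesh.perimeter_segments()
    a = mesh.coords[segs[:, 0]]
    b = mesh.coords[segs[:, 1]]
    d = b - a
    L = np.linalg.norm(d, axis=1)
    Ls = np.maximum(L, 1e-300)
    # perimeter loop is clockwise in (r, z): outward normal = (-dz, dr)/L
    n_out = np.stack([-d[:, 1] / Ls, d[:, 0] / Ls], axis=1)
    rbar = 0.5 * (a[:, 0] + b[:, 0])
    area = 2 * math.pi * rbar * L
    opp = _opposite_nodes(mesh, reaction_depth)
    return segs, L, rbar, n_out, area, opp


def _opposite_nodes(mesh: Mesh, depth: int = 1) -> np.ndarray:
    """For each perimeter segment, the two nodes of the adjacent quad column
    that lie ``depth`` layers into the interior (used to apply
    reaction-force pairs across the membrane-adjacent interaction layer)."""
    nxi, neta = mesh.nxi, mesh.neta
    P = mesh.n_perimeter
    segs = mesh.perimeter_segments()
    opp = np.empty((P, 2), dtype=int)
    row = nxi + 1
    d_bot = min(depth, neta - 1)
    d_side = min(depth, nxi - 1)
    for p in range(P):
        if p < nxi:                       # bottom edge -> shift up rows
            opp[p] = segs[p] + d_bot * row
        elif p < nxi + neta:              # right column -> shift left
            opp[p] = segs[p] - d_side
        elif p < 2 * nxi + neta:          # top row -> shift down
            opp[p] = segs[p] - d_bot * row
        else:                             # left column -> shift right
            opp[p] = segs[p] + d_side
    return opp


def tension_forces(mesh: Mesh, gamma: float) -> np.ndarray:
    """Nodal forces (N, 2) from membrane tension: exact negative gradient of
    gamma * (free-membrane lateral area) with respect to node positions."""
    f = np.zeros_like(mesh.coords)
    segs = mesh.perimeter_segments()
    free = np.where(mesh.seg_tags == FREE)[0]
    a_idx, b_idx = segs[free, 0], segs[free, 1]
    a = mesh.coords[a_idx]
    b = mesh.coords[b_idx]
    d = b - a
    L = np.maximum(np.linalg.norm(d, axis=1), 1e-300)
    rbar = 0.5 * (a[:, 0] + b[:, 0])
    # dA/dr_a = 2 pi (L/2 + rbar (r_a - r_b)/L); dA/dz_a = 2 pi rbar (z_a - z_b)/L
    two_pi = 2 * math.pi
    np.add.at(f[:, 0], a_idx, -gamma * two_pi * (L / 2 + rbar * (a[:, 0] - b[:, 0]) / L))
    np.add.at(f[:, 1], a_idx, -gamma * two_pi * (rbar * (a[:, 1] - b[:, 1]) / L))
    np.add.at(f[:, 0], b_idx, -gamma * two_pi * (L / 2 + rbar * (b[:, 0] - a[:, 0]) / L))
    np.add.at(f[:, 1], b_idx, -gamma * two_pi * (rbar * (b[:, 1] - a[:, 1]) / L))
    return f


def interface_stress_forces(mesh: Mesh, protrusive: np.ndarray, attraction: np.ndarray):
    """Nodal force fields from disjoining/attraction stress pairs.

    ``protrusive``: outward normal stress per perimeter segment (pN/µm²),
    applied to the membrane.  The disjoining pressure acts across the
    membrane-proximal solvent gap, so its reaction loads the solvent phase
    of the adjacent interior layer (whence it spreads through the pressure
    field) rather than pushing directly against the polymerized network
    that is viscously glued to the membrane.
    ``attraction``: inward stress on the adhered membrane with the reaction
    pulling the adjacent cytoskeletal network toward the membrane.
    Returns (f_network, f_solvent, axial_force_on_membrane) where the axial
    force is the z-integral of the stresses applied to membrane nodes.
    """
    f_n = np.zeros_like(mesh.coords)
    f_s = np.zeros_like(mesh.coords)
    segs, L, rbar, n_out, area, opp = _segment_geometry(mesh)
    prot = np.asarray(protrusive, float)
    attr = np.asarray(attraction, float)
    axial = 0.0
    for p in np.where((prot != 0.0) | (attr != 0.0))[0]:
        if prot[p] != 0.0:
            fv = 0.5 * prot[p] * area[p] * n_out[p]
            f_n[segs[p, 0]] += fv
            f_n[segs[p, 1]] += fv
            f_s[opp[p, 0]] -= fv
            f_s[opp[p, 1]] -= fv
            axial += 2 * fv[1]
        if attr[p] != 0.0:
            fv = 0.5 * attr[p] * area[p] * n_out[p]
            f_n[segs[p, 0]] -= fv
            f_n[segs[p, 1]] -= fv
            f_n[opp[p, 0]] += fv
            f_n[opp[p, 1]] += fv
            axial -= 2 * fv[1]
    return f_n, f_s, axial


# ---------------------------------------------------------------------------
# momentum solve
# ---------------------------------------------------------------------------

_constraint_cache: dict = {}


def _constraint_map(mesh: Mesh, with_target: bool, with_volume: bool = False):
    """Transformation matrix T (full dofs -> reduced dofs) implementing the
    kinematic boundary conditions:

      rear_hold:  v = 0 (both phases)
      axis:       v_r = 0 (both phases)
      contact:    v = w ez (both phases; w = rigid target velocity)
      free membrane: v_solvent = v_network (impermeable, no-slip membrane)
    """
    N = mesh.n_nodes
    M = mesh.n_elements
    tags = mesh.node_tags()
    nfull = 4 * N + M + (1 if with_target else 0) + (1 if with_volume else 0)

    red_of = {}
    rows, cols, vals = [], [], []
    nred = 0

    def new_dof():
        nonlocal nred
        nred += 1
        return nred - 1

    w_dof = None
    if with_target:
        w_dof = new_dof()

    vn_map = np.full((N, 2), -1, dtype=int)
    for n in range(N):
        tg = tags[n]
        if tg == REAR:
            continue
        if tg == CONTACT:
            if with_target:
                vn_map[n, 1] = w_dof
            continue
        if tg != AXIS:
            vn_map[n, 0] = new_dof()
        vn_map[n, 1] = new_dof()

    vs_map = np.full((N, 2), -1, dtype=int)
    for n in range(N):
        tg = tags[n]
        if tg == REAR:
            continue
        if tg == CONTACT:
            if with_target:
                vs_map[n, 1] = w_dof
            continue
        if tg == FREE:
            vs_map[n] = vn_map[n]
            continue
        if tg != AXIS:
            vs_map[n, 0] = new_dof()
        vs_map[n, 1] = new_dof()

    p_map = np.arange(M) + nred
    nred += M
    if with_volume:
        vol_red = new_dof()

    for n in range(N):
        for c in range(2):
            if vn_map[n, c] >= 0:
                rows.append(c * N + n); cols.append(vn_map[n, c]); vals.append(1.0)
            if vs_map[n, c] >= 0:
                rows.append(2 * N + c * N + n); cols.append(vs_map[n, c]); vals.append(1.0)
    for e in range(M):
        rows.append(4 * N + e); cols.append(p_map[e]); vals.append(1.0)
    if with_volume:
        rows.append(nfull - 1); cols.append(vol_red); vals.append(1.0)

    T = sp.csr_matrix((vals, (rows, cols)), shape=(nfull, nred))
    return T, w_dof, p_map


def solve_momentum(
    mesh: Mesh,
    state: FieldState,
    params: ConstitutiveParams,
    boundary_stresses: dict | None = None,
    tension: float = 0.0,
    stimulation_factor: float = 1.0,
    with_target: bool | None = None,
    volume_rate: float | None = None,
) -> MomentumSolution:
    """Quasi-static solve for pressure and both phase velocities.

    ``boundary_stresses`` may contain per-perimeter-segment arrays under keys
    ``"protrusive"`` (outward) and ``"attraction"`` (inward pair on the
    adhered patch).  ``tension`` is the cortical tension in pN/µm.

    When ``volume_rate`` is given, a global constraint dV/dt = volume_rate is
    enforced through a Lagrange multiplier (physically a uniform ambient
    pressure), pinning the enclosed cell volume against discretization drift.
    """
    N = mesh.n_nodes
    M = mesh.n_elements
    ops = element_operators(mesh)
    theta = np.clip(state.theta, 0.0, params.theta_max)

    mu_n = viscosity_of(theta, stimulation_factor, params)
    mu_n = np.maximum(mu_n, params.mu_solvent)      # floor: depleted network still wets
    mu_s = params.mu_solvent
    lam_n = params.bulk_ratio * mu_n
    H = params.drag_coeff * theta * np.maximum(1.0 - theta, 0.0)

    q = mesh.quads
    dof_n = np.concatenate([q, N + q], axis=1)          # (M, 8) network dofs
    dof_s = dof_n + 2 * N

    Kn = mu_n[:, None, None] * ops["K_shear"] + lam_n[:, None, None] * ops["K_bulk"]
    Ks = mu_s * (ops["K_shear"] + ops["K_bulk"])
    Cd = H[:, None, None] * ops["Me"]                   # (M, 4, 4) drag mass

    rows, cols, vals = [], [], []

    def add_block(K, rdof, cdof):
        rows.append(np.repeat(rdof, rdof.shape[1], axis=1).ravel())
        cols.append(np.tile(cdof, (1, cdof.shape[1])).ravel())
        vals.append(K.reshape(len(K), -1).ravel())

    add_block(Kn, dof_n, dof_n)
    add_block(Ks, dof_s, dof_s)
    # drag coupling per velocity component
    for comp in range(2):
        dn = q + comp * N
        ds = dn + 2 * N
        add_block(Cd, dn, dn)
        add_block(Cd, ds, ds)
        add_block(-Cd, dn, ds)
        add_block(-Cd, ds, dn)

    # pressure coupling: momentum -G p ; continuity -G^T v + S p = 0
    pcol = 4 * N + np.arange(M)
    Gn = theta[:, None] * ops["dvec"]
    Gs = (1.0 - theta)[:, None] * ops["dvec"]
    for G, dof in ((Gn, dof_n), (Gs, dof_s)):
        rows.append(dof.ravel()); cols.append(np.repeat(pcol, 8)); vals.append(-G.ravel())
        rows.append(np.repeat(pcol, 8)); cols.append(dof.ravel()); vals.append(-G.ravel())

    # jump stabilization on the P0 pressure
    nxi, neta = mesh.nxi, mesh.neta
    e_id = np.arange(M).reshape(nxi, neta)
    cent = mesh.coords[q].mean(axis=1)
    mu_eff = mu_n + mu_s

    def stab_faces(e1, e2, shared_a, shared_b):
        a = mesh.coords[shared_a]
        b = mesh.coords[shared_b]
        L = np.linalg.norm(b - a, axis=1)
        rbar = 0.5 * (a[:, 0] + b[:, 0])
        Af = 2 * math.pi * rbar * L
        h = np.linalg.norm(cent[e1] - cent[e2], axis=1)
        beta = params.stab_alpha * Af * h / (0.5 * (mu_eff[e1] + mu_eff[e2]))
        for ee1, ee2, s in ((e1, e1, 1.0), (e2, e2, 1.0), (e1, e2, -1.0), (e2, e1, -1.0)):
            rows.append(4 * N + ee1); cols.append(4 * N + ee2); vals.append(s * beta)

    node = lambda i, j: j * (nxi + 1) + i
    i = np.arange(nxi - 1); j = np.arange(neta)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    stab_faces(e_id[:-1, :].ravel(), e_id[1:, :].ravel(),
               node(ii + 1, jj).ravel(), node(ii + 1, jj + 1).ravel())
    i = np.arange(nxi); j = np.arange(neta - 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    stab_faces(e_id[:, :-1].ravel(), e_id[:, 1:].ravel(),
               node(ii, jj + 1).ravel(), node(ii + 1, jj + 1).ravel())

    with_t = with_target if with_target is not None else bool(np.any(mesh.seg_tags == CONTACT))
    with_vol = volume_rate is not None
    nfull = 4 * N + M + (1 if with_t else 0) + (1 if with_vol else 0)
    if with_vol:
        # dV/dt = g . v_network on boundary nodes; multiplier acts as an
        # external (ambient) pressure conjugate to the volume constraint
        from .mesh import volume_gradient

        g = volume_gradient(mesh)
        vol_row = nfull - 1
        bidx = np.where(np.abs(g).sum(axis=1) > 0)[0]
        for n in bidx:
            for c in range(2):
                if g[n, c] != 0.0:
                    rows.append(np.array([vol_row, c * N + n]))
                    cols.append(np.array([c * N + n, vol_row]))
                    vals.append(np.array([g[n, c], g[n, c]]))
    rows = np.concatenate([np.asarray(r).ravel() for r in rows])
    cols = np.concatenate([np.asarray(c).ravel() for c in cols])
    vals = np.concatenate([np.asarray(v).ravel() for v in vals])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(nfull, nfull))

    # right-hand side: membrane forces on network velocity rows
    f_nodal = tension_forces(mesh, tension) if tension != 0.0 else np.zeros_like(mesh.coords)
    axial_applied = 0.0
    target_reaction = 0.0
    f_solvent = np.zeros_like(mesh.coords)
    if boundary_stresses:
        P = mesh.n_perimeter
        prot = np.asarray(boundary_stresses.get("protrusive", np.zeros(P)), float)
        attr = np.asarray(boundary_stresses.get("attraction", np.zeros(P)), float)
        f_if, f_if_s, axial_applied = interface_stress_forces(mesh, prot, attr)
        f_nodal = f_nodal + f_if
        f_solvent = f_solvent + f_if_s
        zf = boundary_stresses.get("zip_forces")
        if zf is not None:
            # contact-line capture: membrane fringe pulled onto the target,
            # equal-and-opposite axial reaction on the target itself
            f_nodal = f_nodal + zf[0]
            target_reaction += zf[1]
    f = np.zeros(nfull)
    f[:N] = f_nodal[:, 0]
    f[N : 2 * N] = f_nodal[:, 1]
    f[2 * N : 3 * N] = f_solvent[:, 0]
    f[3 * N : 4 * N] = f_solvent[:, 1]
    if with_vol:
        f[nfull - 1] = volume_rate

    key = (mesh.nxi, mesh.neta, with_t, with_vol, mesh.seg_tags.tobytes())
    cached = _constraint_cache.get(key)
    if cached is None:
        cached = _constraint_map(mesh, with_t, with_vol)
        _constraint_cache.clear()
        _constraint_cache[key] = cached
    T, w_dof, p_map = cached
    A_red = (T.T @ A @ T).tocsc()
    f_red = T.T @ f
    if with_t and target_reaction != 0.0:
        f_red[w_dof] += target_reaction
    try:
        x_red = spla.spsolve(A_red, f_red)
    except Exception as exc:  # pragma: no cover - rare factorization failure
        raise NumericalError(f"momentum solve failed: {exc}") from exc
    if not np.all(np.isfinite(x_red)):
        raise NumericalError("momentum solve returned non-finite solution (singular system?)")
    resid = np.linalg.norm(A_red @ x_red - f_red) / max(np.linalg.norm(f_red), 1e-300)
    if resid > 1e-6 and np.linalg.norm(f_red) > 1e-12:
        raise NumericalError(f"momentum solve residual {resid:.2e} exceeds tolerance")

    x = T @ x_red
    v_n = np.stack([x[:N], x[N : 2 * N]], axis=1)
    v_s = np.stack([x[2 * N : 3 * N], x[3 * N : 4 * N]], axis=1)
    pressure = x_red[p_map]
    w = float(x_red[w_dof]) if with_t else None
    return MomentumSolution(
        v_network=v_n, v_solvent=v_s, pressure=pressure,
        target_velocity=w, residual=float(resid),
        target_applied_force=float(axial_applied),
    )


# ---------------------------------------------------------------------------
# messenger reaction-diffusion and phase interconversion
# ---------------------------------------------------------------------------

def step_messenger(
    mesh: Mesh,
    m: np.ndarray,
    D_m: float,
    k_decay: float,
    boundary_source: np.ndarray | None,
    dt: float,
) -> np.ndarray:
    """Backward-Euler Galerkin step of dm/dt = D_m lap(m) - k_decay m with a
    Neumann influx on designated boundary segments (a.u. µm/s per area).

    Lumped mass matrix; unconditionally stable; a uniform field decays by the
    exact backward-Euler factor 1/(1 + k dt).
    """
    if dt <= 0.0:
        raise ConfigurationError("dt must be positive")
    m = np.asarray(m, float)
    if boundary_source is not None and np.any(np.asarray(boundary_source) < 0):
        raise ConfigurationError("negative messenger source")

    N = mesh.n_nodes
    ops = element_operators(mesh)
    q = mesh.quads
    Ml = np.zeros(N)
    np.add.at(Ml, q.ravel(), ops["Mlump"].ravel())

    rows = np.repeat(q, 4, axis=1).ravel()
    cols = np.tile(q, (1, 4)).ravel()
    K = sp.csr_matrix((ops["Kdiff"].reshape(-1), (rows, cols)), shape=(N, N))

    b = Ml * m / dt
    if boundary_source is not None:
        segs = mesh.perimeter_segments()
        src = np.asarray(boundary_source, float)
        act = np.where(src > 0)[0]
        if len(act):
            a = mesh.coords[segs[act, 0]]
            bb = mesh.coords[segs[act, 1]]
            L = np.linalg.norm(bb - a, axis=1)
            rbar = 0.5 * (a[:, 0] + bb[:, 0])
            load = src[act] * 2 * math.pi * rbar * L * 0.5
            np.add.at(b, segs[act, 0], load)
            np.add.at(b, segs[act, 1], load)

    A = sp.diags(Ml * (1.0 / dt + k_decay)) + D_m * K
    m_new = spla.spsolve(A.tocsc(), b)
    return np.maximum(m_new, 0.0)


def interconvert_phases(
    theta: np.ndarray, m_elem: np.ndarray, params: ConstitutiveParams, dt: float
) -> np.ndarray:
    """Exact exponential update of the polymerization/depolymerization law

        d(theta)/dt = k_poly m (theta_max - theta) - k_depoly (theta - theta_base)

    with the element-mean messenger ``m_elem`` held constant over the step.
    theta stays in [min(theta, theta_base), theta_max] by construction.
    """
    m = np.maximum(np.asarray(m_elem, float), 0.0)
    kp = params.k_poly * m
    kd = params.k_depoly
    ktot = kp + kd
    theta_eq = np.where(
        ktot > 0,
        (kp * params.theta_max + kd * params.theta_base) / np.maximum(ktot, 1e-300),
        theta,
    )
    decay = np.exp(-ktot * dt)
    out = theta_eq + (theta - theta_eq) * decay
    return np.clip(out, 0.0, params.theta_max)


def messenger_element_mean(mesh: Mesh, m: np.ndarray) -> np.ndarray:
    return np.mean(m[mesh.quads], axis=1)
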