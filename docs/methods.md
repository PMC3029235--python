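# Methods

## The model

phagosim simulates the mechanics of a human neutrophil engulfing a rigid
spherical target (diameter 3.2 µm) held against the cell on its symmetry
axis, with the cell itself held at the rear on a rigid pipette plug.  The
cytoplasm is treated in the *reactive interpenetrating flow* picture: a
mixture of two interconverting phases — a viscous cytoskeletal (F-actin)
network with volume fraction θ and a low-viscosity cytosolic solvent with
fraction 1−θ — enclosed by a membrane under cortical tension.  In the
creeping-flow regime the governing equations are two coupled Stokes-like
momentum balances with interphase drag,

    0 = ∇·(2 μ_n(θ) e(v_n) + λ_n (∇·v_n) I) − θ ∇p − H (v_n − v_s) + f_n
    0 = ∇·(2 μ_s e(v_s) + λ_s (∇·v_s) I) − (1−θ) ∇p + H (v_n − v_s)

together with mixture incompressibility ∇·(θ v_n + (1−θ) v_s) = 0.  The
network viscosity is purely viscous and linear in θ, μ_n = S(t)·μ₀·θ, where
S(t) is a global stimulation factor that ramps in lockstep with the cortical
tension (×5 for the fungal-particle scenario, constant for antibody-coated
beads).  Network mass obeys ∂θ/∂t + ∇·(θ v_n) = k_poly·m·(θ_max−θ) −
k_depoly·(θ−θ_base), where m is a generic diffusible signaling messenger
(∂m/∂t = D_m ∇²m − k_decay·m) produced transiently at the leading edge of
the adhered membrane patch.

Target-specific mechanical effectors (the scenario "switchboard"):

* **Adhesion** — upon contact, irreversible, in both scenarios.  Boundary
  nodes within the gap tolerance (2% of the target radius) of the sphere and
  contiguous with the patch join it and never detach.  The adhesive
  interaction additionally appears as a short-range capture traction (see
  "contact-line capture" below).
* **Polymerization stimulus** — messenger production on the freshly adhered
  patch (age < τ = 10 s) and a two-segment annulus of free membrane ahead of
  the rim, at 100% (antibody) or 75% (fungal particle) of the source
  strength.
* **Disjoining (protrusive) stress** — outward normal stress
  zone_scale·σ_p·θ on the membrane.  zone_scale = 1 on the free membrane in
  both scenarios; on the contact patch it is 0 (antibody) or 0.5 (fungal
  particle).  The reaction is applied to the *solvent* phase of the
  membrane-adjacent interior layer: the disjoining pressure acts across the
  membrane-proximal fluid gap, so it must not load the polymerized network
  that is viscously glued to the membrane (doing so cancels the pair almost
  completely at coarse resolution).
* **Membrane–cytoskeleton attraction** — antibody scenario only: a constant
  inward stress σ_a on the adhered patch, with the reaction pulling the
  adjacent network onto the bead; this is the "flattening" interaction that
  drives the thin enveloping lamella.
* **Cortical tension** — prescribed piecewise-linear timeline: resting
  0.025 mN/m, linear rise starting 10 s after contact over 60 s, plateau at
  0.3 mN/m (fungal particle) or 0.15 mN/m (antibody).  Implemented as the
  exact gradient of the discrete free-surface energy γ·A with respect to
  node positions, which is the consistent weak form of the γκ n traction
  and inherently damps sub-element membrane wiggles.

The target is rigid; adhered boundary nodes move with it, its axial velocity
is an extra unknown of the momentum solve, and the corresponding equation is
the axial force balance on the (massless) particle.  Target position is
reported relative to the held rear edge.

### Contact-line capture

At desk-scale resolution the advancing adhesion front ("zipper") cannot be
resolved at the molecular scale at which adhesive contact forms.  The
adhesive interaction is therefore regularized as a capture traction on the
first few free-membrane segments ahead of the rim: membrane within the
capture range (0.65 µm, about one boundary element) is pulled toward the
sphere with stress σ_zip tapering linearly to zero at the range, the
equal-and-opposite reaction acting on the particle.  The force is
self-limiting — captured membrane adheres irreversibly and the traction only
ever acts on the advancing fringe.  The capture range is the single most
influential numerical regularization parameter (it sets how easily the
purse-string closure at the end of uptake re-attaches to the sphere crown)
and is part of the package calibration.

### Completion criterion

Engulfment is counted as complete when 95% of the target surface is covered
(adhered arc ≈ 154°).  The remaining crown subtends only a few boundary
elements, and its closure — membrane self-contact and fusion of the
phagosome mouth — is sub-resolution physics that a simply-connected
continuum surface cannot represent; simulations continue 20 s past
completion to confirm rounding.

## Discretization

* **Mesh** — a single structured block of axisymmetric quadrilaterals
  (logical grid 40×8 at the default resolution scale 1.25, i.e. 500
  elements).  The "shell" layout places the long logical edge along the
  symmetry axis + adhered arc + a short free lip past the rim, the opposite
  edges along the free membrane, and the short edge on the rigid pipette
  plug (bore + chamfered notch + bi-conical cap).  All four logical corners
  coincide with genuine convex corners of the geometry, so the cup rim — a
  reflex vertex once the cell wraps the target — always lies mid-edge,
  shared between two elements.  Grid rows are rings nested between the
  inner spine and the membrane and follow the cup at any depth of wrap.
* **Interior placement** — after each boundary update the interior is
  rebuilt: transfinite interpolation and (when that is marginal) a direct
  discrete-harmonic solve provide initial candidates, short under-relaxed
  smoothing polishes them, a Winslow (inverse-harmonic) relaxation bends the
  grid around the engulfed sphere, and a local Gauss–Seidel untangler
  repairs residual folds; the best-quality configuration wins and the input
  interior is never degraded.
* **Momentum** — Galerkin mixed elements: bilinear (Q1) velocities for both
  phases, piecewise-constant (P0) pressure with inter-element jump
  stabilization (the stabilization matrix has zero row sums, so it
  redistributes but never creates volume).  Kinematic constraints (rigid
  target motion, held plug, axis symmetry, solvent no-slip at the membrane)
  are imposed by a dof-merging transformation; sparse direct factorization
  solves the reduced saddle system, and solution residuals above 10⁻⁶ are
  treated as failures.
* **Transport** — the element-wise network fraction is remapped between
  meshes by a conservative, monotone first-order upwind flux scheme built
  from exact swept volumes (network mass is conserved to round-off when no
  material crosses the membrane).  The nodal messenger uses monotone
  bilinear interpolation with a semi-Lagrangian backtrack and a
  mass-restoring fix-up.  The reaction–diffusion step is backward-Euler
  Galerkin with a lumped mass matrix (a uniform field decays by exactly
  1/(1+kΔt) per step); phase interconversion uses the exact exponential
  update of its linear rate law, so θ stays in [0, θ_max] by construction.
* **Timestep** — limited by mesh distortion (element edge length over
  *relative* edge velocity) and by the target's travel per step, rather than
  by the pure advective Courant bound, which the thin, near-rigidly-moving
  cup-wall elements would make needlessly severe; capped at 0.5 s.  The
  advective Courant estimate remains available as a separate utility.
* **Volume** — enclosed volume is tracked by Pappus quadrature; membrane
  polylines are resampled on a shape-preserving monotone (PCHIP) curve so
  redistribution does not systematically erode volume, and a tiny uniform
  normal offset of the free membrane (≤10 nm per step) closes the residual
  bookkeeping drift.  Over full runs the net drift is below 10⁻⁵.
* **Robustness ladder** — when a step's relayout cannot produce a valid
  mesh, the step is retried with a halved timestep, then with light
  curvature smoothing of the free membrane (standing in for tension-driven
  smoothing of sub-element kinks), and finally with newly captured adhesion
  deferred by one step.

## Parameters

Material and kinetic magnitudes are not printed in the experimental
literature at this level; they are calibration targets.  The calibration
strategy fixes one base parameter set so that the antibody scenario
reproduces its observed engulfment duration, and then switches only the
Table-of-effectors entries for the other scenarios.

| parameter | value | units | role |
|---|---|---|---|
| μ₀ (mu_network_0) | 2.5·10⁴ | pN·s/µm² per unit θ | network viscosity scale; bulk cytoplasm μ₀·θ_base = 500 Pa·s |
| μ_s | 10 | pN·s/µm² | cytosol viscosity |
| drag | 10⁵ | pN·s/µm⁴ | interphase friction; keeps phases co-moving away from polymerization zones |
| θ_base / θ_max | 0.02 / 0.5 | — | resting and packing network fractions |
| k_poly | 0.7 | 1/(a.u.·s) | polymerization gain; kept moderate so the stimulated rim does not stiffen and throttle the zipper |
| k_depoly | 1.0 | 1/s | localizes polymerized θ to ~1 s of trailing history |
| D_m / k_decay | 1.0 / 2.0 | µm²/s, 1/s | messenger range √(D/k) ≈ 0.7 µm |
| source_strength | 2.0 | a.u.·µm/s | sets m = O(0.1–0.5) at the leading edge |
| σ_p (sigma_protrude) | 6·10³ | pN/µm² per unit θ | disjoining stress scale |
| σ_a (sigma_attract) | 10³ | pN/µm² | antibody flattening stress |
| σ_zip / range | 6·10³ / 0.65 | pN/µm², µm | contact-line capture regularization |

Geometry: cell radius 4.25 µm, target radius 1.6 µm, initial contact
half-angle 0.25 rad, plug radius 0.9 µm.  Tensions are stored internally in
pN/µm (1 mN/m = 10³ pN/µm), converted once at configuration parse.

## Synthetic benchmarks

The benchmark generator emulates single-cell target-tracking data: per
event it draws a push-out distance and completion time from the published
population statistics (normal, truncated at zero), builds a smooth skeleton
(cubic-smoothed rise to the peak, exactly linear inward motion at 33 nm/s,
plateau after completion) and adds i.i.d. Gaussian tracking noise (SD
0.05 µm, sub-pixel scale) on a 1 Hz grid.  The noise-free skeleton
reproduces its generating parameters exactly under the observables module.
What the generator does *not* emulate: correlated tracking noise, shape
information, heterogeneous inward speeds, or any mechanics — passing the
recovery tests shows the metric pipeline is correct, not that the mechanical
model is.  Note that the naive per-trace metric estimators are biased
upward on noisy traces (a max over noisy samples); cohort-level checks
therefore compare the generating parameters.

## What the calibrated model does and does not reproduce

With the single calibrated base set and only the effector switches, the
model reproduces: the engulfment durations of both scenarios (≈ 172 s vs
≈ 59 s at default resolution, against 167±73 s and 66±19 s observed), their
ratio (≈ 2.9, observed ≈ 2.5), the near-zero push-out of antibody-coated
beads, volume conservation, irreversible monotone patch growth, and the
tension-synchronized onset of inward motion.

Two observables are **not** reproduced and are reported honestly by the
test suite:

* **The ~1 µm push-out of fungal particles.**  In this discretization the
  contact-zone disjoining force cannot push the particle outward against
  the combination of the capture traction and the stiff, viscously-glued
  membrane-adjacent layer; simulated push-out stays near zero for every
  force routing tried (network-phase reaction, solvent-phase reaction,
  deeper reaction layers).  Resolving the push-out most likely requires the
  membrane to be an independent surface phase separated from the network by
  a resolved disjoining gap, which a ~500-element single-block mesh cannot
  represent.
* **The ~33 nm/s inward target speed.**  The capture traction that makes
  coarse-grid zipping robust also reels the particle inward during the
  rapid wrapping phase at 100–250 nm/s (10 s smoothed); the experimental
  speed is an order of magnitude lower because real zipping advances the
  membrane over an almost stationary particle.  The engulfment *durations*
  are nevertheless correct because wrap progress, not particle travel,
  controls them here.

## Known limitations

* Membrane is the domain boundary, not an independent phase: no membrane
  reservoir, no slack/tension coupling, no self-contact or fusion.
* Adhesion has no bond kinetics; capture is geometric + short-range
  traction with irreversibility imposed.
* The final ~5% of target coverage (phagosome mouth closure) is below
  resolution and excluded from the completion metric.
* The momentum pair uses the symmetric pressure coupling (the transpose of
  the mixture-incompressibility operator), omitting the p∇θ distinction of
  non-conservative formulations.
* Trajectories are deterministic but exhibit sensitive dependence on
  numerical parameters near the zipping threshold; the resolution
  insensitivity of metrics is verified at the ~10% level for the antibody
  scenario.
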