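# Methods

## Problem

Percutaneous microwave coagulation of a large liver tumor needs several
needles placed through the abdominal wall, each hitting a preassigned target
point inside the tumor. A trajectory is the straight line from a skin entry
point to its target. It must (i) keep a configurable safe clearance γ from
every obstacle — ribs, primary vessels, and the needles already inserted —
(ii) respect the insertion-angle limits of the needle-driving robot, and
(iii) be as short as possible, since long paths amplify targeting error under
tissue deformation. `cfrwplan` plans all needles sequentially: each planned
needle becomes an obstacle for the ones after it, and target positions can be
shifted between insertions by an external deformation model through a
pluggable displacement provider (the default provider returns zero).

## Geometry model

All surfaces are posed super-quadrics

    f(p) = Σ_i |p'_i / a_i|^{e_i} − c,      p' = Rᵀ (p − t),

with even integer exponents e_i ≥ 2, so f is smooth (the absolute values
drop), negative inside, zero on the surface. Vessels and needle shafts use
exponents (8, 2, 2) — nearly-cylindrical solids with soft caps; spheres use
(2, 2, 2). The needle is split into a head and a tube part, both canonical
super-quadrics aligned with the local x-axis. The canonical head parameters
default to scales (60, 0.1, 0.1), exponents (8, 2, 2), level 1000, giving an
axial half-extent 60·1000^{1/8} ≈ 142 mm and cross-radius 0.1·√1000 ≈ 3.16 mm.
These defaults are deliberately preserved as configuration even though a
284 mm "head" is physically odd for a coagulation needle (a plausibility
warning is logged); every dimension is configurable. `head_length` defaults
to the head's own axial extent so that the head solid spans exactly
[tip, tip + l·u] along the insertion direction u.

The world frame has its origin at needle 1's target, z vertical-up, units mm.
A trajectory through target P_B' is parameterized by its polar angle θ from
+z and azimuth φ, both obtained with full-quadrant `atan2` (a plain arctan of
the coordinate ratio would misplace the needle in half the azimuth range).
Angle limits enter through the sine substitution

    θ(w₁) = θ_mid + θ_amp sin w₁,    φ(w₂) = φ_mid + φ_amp sin w₂,

which maps unconstrained (w₁, w₂) onto the closed angle boxes; θ and φ use
independent parameters.

## Workspace boundary (CFRW)

The collision-free reachable workspace of a needle is the set of trajectories
through its target that keep clearance ≥ γ from an obstacle. Its boundary is
computed per z-layer: in the plane z = h the needle axis pierces the point
u = (x, y), and the boundary is a closed curve in u.

Clearance is encoded by an interior-point formulation of the closest-pair
problem between the needle solid and the obstacle solid: unknowns are the
candidate points a (obstacle) and b (needle), multipliers λ₁, λ₂ > 0, slacks
s₁, s₂ > 0 and a clearance slack s_d, subject to

* stationarity   2(a−b) + λ₂∇f_obs(a) = 0,  −2(a−b) + λ₁∇f_n(b) = 0,
* membership     f_n(b) + s₁ = 0,  f_obs(a) + s₂ = 0,
* barrier        λᵢ sᵢ = μ,
* clearance      ‖a−b‖² − γ² − s_d² = 0,

11 equations in 11 unknowns. Stacking the 2-row kinematic constraint linking
u to (w₁, w₂) gives the 13-equation extended system Φ̃(u, z̃) with
z̃ = [a, b, λ, s, s_d, w₁, w₂]. For u in the interior of the workspace the
system has an isolated solution with s_d ≠ 0; on the boundary the two
s_d-branches merge and the Jacobian Φ̃_z̃ becomes singular. The boundary
criterion therefore augments Φ̃ with a unit null direction ξ:

    G̃(x̃) = [Φ̃; Φ̃_z̃ᵀ ξ; ξᵀξ − 1] = 0,   x̃ = [u, z̃, ξ] ∈ R²⁸,

27 equations over 28 unknowns — a one-dimensional solution curve whose
u-projection is the layer boundary. ξ and −ξ describe the same point. The
same fold condition also captures the angle-limit envelope (there ∂θ/∂w₁ or
∂φ/∂w₂ vanishes); reachability is additionally checked in closed form when
testing membership.

### Barrier bias

The barrier solution places a and b slightly inside their solids, at depth
≈ μ/(2γ) each along the gap normal (independent of the gradient scaling of
f). The fold occurs where the *relaxed* pair distance equals γ, so the true
surface-to-surface clearance on the traced boundary is

    d ≈ γ − k·μ/(2γ),

with k the number of "fat" bodies (k = 1 for a near-line needle against a
vessel, giving d ≈ 1.467 mm at γ = 1.5 mm, μ = 0.1). The bias is linear in μ
and shrinks tenfold when μ does; the tests verify this scaling. This is an
inherent property of the formulation, not of the implementation.

### Numerics

* Residuals are written to be holomorphic in all unknowns (even powers, trig
  substitutions), so Jacobians are computed by complex-step differentiation
  (step 1e-30) — exact to machine precision, with none of the cancellation of
  real finite differences. The curvature block ∂(Φ̃_z̃ᵀξ)/∂z̃ of the
  criterion Jacobian uses central differences of the complex-step Jacobian
  (step 1e-6·max(1, |z̃ᵢ|)); it only steers Newton/predictor directions, so
  ~7 significant digits suffice. Closed-form super-quadric gradients appear
  directly in the residual; closed-form Hessians are exported for oracles.
* Convergence is judged on a row-scaled residual (membership rows divided by
  the local gradient magnitude, clearance by γ²), tolerance 1e-9: with thin
  needle cross-sections the raw membership rows amplify position roundoff by
  the gradient norm and an absolute tolerance would be unattainable.
* Interior solves at fixed u run undamped Newton (Jacobian restricted to the
  11 collision-free rows) with a fraction-to-boundary cap keeping λ, s > 0,
  warm-started during marching; cold starts use a short μ-continuation from
  μ₀ = max(10, 100 μ). Newton residuals are allowed to grow transiently
  (monotone line searches stall on the barrier central path).
* `find_boundary_point` marches from a feasible u along a ray, brackets the
  first fold where the interior solve fails, bisects the bracket to 1e-8 mm,
  seeds ξ with the smallest left singular vector of Φ̃_z̃, and polishes the
  full 28-vector with minimum-norm Gauss–Newton on G̃.
* `trace_boundary` is pseudo-arclength continuation run on the
  *active-clearance branch* of the criterion: on the clearance fold the null
  direction is the s_d coordinate, so the criterion curve restricted to that
  branch is exactly {Φ̃ = 0, s_d = 0} — 13 equations over 14 unknowns. This
  reduced system is the same solution curve of G̃ = 0 but is immune to the
  criterion's spurious fold sheets (the sine substitution is also singular
  along the azimuth-wrap ray and the θ-limit circle, and a tracer on the
  full 28-dimensional system can wander onto those sheets), and it needs no
  curvature tensor. Full `CriterionState`s, with ξ recovered from the SVD
  of Φ̃_z̃, are reconstructed for every stored sample; the 27-equation
  criterion remains the polishing and verification system.
* Continuation details: tangent from the SVD null space of the 13×14
  Jacobian, oriented for continuity (orientation restricted to the
  unaffected components across an azimuth recentering); the arc step targets
  consecutive u-samples ~`step` (default 0.5 mm) apart, with a persistent
  factor that halves on corrector failure and relaxes on easy success
  (obstacle end caps concentrate curvature in the closest-pair unknowns and
  need temporarily tiny steps; stall below 1e-6 mm raises an error). The
  corrector bounds the displacement of the geometric unknowns (u, a, b) by
  the arc step so it cannot silently jump to a distant curve point. A curve
  closes only after its accumulated *u*-path length exceeds 4·step, it
  returns within 1.2·step of the seed, *and* it is moving the same way as
  when it left — the last condition keeps the opposite edge of a thin rod
  shadow from triggering closure. With full-circle azimuth limits the
  substitution center slides along with the curve so its wrap fold is never
  crossed. Tracing also stops at the θ-limit fold of the substitution and
  at the |uᵢ| ≤ h_max box (h_max = 200 mm).
* The needle cross-section of "near-line" oracle scenes uses scale 1e-4
  (half-width ≈ 3×10⁻³ mm). A still thinner needle would push the membership
  row's gradient norm to ~10⁷ and make the system unsolvable at double
  precision; the residual thickness is far below every tolerance used.

### Curve seeding and membership

One obstacle casts one connected shadow per layer in all scenes handled
here, so the default seeding projects the obstacle's bounding box through
the target onto the layer, picks a feasible point on a ring around the
projected hull, and marches inward (deterministic, one trace per obstacle
and layer). An 8×8 interior-grid seeding with Hausdorff-distance
deduplication is available (`seed_strategy="grid"`) for scenes with
disconnected shadow components. A located fold whose clearance slack s_d is
not zero is an angle-limit fold, not a clearance boundary, and is skipped
as a seed (reachability covers it analytically). If no feasible seed
exists the layer is marked fully infeasible for that obstacle.

Membership of a trajectory is tested on every stored layer it crosses: the
axis-plane intersection point is ray-cast against the obstacle's curve set
(odd/even crossing parity, +x ray, deterministic retry rotated by the fixed
irrational angle √2/100 when a vertex lies on the ray — no randomness).
Because a traced curve bounds the obstacle's *infeasible* shadow, each curve
set stores the parity observed at its known-feasible march start; a
directly-constructed boundary defaults to odd-parity = inside-the-workspace.
Membership requires the correct parity for every obstacle plus closed-form
angle-limit reachability.

A boundary curve that exits through the θ-limit is closed along the
reachability circle (the arc on the side whose midpoint is infeasible — the
circle there is covered by the shadow — so the closed polyline bounds
infeasible ∩ reachable). A shadow clipped by the h_max domain box instead
leaves genuinely open curves, for which ray parity is ill-defined; such
layers are flagged and their membership is decided by a direct conservative
clearance test: the needle capsule against the obstacle capsule in closed
form (exact segment–segment distance; every (8,2,2) rod and sphere used
here circumscribes to a capsule, erring on the safe side since the rod's
cross-radius tapers toward the caps), or the SLSQP surface distance for
general shapes, thresholded at γ minus the barrier bias so the two
membership paths agree at the boundary. The interior-point system is *not*
used for this fallback: it characterizes stationary closest pairs, and a
cold start can converge to a non-global pair when two long rods cross.

## Entry search

The optimal entry point minimizes the trajectory length over the skin patch
S(u, v) subject to CFRW membership, by four-quadrant grid refinement: start
at the parameter midpoint with intervals (L₁, L₂) = half the parameter
ranges; evaluate the four quadrant centers at ±L/2 offsets (clipped to the
patch bounds); keep the feasible candidate with the smallest distance (ties
broken by lexicographically smallest (u, v)); halve the intervals and
recenter on the incumbent. Termination: the sine of the angle between the
trajectory and the surface normal ≤ δ (default 1e-5) *or* max(L₁, L₂) ≤ ε
(default 1e-4) — the alignment criterion alone can be unattainable when the
unconstrained optimum is infeasible. If all four quadrant candidates are
infeasible but the center is feasible, the intervals are halved around the
center. The search is local by design; an optional m×m multi-start (default
off, m = 3) covers multi-modal cases. An entry whose trajectory crosses none
of the stored layers is treated as infeasible rather than untested.

Skin patches: elliptic-cylinder (abdominal wall cross-section), polynomial
graph patches z = p(u, v) (planes as the degenerate case), spherical patches
(added for constant-distance verification), and bicubic-spline gridded
interpolants of sampled patches.

## Sequential planner

Needles are planned in the given insertion order (an input; default the
target order). After each needle is planned, its head and the remaining
inserted length (tube) are posed as new obstacles — truncated at the skin
entry by default, optionally extended as a full line for conservatism — and
the displacement provider may shift the remaining targets (accumulating over
insertions). Per-needle diagnostics record the independently computed
clearance of the planned segment to every obstacle (joint SLSQP minimization
over the surface point and segment parameter, multi-started from coarse
samples — entirely separate from the KKT/continuation machinery). The
planning path contains no random number generator, so identical inputs give
bit-identical plans.

## Synthetic scenes

* `three-target`: three collinear targets at (0,0,0), (0,−15,0), (0,−30,0) mm, two
  elongated vessels between liver and abdominal wall (centers at z = 85 and
  65 mm, radii 4 and 5 mm), an elliptic-cylinder skin patch with top z
  between ≈158 and 185 mm, angle limits θ ∈ [0, 1.0] rad, φ free. The vessel
  geometry is this package's own choice of plausible anatomy, so
  verification on this scene relies on properties (clearance = γ,
  feasibility, mutual avoidance) rather than on any particular boundary
  coordinates.
* `sphere-oracle`: a sphere (default r = 10 mm) at D = 40 mm straight above
  a single target, near-line needle. The boundary is exactly the tangent
  cone with half-angle arcsin((r+γ)/D); each layer's boundary is a circle —
  the closed-form oracle for the continuation machinery.
* `single-vessel`: one vessel (radius 4 mm, axis along y, center z = 90 mm)
  above one target with a near-line needle — the clearance-verification
  scene.
* `random-vessels`: seeded random elongated horizontal-ish vessels in the
  slab z ∈ [50, 120] mm; bit-identical output per seed, seed recorded in the
  scene metadata.

What these scenes do not emulate: patient-specific anatomy (obstacle counts,
shapes beyond super-quadrics), actual liver deformation fields, registration
error, or respiratory motion. Passing tests therefore demonstrate the
correctness of the planning mathematics and numerics on super-quadric
geometry, not clinical targeting accuracy.

## Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| γ (`gamma`) | 1.5 | mm | safe clearance to any obstacle surface |
| μ (`mu`) | 0.1 | – | barrier parameter; boundary clearance bias ≈ μ/(2γ) per fat body |
| `z_layers` | 150, 160, 170 | mm | boundary slice heights |
| `h_max` | 200 | mm | domain height bound |
| δ (`delta_tol`) | 1e-5 | – | entry-search normal-alignment sine precision |
| ε (`eps_tol`) | 1e-4 | param units | entry-search interval precision |
| `continuation_step` | 0.5 | mm | boundary sampling step in u |
| `newton_tol` | 1e-9 | – | row-scaled residual tolerance |
| needle tube radius | 0.9 | mm | cross-radius of inserted-shaft obstacles |

Tests and the acceptance script use reduced problem sizes chosen for a
single-CPU workstation: single-vessel or two-vessel scenes, up to three
layers, continuation steps of 0.5–1.0 mm, and oracle grids up to 2000×2000.

## Known limitations

* The boundary tracer assumes the G̃ = 0 curve is regular; cusps (higher-order
  folds) would stall the continuation with an explicit error rather than
  produce wrong curves.
* Membership parity on an open (domain-clipped) curve closes it with the
  chord between its endpoints, an approximation only exercised when a shadow
  leaves the ±h_max box.
* The traced clearance equals γ only up to the barrier bias above; drive μ
  down if an exact clearance is required (cost: worse conditioning near the
  fold).
* A 3D boundary surface is presented as stacked layer curves; no watertight
  surface reconstruction is attempted.
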