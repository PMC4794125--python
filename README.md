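# cfrwplan

Automatic multiple-needle insertion trajectory planning for percutaneous
microwave coagulation of large liver tumors.

Large tumors need several overlapping coagulations, so several needles must
be placed through the abdominal wall, each reaching a preassigned target
point P_B inside the tumor from an entry point P_A on the skin. A usable
trajectory must keep a safe clearance γ from ribs, primary vessels *and the
needles already inserted*, respect the insertion-angle limits of the
needle-driving robot, and be as short as possible. `cfrwplan` plans all
needles sequentially and automatically, which is otherwise a tedious,
experience-driven manual task; the intended users are researchers in
image-guided intervention planning and surgical robotics.

## Method

All anatomy and needle parts are posed super-quadrics
`Σᵢ |p'ᵢ/aᵢ|^{eᵢ} = c`. For a needle pivoting about its fixed target, the
**collision-free reachable workspace** (CFRW) is the set of insertion
trajectories whose clearance to every obstacle is at least γ. Its boundary
is computed analytically, per horizontal slice z = h, from an interior-point
closest-pair system between the needle solid and the obstacle solid:

    ∂f₀/∂η + λ₁ ∂f_n/∂η + λ₂ ∂f_obs/∂η = 0      (stationarity, 6)
    f_n(b) + s₁ = 0,  f_obs(a) + s₂ = 0          (membership, 2)
    λᵢ sᵢ = μ                                    (barrier, 2)
    ‖a − b‖² − γ² − s_d² = 0                     (clearance, 1)

with f₀ = ‖a−b‖². Stacked with the 2-row kinematic constraint tying the
slice point u = (x, y) to the insertion angles, this is the 13-equation
extended system Φ̃(u, z̃). The workspace boundary is the fold of Φ̃ — where
Φ̃_z̃ is singular — expressed by the 27-equation criterion
G̃ = [Φ̃; Φ̃_z̃ᵀξ; ξᵀξ−1] over 28 unknowns, a 1-D curve traced by
pseudo-arclength continuation. Membership of a candidate trajectory is then
a ray-casting parity test against the traced curves. The optimal entry point
minimizes ‖P_A − P_B'‖ over the parametric skin S(u, v) by four-quadrant
grid refinement restricted to the CFRW, and each planned needle is injected
as a new obstacle for its successors. `docs/methods.md` has the full
numerical story.

## Worked example

```
$ cfrw-plan synth --preset three-target --out scene.json
$ cfrw-plan run --scene scene.json --gamma 1.5 --mu 0.1 \
      --z-layers 150,160,170 --out outdir/
needle 0: entry [-61.898, -39.345, 172.301] mm, d_min 187.262 mm, min clearance 4.596 mm
needle 1: entry [-11.678, -15.0, 184.563] mm, d_min 184.932 mm, min clearance 5.001 mm
needle 2: entry [-46.163, -30.0, 178.049] mm, d_min 183.936 mm, min clearance 8.544 mm
```

The preset is the three-target simulation environment (collinear targets at
(0,0,0), (0,−15,0), (0,−30,0) mm with two vessels between liver and skin).
For each needle the planner prints the chosen entry point, the trajectory
length `d_min` (the optimization objective), and the smallest axis-to-surface
clearance over all obstacles present when it was planned. Needle 0's
clearance of 4.596 mm to the nearer vessel is exactly the safe distance:
1.5 mm of clearance plus the 3.16 mm cross-radius of its own shaft (minus
the small barrier relaxation, ≈γ − μ/γ); the entry search has pushed the
trajectory right up against the workspace boundary to shorten the path.
Needles 1 and 2 are planned with their predecessors as obstacles, and the
pairwise shaft clearances all exceed γ. `outdir/` receives `plan.json`
(full trajectories and diagnostics), `boundaries.csv` (all traced layer
curves), and optional plots/PLY.

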