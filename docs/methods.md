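# Methods

## The model

Cells are rigid spheroids of constant volume moving in unbounded 3-D space
under deterministic two-body rules; there is no chemotaxis field, no
extracellular-matrix mechanics, no division or death, and no stochastic
forcing — the only randomness is in the initial conditions (seeding
positions and axis directions). The state of cell *i* is (rᵢ, vᵢ, Rᵢ) with
Rᵢ ∈ SO(3) the frame whose columns are the major (e_x), middle (e_y) and
minor (e_z) axes. One time step corresponds to roughly 2 minutes and one
length unit to roughly 40 µm.

### Shape

The single shape parameter is the oblateness χ = 1 − b_r/a_r ∈ [0, 1).
Under the volume normalisation a_r·b_r² = 1 this fixes
a_r = (1−χ)^(−2/3) and b_r = c_r = (1−χ)^(1/3). (Note both constraints are
needed; a_r alone does not determine b_r.) χ = 0 is the unit sphere; at
χ = 0.7, a_r ≈ 2.231 and b_r ≈ 0.669.

### Contact by surface sampling

Exact ellipsoid–ellipsoid intersection is deliberately avoided. A
(K+1)×L grid of surface points x(φ_k, θ_l), φ_k = πk/K, θ_l = 2πl/L, is
evaluated on each spheroid, and two cells are in contact when a sampling
point of either lies inside the other (body-frame quadratic form ≤ 1, the
boundary counting as inside with a 1e−12 floating tolerance). The test is
symmetrised by default — a one-sided variant (points of the lower-index
cell only) is available via `ModelParams(symmetric_contact=False)` — because
a one-sided test can miss a thin cell piercing a fat one between sampling
points. The two poles appear L times each in the grid; they are kept so
that indices match the (K+1)×L index set, and they are harmless because the
contact-rotation angle ∝ sin 2φ_k vanishes at φ = 0, π.

Against a dense 100×200 oracle grid, the default 11×8 sampling agrees on
≥ 97% of random χ = 0.7 pairs; every disagreement is a miss of a grazing,
near-tangent contact (sampling can only produce false negatives, since each
sampling point is a genuine surface point).

### Forces and update order

All quantities on the right-hand sides are evaluated at time t
(synchronous update):

1. contact repulsion F_r = −f_r·û per contacting neighbour (û the unit
   centre separation, pointing away from the neighbour);
2. attraction F_a = +f_a·û per neighbour with centre distance ≤ R_a
   (boundary inclusive); contact does not switch attraction off, so an
   interpenetrating pair feels the net radial push f_r − f_a;
3. drive D = d·v/‖v‖ iff ‖v‖ > v_zero_tol and some neighbour's centre is
   within R_a;
4. vᵗ⁺¹ = (1−γ₁)vᵗ + ΣF + D, then rᵗ⁺¹ = rᵗ + vᵗ (positions move with the
   old velocity);
5. frame update Rᵢ ← Q·P·Rᵢ with Q computed from vᵗ⁺¹ (see below).

Rotations: Q = exp(χ_rot·S(n)) with χ_rot = γ₂·sin 2ξ, ξ the angle between
e_x and vᵗ⁺¹ and n = e_x × vᵗ⁺¹ normalised (identity when the velocity
vanishes or is collinear with the axis — the sin 2ξ factor makes both the
parallel and antiparallel orientations fixed points, i.e. alignment is
nematic). P = exp(Σ ψ_k S(n_l)) summed over every penetrating sampling
point (k, l) of the cell's own grid across all contacting neighbours, with
ψ_k = −f_p·sin 2φ_k and n_l = e_z rotated about e_x by 2πl/L. The summed
generator is exponentiated once; a per-neighbour product variant
(`per_neighbor_rotation=True`) exists for sensitivity checks — at baseline
rotation strengths (10⁻³–10⁻²/step) the difference is negligible.

The frame-evolution rule rotates all three axes by R (not only e_x): the
contact-rotation axes n_l are built from e_z, so e_z must co-rotate for the
operator to stay defined; for a body of revolution the spin about e_x is
dynamically irrelevant.

### Parameters

| name | meaning | default | units |
|---|---|---|---|
| γ₁ | velocity friction per step | 0.1 | – |
| f_r | contact repulsion magnitude | 0.02 | length/step² |
| f_a | attraction magnitude | 0.001 | length/step² |
| d | drive magnitude | 0.002 | length/step² |
| R_a | interaction radius | 1.25·a_r | length |
| f_p | contact-rotation strength | 0.001 | rad/step per point |
| γ₂ | alignment-rotation strength | 0.01 | rad/step |
| K, L | sampling divisions | 10, 8 | – |
| v_zero_tol | speed treated as zero | 1e−12 | length/step |

R_a is stored as a rule (factor × a_r), so it scales with oblateness. The
model assumes f_r > f_a > 0 (excluded volume); the container also admits
zero force constants so degenerate oracle configurations (free decay,
momentum conservation, null dynamics) remain expressible.

## Numerical choices

- **Synchronous step, vectorised.** Candidate pairs come from a k-d tree
  fixed-radius query with cutoff max(2a_r, R_a) — no interacting pair can be
  farther apart — followed by an exact support-slab rejection (bodies whose
  projections on the centre line don't overlap cannot touch). The pruned
  search is bit-identical to the all-pairs loop (tested).
- **Frames** are re-orthonormalised each step by polar projection (SVD) to
  the nearest rotation; over 10⁵ steps orthonormality holds to < 1e−9.
  Cells with no active rotation that step keep their frame bit-identically.
- **Coincident centres** (protocol A introduces cells at the exact origin,
  so a newcomer can sit exactly on an existing cell) make the force
  direction 0/0. The unit separation is replaced by the major axis of the
  lower-index cell: deterministic given the state, isotropic across seeds.
  A fixed laboratory axis here would be a trap: with all cells seeded at one
  point, every separation, force and position would stay on that axis
  forever and the population would degenerate to an exact straight line.
- **Rotation exponentials** use the closed-form axis-angle (Rodrigues)
  formula, checked in tests against a 20-term matrix-power series.
- **Introduction timing** (protocol A): a cell is added before the step
  leaving every time divisible by the interval, including t = 0, which
  reproduces N_t = ⌈t/10⌉ at every recorded step (N₀ = 0; the first cell
  exists from t = 1).

## Pattern metrics

### Local order parameter Õ(ε)

For each cell the neighbour direction is the plain (unnormalised) vector sum
of e_x over all cells strictly within ε; the cell contributes |cos σ|
between its own axis and that sum. Cells with an empty neighbourhood, or a
neighbour sum of norm < 1e−12 (cancellation), have no defined angle; they
are excluded from the average and counted in the result (`n_excluded`).
Õ = 1 for perfect (nematic) alignment; for axes uniform on the sphere the
summed-neighbour direction is isotropic, |cos σ| is uniform on [0, 1], and
Õ → 0.5. Default radii: ε = 5, 10, 20, ∞ (∞ = all other cells).

### Box-counting dimension

Occupied-box counts on a grid anchored at the cloud's bounding-box corner,
with edge lengths descending by factor 2 from half the largest bounding-box
extent; the ladder stops before the scale at which the count exceeds n/3,
because counts then saturate toward one box per point and bias the slope
toward zero. The dimension is the least-squares slope of log N vs
log(1/edge) over the whole retained ladder, clipped to [0, 3]. Calibration
on uniform samples of known dimension (segment, square patch — also tilted —
and solid cube) recovers 1/2/3 within ≈0.1 at 10⁴ points and ≈0.15 at 500;
finite clouds carry a small negative bias from boundary-straddling boxes at
coarse scales, so comparisons between patterns should be made at similar n.
Degenerate input (all points coincident) returns dimension 0 with a flag.

### Replicates and trajectories

Replicate metrics are summarised by the sample mean with a Student-t 95%
confidence interval (appropriate at ~10 replicates). Cell mixing inside a
branch is inspected by projecting each cell's recorded positions onto a
user-supplied unit branch axis; crossings of the resulting 1-D curves are
overtaking events.

## Seeding protocols and the synthetic generators

Protocol A introduces one resting cell with a uniformly random axis
(normalised Gaussian draw) at the origin every 10 steps; protocol B places
all cells at once, uniform in an axis-aligned cube, resting, random axes.
The cube side for protocol B is not uniquely determined by the model; the
default pairs 2,500 cells with side 20 (the reference density), and
`cube_side=None` scales the side as (N/2500)^(1/3)·20 so that smaller runs
keep the same mean number density. At this density the initial packing
fraction exceeds 1 (cell volume is 4π/3 per unit-volume-normalised
spheroid), so bulk runs begin with widespread interpenetration and a strong
repulsive transient; see Limitations. A single seeded
`numpy.random.Generator` drives all draws, making runs bit-reproducible
from (config, seed).

The `fixtures` module generates analytic test surfaces: orientation fields
with known Õ (aligned → 1, uniform-random → 0.5), point clouds with known
dimension (segment 1, patch 2, cube 3), and a two-walker trajectory with
exactly one overtaking event. These calibrate the metrics; they do not
emulate simulator output (no velocity field, no contact structure), so
passing metric tests certifies the metrics, not the dynamics.

## Problem sizes used by tests and the acceptance script

Full-scale runs (2,500 cells, 25,000 steps) take tens of minutes; the test
suite and `scripts/acceptance.py` use scaled-down conditions chosen as this
package's standard check sizes: bulk (protocol B) runs with 500 cells at
the reference density for 5,000 steps, sequential (protocol A) runs of
2,500 steps (250 cells), and metric calibrations at 10⁴ points. The
acceptance script averages the bulk-run dimension over 3 seeds and the
random-axis order parameter over 5 seeds.

## Behaviour at baseline parameters, and limitations

- **Hit-and-run scattering.** At the baseline force balance, a contacting
  pair does not stay bound: the discrete-time bounce roughly doubles the
  infall speed (repulsion keeps adding impulse during the steps needed to
  climb back out of overlap), and the pair coasts to ≈3.1 length units —
  just beyond R_a ≈ 2.79 at χ = 0.7 — where it freezes. This is insensitive
  to the contact rule (one- vs two-sided), sampling fineness, impact
  parameter, and explicit vs semi-implicit position update.
- **Consequence for bulk runs.** Populations seeded at or near the
  reference density disperse through repeated scattering into a frozen,
  nearly isotropic cloud (box dimension ≈ 2.4–2.8 depending on n and χ)
  rather than condensing into persistent branch networks; the elongation
  dependence survives only as a modest monotone trend (rounder cells →
  higher dimension). Users who want persistent bound structures should
  explore stronger attraction/drive or weaker repulsion than the baseline.
- The box-counting estimator is scale-window-limited at n ≤ 500 (3–5 usable
  ladder scales); treat absolute values there as indicative.
- The dynamics are deterministic; all run-to-run variation comes from the
  seeding, so confidence intervals quantify initial-condition variability
  only.
- No walls or boundary conditions: dispersing cells travel arbitrarily far.
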