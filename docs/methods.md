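# Methods

`thallus` simulates and quantifies the cell-packing geometry of a flat,
single-cell-layer sheet of walled cells — the thallus of a bladed red
alga is the motivating system.  The sheet is a gap-free planar
tessellation: junctions (vertices), straight walls (edges) and simple
polygonal cells (faces), in µm/µm²/degrees.  This note records the model,
its assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## The data model and its invariants

A `Tessellation` stores junction positions, cells as counterclockwise
junction cycles, and a wall registry keyed by junction pairs.  Enforced
invariants: every cell is a simple, positively oriented polygon whose
interior angles sum to (n−2)·180°; interior walls bound exactly two
cells; walls intersect only at shared junctions; the union of cell
polygons is a single hole-free polygon whose area equals the sum of cell
areas; and for every connected non-periodic patch F − E + V = 1 (outer
face excluded).  `validate()` checks all of these and reports offenders.
Periodic (toroidal) lattices exist purely to probe the uniform-degree
limits — a tiling whose junctions all have degree z averages 2z/(z−2)
sides per cell — and support no geometric queries.

Side counting follows the microscopy convention: a boundary segment is a
side only if longer than the wall thickness (`min_side_length`, default
1 µm); shorter segments merge into the following side counterclockwise.
Counting never edits the mesh.  Angles are measured on the counted-side
polygon; measuring on the raw polygon instead is available through
`min_side_length=0` (the convention choice is a config switch because the
measurement protocol for merged sides is underdetermined).

## Division

A division transects a *pair of sides*: each is split at a cut point, a
new straight wall joins the two points, and the mother is replaced by two
daughters.  Bookkeeping of the tricellular cut: +1 cell, +3 walls, +2
junctions of degree exactly 3, +6 total per-cell sides (each neighbour
across a cut wall gains one).  These are asserted in fuzz tests after
every division.

**Pair selection** (`pair_selection="paper"`): with probability
1 − `connected_pair_prob` (default 0.994) the cut pair is unconnected and
chosen to equalize the daughters: among all unconnected pairs, midpoint
cuts within `area_balance_band` (2% of cell area) of the best area
balance count as equally balanced; among those the cut that splits the
boundary sides most evenly wins, then the shortest new wall (Errera's
rule for walled cells), then a uniform random choice.  The
shortest-wall/side-balance preferences replace a purely random
tie-break because uniform tie-breaking lets aspect ratios random-walk
into slivers that the side-counting threshold then locks out of
division; with Errera's rule aspect ratios self-correct (a cut across an
elongated cell's short axis halves its elongation).  With probability
`connected_pair_prob` a connected (adjacent) pair is cut instead,
producing a transient triangular daughter — matching the observed 0.6%
exception rate.  A `uniform_pair` mode and a `fixed` mode (used for the
transverse cuts of the filament stage) are also provided.

**Cut jitter.** The cleavage plane starts as the midpoint-to-midpoint
chord of the selected pair, then is rotated about its centre by a normal
angle (sd `cut_tilt_sd_deg`, default 12°) and translated perpendicular to
itself by a normal offset (sd `cut_shift_frac`·√area, default 0.03), and
re-intersected with the boundary.  The tilt moves both cut points off the
side midpoints while conserving the area balance; only the small shift
unbalances the daughters.  This two-parameter decomposition is what
reconciles the two observed symmetry statistics simultaneously: the
division section DS = |S1/(S1+S2) − 0.5| averages ≈ 0.12 (measured on
real divisions: 0.13 ± 0.03) while the size ratio SR = As/Ab stays near
0.79–0.80 (measured: 0.86 ± 0.03).  Independent per-wall jitter cannot do
this — it drives SR down to ≈ 0.71 and, on elongated cells, produces
extreme oblique cuts.  Defaults were calibrated to the two measured
means; both are configuration knobs, not fitted constants.

**Minimum wall length.**  Cut points may not land within
`min_wall_length` (1 µm, the physical wall thickness) of an existing
junction, so every fragment a division creates remains a countable side.
Without this constraint, sub-µm fragments accumulate and the counted-side
statistics decouple from the topology.

**Null models.**  `random_cleavage_null` gives the probability that a
random cleavage transects a *connected* pair of a regular n-gon under
three nulls: uniformly random side pair (2/(n−1)); two uniform perimeter
points; and an isotropic uniform random (IUR) chord, computed in closed
form from the integral-geometry measure of lines meeting two adjacent
sides, m = a + b − d (which reduces to 2 − 2cos(π/n)), with a Monte-Carlo
cross-check required to agree within 3σ.  No null is privileged: the
observed ~0.6% connected-pair rate is far below all of them.

## Wall reorientation (relaxation)

Splitting a straight wall leaves a 180° angle in the neighbour cell;
time-series observation shows this angle decreases at 20 ± 3°/day for
about two days.  The rate is kinematic, so the dynamics are the simplest
that reproduce it: junction positions descend the angular-deviation
energy E = Σ_junctions Σ_angles (θ − 360°/degree)², with each junction's
step sized (by line search along the descent direction) so its largest
angular deviation shrinks by `rate × timestep` per step.  Only junction
positions move; topology never changes; moves that would fold a cell,
increase the local energy, or squeeze a wall below `min_wall_length` are
halved and ultimately rejected, so the gap-free tiling is preserved and
E is non-increasing.  Boundary junctions (on the sheet margin) have no
well-defined target angle and do not move.

`RelaxationParams`: `rate` 20°/day, `window` 2 days, `timestep` 0.1 day,
`max_step` 1 µm, `age_gate` on by default (only junctions younger than
the window move, matching the observed two-day persistence).  The
mature-sheet study conditions (`growth.mature_config`) disable the age
gate so the whole sheet relaxes to steady state between divisions — the
natural meaning of "mature, relaxed" for a sheet observed long after its
divisions; a daughter angle and a neighbour angle relax under the same
single global rate, since the observation quantifies only the neighbour
angle.

## Growth simulation

Development is staged: a single quadrilateral founder (10 × 14 µm);
transverse (fixed-pair) divisions building a file whose target length is
sampled uniformly in [4, 10] cells; then 2D proliferation.  Growth is
uniform: all positions scale so every area grows at `growth_rate`
(default 0.4/day) — shape-preserving isotropic scaling (an axis-restricted
variant exists for filament experiments).  Division is size-triggered:
a cell becomes eligible above `division_area_threshold` (150 µm², giving
cells of roughly 8–15 µm across, the scale seen under the microscope),
with a per-cell lognormal factor (`threshold_jitter`, sd 0.1) expressing
cell-cycle heterogeneity; the largest eligible cell divides first, which
keeps areas homogeneous.  Divisions are restricted to the dark half of
each day (`night_division`), as observed.  All randomness flows through
one seeded generator: the same config and seed give bit-identical event
logs and meshes.

Problem sizes used in the shipped analyses: mature runs stop at 500
interior cells (about 600 divisions, ~15 s each); the Euler check runs a
500-division trajectory; these sizes put ~80% of cells in the interior
while keeping a five-seed sweep under two minutes.

## What the simulations reproduce, and what they do not

Across five seeds of the mature study conditions the simulated sheets
give: mean interior side number 5.93–5.95 (observed on long thalli:
5.72–5.97, approaching the hexagonal limit 6); tissue-mean interior
angle 119.3–119.5° (observed 112–119°, hexagon limit 120°), identical by
construction to the angle-sum identity 180°(1 − 2F/Σn), which the
pipeline computes through both routes as a cross-check; 71–77% of
interior angles in [100°, 140°] (observed > 60%); 100% 3-fold junctions
(observed 99 ± 1%); mean DS ≈ 0.12 and mean SR ≈ 0.79.

The 5–7-sided fraction of interior cells comes out at 79–84%, short of
the ~90% counted on real mature thalli.  This is a property of the model
class, not a numerical artifact: a mean-field Markov chain of the same
kernel — balanced equal division plus one side granted to each of the
two neighbours across the cut walls — has a stationary 5–7 fraction of
0.84, and the geometric simulation sits at its kernel's equilibrium.
Real tissue evidently concentrates the polygon distribution further
through mechanisms (lower-variance side gains, coordinated division
timing, rearrangement) that the observations here do not quantify, so the
package reports the honest model value rather than tuning toward the
empirical one.  The observational statistics themselves (DS, SR, the
93% of dividing cells with 5–7 sides, the n = 6,434 side counts) are
encoded as benchmark intervals in `metrics.PAPER_BENCHMARKS` and checked
by `benchmarks_table`, with parameter-recovery tests (the planted
cleavage tilt is recovered from a generated log within 3 SE) standing in
for reproduction of the raw counts.

## Synthetic data

`synthetic.make_fixture` fabricates segmented-cell datasets with known
ground truth: regular lattices; perturbed Voronoi mosaics (triangular
seed grid, jitter fraction `seed_jitter`, zero jitter giving exact
hexagons — the classical generator of hexagon-dominated mosaics); and
growth-simulation outputs.  Measurement error jitters *junction*
positions (shared vertices, as a shared-boundary segmentation produces),
so noisy fixtures remain gap-free by construction; draws that would fold
a cell or flip a wall across the side-counting threshold are redrawn, so
side counts survive digitization noise exactly and the tissue-mean angle
— pinned by the angle-sum identity — is recovered exactly, while the
angle spread degrades with noise.  The generator does not emulate
segmentation failure modes (merged/split cells) or pixel rendering.
A planted Lewis-law slope is rejected as infeasible: no closed
construction yields a gap-free tiling with prescribed class-mean areas;
the Lewis fit is instead validated against a brute-force groupby
regression on the same mesh and a planted (n, area) line on the
regression helper.

## Numerical choices and degenerate inputs

Geometric predicates use exact float comparisons with explicit
tolerances: gap-free area mismatch < 1e-6 relative; angle sums to 1e-6
relative; daughters must partition the mother's area to 1e-6 relative.
Degenerate cut draws (a plane through a vertex, fewer or more than two
crossings, a stub below the wall thickness) are redrawn up to
`max_retries`, then the exact midpoint cut is tried, then the division
fails with a diagnostic — a failed division never corrupts the mesh, and
the scheduler simply skips that cell for the night.  Degree-2 junctions
(possible on imported outlines) are merged by `canonicalize`, except
boundary corners, which are geometric.  Lattice tori need at least 3
rows and columns; smaller tori would collapse distinct walls onto one
junction pair.

## Known limitations

Cells are straight-walled polygons on a flat plane: no curved walls, no
3D, no two-layer thalli, no rhizoids or basal cell rounding.  There is
no mechanical model — no pressure, tension or force inference — so the
relaxation reproduces the measured angular kinematics, not their cause.
The division scheduler (size trigger, nightly gating) is a declared
approximation; the observations do not state how many divisions occur
per night or per cell cycle.  Boundary (margin) cells never relax and
their statistics are excluded, as in the microscopy protocol.
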