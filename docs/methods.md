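# Methods

`lexiplan` implements automated multi-criterial IMRT planning for
locally advanced non-small-cell lung cancer (LA-NSCLC) at desk scale:
wish-list-driven lexicographic fluence-map optimization (FMO) with
integrated beam-angle optimization (BAO), followed by an automated
DVH-to-objective handover to a surrogate re-optimizer, exercised on
synthetic 2D thorax phantoms.  This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Phantom model

A phantom is an axial cross-section on a regular grid: an elliptical
body outline, two elliptical lungs, a mediastinal heart, a small
posterior esophagus and spinal canal, and a circular PTV placed in the
ipsilateral hemithorax.  Organ centers and semi-axes receive seeded
uniform jitter (half-width 4 mm by default) so that seeds form a
reproducible population.  Masks are resolved to be mutually exclusive in
the order spinal canal > esophagus > heart > lungs; the PTV may overlap
soft tissue but never the spinal canal.  Invariants (containment in the
body, non-empty simply-connected geometry, laterality consistent with
the PTV centroid) are asserted after every generation.

Two grids are used throughout:

* **default** — 2.5 mm voxels, 96 x 128 grid;
* **study** — 3 mm voxels, 76 x 112 grid, PTV radius 22 mm with its
  center 55 mm lateral.  3 mm is the coarsest spacing that still
  resolves the innermost 3 mm conformity shell, and the medial tumor
  position reflects the dominant LA-NSCLC presentation in which nodal
  volumes extend the target into the mediastinum.

Derived structures: *shells* are one-voxel bands of voxels whose
Euclidean distance to the PTV lies in `[d, d + voxel diagonal)` for
d = 3 mm / 1 cm / 3 cm / 7 cm (a band of one voxel diagonal is the
smallest discrete set that is reliably non-empty); the *external ring*
is the 2 cm band inside the body surface minus the 4 cm-dilated PTV.
Both use exact Euclidean distance transforms and are checked against
O(N^2) brute-force oracles in the tests.

## Dose engine

Parallel (non-divergent) beamlets with IEC 61217 gantry angles (0 deg
anterior, increasing to patient-left).  For each beamlet,

* radiological depth is the density-weighted line integral back toward
  the source, computed by fixed-step midpoint quadrature (default step
  1 mm, study fixtures 2 mm) with nearest-voxel density sampling —
  this quadrature *is* the model's definition of depth, and the test
  oracle evaluates the same integral scalar-by-scalar;
* the primary fluence attenuates as `exp(-mu * depth)` with
  mu = 0.005/mm (water-like at ~6 MV beam quality);
* densities are body 1.0, lungs 0.25, tumor 1.0, air 0;
* the lateral profile is a top-hat of the beamlet width (default 10 mm,
  study fixtures 15 mm) convolved with a Gaussian penumbra
  (sigma = 3 mm); entries below 1e-4 of the entrance dose are dropped,
  keeping the matrix sparse.

Beamlet grids span the PTV's lateral projection plus a 10 mm margin.
There is no scatter, divergence, or build-up; the model is the smallest
one in which depth and laterality trade off the way beam-angle
optimization needs them to.

## Wish-list and LTCP

The default wish-list carries seven hard constraints (PTV max
1.02 D_p, PTV mean at least 0.997 D_p as the coverage floor, spinal
canal max 47 Gy, brachial plexus max 60 Gy when present, shell and
external-ring maxima) and thirteen prioritized objectives: PTV coverage
via LTCP first, then staged lung/heart/esophagus mean-dose goals
interleaved with shell maxima steering conformity, ending with
unconditional mean-dose minimization (goal 0).

LTCP — logarithmic tumor control probability — is the convex coverage
surrogate

    LTCP = (1/m) * sum_j exp(-alpha * (d_j - d_ref)),

with d_ref = 0.95 D_p and alpha = 0.85/Gy at D_p = 60 Gy, 0.80/Gy at
66/70 Gy; its goal (= sufficient) value is 0.14 at 60 Gy, 0.12
otherwise.  It equals 1 on a uniform dose at d_ref and is strictly
decreasing and convex in every voxel dose.  All internal computation is
in log space: log-sum-exp is convex, overflow-free for cold voxels, and
its softmax gradient has bounded norm.

## Two-round lexicographic optimization

Objectives are minimized one at a time in priority order.  After each
round-1 stage, a constraint is inserted: the *Goal* value if the optimum
reached it (deliberately leaving head-room for lower priorities, even
when further improvement was possible), otherwise the achieved value
multiplied by the relaxation factor (default 1.03; the clinical quantity
is configurable, only "some relaxation" being prescribed).  In round 2,
every objective *without* a Sufficient value is re-minimized to the
fullest extent in priority order, its bound replaced by the new optimum;
objectives with a Sufficient value are left alone.  During round-2
re-minimization all other objectives' current bounds stay fixed.
Inserted bounds carry a 1e-9 relative slack to absorb solver round-off.

Solvers: stages whose objective and active bounds are all linear are
LPs, solved with HiGHS.  Stages involving LTCP (as objective or bound)
are solved by SLSQP on the log-sum-exp form inside an outer active-set
loop: the SQP subproblem sees only the linear rows nearly active at the
warm start (previous stage solution), violated rows of the full set are
appended, and the loop repeats until everything holds to 1e-8 relative.
If SLSQP stalls, linear-objective stages fall back to Kelley cutting
planes (tangent cuts to the LTCP level set, placed where the segment
from the last feasible point crosses the boundary) and LTCP stages to a
trust-region solver.  Max-type objectives are linearized with an
epigraph variable; per-voxel Max rows that no beamlet reaches are
dropped as trivially satisfied.

### Comparison vectors

Two plans are compared lexicographically on the **goal-clamped round-1
stage-optimum vector** (`FluencePlan.score_vector`), not on the final
achieved values:

* at the first index where two round-1 vectors differ, both runs carry
  identical inserted bounds, so "smaller is better" is sound there; the
  final achieved values, by contrast, depend on how much slack earlier
  relaxed bounds left and are *not* monotone when the feasible set
  grows;
* entries are clamped at the Goal because two plans that both meet a
  Goal are equally good on that objective by wish-list semantics (round
  1 inserts the Goal either way); unclamped comparison would reward
  over-achieving high priorities at the expense of everything below —
  precisely the greediness the Goal mechanism exists to suppress.

With this vector, adding a beam to a greedy trajectory provably never
worsens the comparison (feasible-set inclusion), which is the nested
monotonicity property the test-suite asserts.

## Beam-angle optimization

Greedy sequential selection over the ipsilateral candidate arc
(140 -> 40 deg through 270 deg for right-sided tumors, 320 -> 220 deg
through 90 deg for left-sided; 5 deg clinical spacing, thinned to 26 deg
in the desk-scale studies).  Each iteration runs the full two-round FMO
for every unused candidate added to the current set and keeps the
lexicographically best score vector; ties go to the earliest candidate.
Influence is traced once for the entire arc, trial sets being column
subsets, so candidates are judged on exactly the dose model the final
plan uses ("integrated" BAO).  The true clinical BAO algorithm is more
elaborate; the greedy scheme is this package's own design, with
exhaustive search as a test oracle at tiny sizes.

With one or two beams the full wish-list is infeasible — a single beam
cannot satisfy the PTV coverage floor and the entrance-dose caps
simultaneously.  Iterations where no candidate is feasible rank
candidates by *elastic infeasibility*: the minimal uniform relative
relaxation `s` of the hard constraints (`a.x <= b + s(1+|b|)`, single
elastic variable) that admits any plan.  Once enough beams are selected,
normal lexicographic scoring resumes; plans are only recorded for
feasible beam counts.

The nested trajectory yields 4/6/8-beam plans from a single greedy run,
which is how the beam-count study is produced.

## Handover and surrogate re-optimization

Each OAR DVH of the (PTV-median-normalized) FMO plan becomes a *line
objective*: dose-volume points every 0.7 Gy from 0 up to and including
the first multiple at or above the curve's maximum dose, volumes
linearly interpolated.  The objective template adds fixed PTV min/max
points at D_p -/+ 0.5 Gy (priority 130), OAR max points (spinal canal
48 Gy, brachial plexus 62 Gy, priority 100), line priorities
(lungs/heart 80, esophagus 60, spinal canal/plexus 40) and a normal
tissue objective (NTO): allowed dose 105 % of D_p at 5 mm outside the
target border decaying exponentially (rate 0.15 per mm — the concrete
fall-off form is this package's reading of the parameter) to 60 % far
away.  Templates serialize to a documented XML schema.

The surrogate re-optimizer rebuilds a plan from the template by
minimizing a priority-weighted sum of one-sided quadratic penalties
(L-BFGS-B, analytic gradients, nonnegative fluence): PTV band
violations and max-point violations in Gy^2, line-objective violations
in volume percentage points squared with the voxel count smoothed by a
logistic step of width 0.25 Gy, and NTO violations against the
distance-dependent threshold.  Three calibration parameters matter:

* `VOLUME_WEIGHT = 25` — relative weight of squared volume excess
  against squared dose excess (the units are incommensurable; this
  setting reproduces DVHs tightly without surrendering the PTV band);
* a weak proximal anchor (1e-4 of the summed term weights) on the
  starting fluence — the one-sided penalties are indifferent between
  many minimizers, and the anchor keeps the solution from wandering
  through that degenerate set;
* a strong dose-reproduction term (`REPRO_WEIGHT = 5e6` per unit
  priority) pinning each line-objective structure's voxel doses to the
  handed-over plan whenever a starting fluence is supplied.  The
  handover's contract is DVH reproduction, and on small structures a
  single voxel crossing a 0.7 Gy sample already moves the DVH by
  several percentage points, so reproduction must hold voxel by voxel;
  residual dose deviations are ~1e-4 Gy.

The optimum of the weighted sum is invariant under a common rescaling of
all priorities (every term, including anchor and reproduction, scales
with them).  Because the same influence matrix is reused and no leaf
sequencing is modelled, handover fidelity is measured purely as DVH
reproduction; the commercial optimizer being emulated keeps its penalty
semantics proprietary, and no equivalence is claimed.

## Evaluation machinery

* **Wilcoxon signed-rank** (two-tailed): zero differences dropped; for
  up to 12 remaining pairs the null is enumerated exactly over all sign
  assignments conditional on the observed (tied) ranks, two-tailed p by
  doubling the smaller tail; above 12 the tie-corrected normal
  approximation (no continuity correction) is used.  p <= 0.05 is the
  conventional significance threshold applied by callers.
* **Population DVHs** — pointwise means on a common resampled axis.
* **Paired DVH difference bands** — percentile bootstrap over subjects
  (2000 resamples, seeded); the band construction behind such figures
  is rarely stated, and the bootstrap is this package's choice.
* **Metric tables** — the standard panel (PTV V_95%; lungs
  D_mean/V_5Gy/V_20Gy; heart D_mean/V_5Gy/V_30Gy; esophagus
  D_mean/V_20Gy/V_60Gy) with median, IQR and Wilcoxon p per metric.
* **DVH conventions** — cumulative, 0.1 Gy bins; V_xGy by direct voxel
  counting (not curve interpolation, avoiding bin bias); even-count
  medians are midpoints of the central order statistics; V_95% uses
  0.95 x D_p.

## Study conditions and problem sizes

The cohort experiments (beam-count study, BAO-versus-template
comparison, the acceptance script) run ten seeded study phantoms;
per subject one greedy trajectory to 8 beams over the 26 deg arc plus a
fixed-template 6-beam plan, roughly 70 FMO solves in ~1-2 minutes.
These sizes are the package's desk-scale defaults: large enough that
the lung/heart/esophagus trade-offs and the beam-count effect are
physical, small enough that the whole study is an interactive
computation.

## What the synthetic studies do and do not show

The phantom population exercises every algorithmic contract — priority
protection, goal/sufficient bookkeeping, BAO dominance over fixed
templates, handover fidelity, the sign of the beam-count effect on OAR
sparing.  It does **not** emulate: 3D dose spread (a single axial slice
concentrates all beams in the OAR plane, so absolute OAR doses run far
above clinical values and some volumetric audit limits are structurally
hard); anatomical variability beyond jittered ellipses (the cohort is
homogeneous in laterality and topology); breathing motion, CT
heterogeneity beyond a uniform lung density, or deliverability
(segmentation, monitor units, QA are out of scope).  Passing tests
validate the method's logic and its qualitative physics, not clinical
dose levels.

## Known limitations

* Greedy BAO is a stand-in for the clinical integrated algorithm; it is
  exact only for the first beam.
* The esophagus beam-count effect is the least stable quantity the
  study reports, and at the frozen conditions the 6 -> 8-beam median is
  *adverse* — opposite to the clinical finding.  The mechanism is a
  lexicographic squeeze: the esophagus holds the lowest OAR priorities,
  and with more beams every higher-priority stage achieves better
  round-1 optima, so the relaxed bounds inserted above it tighten and
  its own re-minimization inherits a smaller feasible set.  In 3D the
  geometric freedom from extra beams outweighs the squeeze; in a single
  axial slice, where the esophagus lies in the plane of every
  posterior-oblique beam, it does not.  The sign also flips under
  half-beamlet shifts of the fluence grid, i.e. it is chaotic at this
  scale.
* SLSQP accuracy (~1e-7 relative on stage optima) bounds the precision
  of LTCP-coupled stages; pure-LP stages are HiGHS-exact.
* The surrogate re-optimizer with a supplied starting fluence is, by
  design, a minimal-change operator; templates used without a starting
  fluence optimize from zero and will not reproduce any particular
  plan.
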