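# Methods

This note documents the models, conventions and numerical choices behind
cytomorph, in the order the pipeline runs.

## Reconstruction repair and normalization

Raw tracings are repaired in a fixed order: **connect fragments → split
multifurcations → anterograde sort → resample**. The order matters only
for the first two steps (sorting requires a connected tree; resampling
requires a sorted one); fragment connection before splitting was chosen
so that a fragment root attaching to an already-binary branch point can
still be rewritten into a bifurcation chain.

* **Fragment connection** is greedy nearest-pair: at each step the
  fragment whose closest node is nearest (Euclidean) to the
  already-connected component is re-rooted at that node and joined
  there. The designated soma root always remains the root. The manual
  procedure this replaces is interactive and under-specified; greedy
  nearest-pair is the deterministic, oracle-checkable reading.
* **Multifurcation splitting** inserts helper nodes at the parent's own
  coordinates, producing zero-length compartments. These are permitted
  internally and contribute 0 to every length sum, so no geometry is
  perturbed.
* **Resampling** (default spacing 2 μm, the granularity all metrics and
  the simulator share) re-places nodes along each branch polyline at
  arc-length multiples of the spacing, interpolating radius linearly.
  Branch points and tips are preserved exactly; the final compartment of
  each branch carries the sub-spacing remainder rather than
  redistributing it, so bifurcation/tip geometry is untouched and total
  branch length is preserved along the polyline. (Chord lengths of a
  curved polyline are ≤ the arc they replace, so total tree length can
  only decrease, never grow.)
* **Scaling** converts pixel units to microns per axis. The default
  factors (0.593, 0.593, 1, 0.593) for (x, y, z, radius) correspond to
  0.593 μm pixels with 1 μm z-steps; change them to match the
  acquisition.

Writers renumber nodes 1..N in stored order (anterograde for sorted
trees), because resampling and splitting invalidate any original
numbering. Floats are serialized via `repr`, so read–write round trips
are bit-exact.

## Voxel-to-compartment assignment and channel statistics

A compartment's spatial extent is the frustum spanned by its node and
parent positions and radii (the root contributes its own sphere). A
voxel belongs to a frustum when the distance from its center to the
axis, at the clamped projection parameter t, is at most the radius
interpolated at t. Voxels eligible for several frustums are assigned
**disjointly** to the one with the nearest axis (ties to the smaller
node id), so no voxel is ever counted twice. Membership is a
voxel-center point test; anisotropic voxels are handled by working
entirely in micron coordinates, with voxel (i,j,k) centered at
((i+0.5)·vx, (j+0.5)·vy, (k+0.5)·vz).

Acquisition runs once per signal. Within each compartment, S is the set
of assigned voxels whose *primary*-channel intensity passes threshold
and T ⊆ S those whose *secondary* intensity also passes. The recorded
statistics are F = |T|/|S|, ASI = mean secondary intensity over T, and
the population SD over T (|T| ≤ 1 → SD 0; S or T empty → all three 0).
The fraction denominator is |S| — both thresholds apply, one per
channel. Thresholds are **inclusive** (≥): intensity exactly at the
threshold is counted. The default threshold is 10 on the 0–255 scale.

The vectorized implementation deliberately evaluates the membership
formula with the same left-to-right floating-point arithmetic as a
scalar loop, so it is exactly reproducible against a brute-force voxel
enumeration — the equivalence the test suite asserts on randomized
stacks.

## The 20 per-compartment metrics

Column order is fixed (`quantify.METRIC_COLUMNS`). Conventions the
literature leaves open:

* **Topological distance** is the edge count from the root (distinct
  from **path distance**, the summed compartment lengths in μm).
* **Branch order** counts bifurcations on the root→node path.
* **Intensity** = F·ASI (CQ with the width factor removed).
* **Relative changes** are (current − parent)/parent, NaN at the root
  and wherever the parent value is 0; NaN rows are excluded from
  downstream curves.
* **Arbor length** is the summed length strictly downstream: total
  neurite length at the soma, exactly 0 at tips.
* **Strahler order** is the standard scheme (leaves 1; equal children
  increment; elongations inherit).
* **Integral microtubule / F-actin** is defined here as the downstream
  sum of CQ·compartment-length including the compartment itself — the
  cytoskeletal analogue of arbor length. No published formula pins this
  down; the choice is documented, not asserted as anyone else's.
* Axonal and somatic compartments keep their rows (a `compartment_type`
  column supports filtering); profiles accept a `dendrites_only` flag.

Distribution profiles bin compartments by Strahler order (integer bins)
or path distance (default width 25 μm, configurable; no canonical value
exists) and sum length, CQ·length (microtubule) and CQ·length (F-actin)
per bin; binned length always sums to total neurite length. Group
normalization divides the cytoskeletal bins by the reference group's
mean per-neuron totals, so the reference group's mean normalized total
is 1. Pearson correlations of arbor length against the five local
predictors pool compartments across the neurons of a group (per-neuron
averaging would weight small neurons up; pooling matches a
per-compartment reading); zero-variance predictors yield NaN rather
than 0.

## Growth model

Tips are processed breadth-first; each carries (position, direction,
mt, fa). Per iteration, one uniform draw selects the event from

* p_term = exp(−k_term·mt) — termination approaches certainty as the
  microtubule supply is depleted (k_term·mt → 0) and vanishes for a
  well-supplied tip;
* p_bif = (1 − p_term)·min(1, k_bif·fa) — branching promoted by local
  F-actin;
* p_elong = the remainder.

Elongation advances one `step_length` (2 μm, matching the resampling
spacing so real and simulated trees share compartment granularity),
decays mt by `mt_decay`, resamples fa ~ max(0, N(initial_fa, fa_sd)),
and jitters the direction by an isotropic Gaussian (SD
`direction_jitter`) before renormalizing. Bifurcation multiplies the
branch compartment's fa by `fa_branch_boost`, splits mt between the
daughters by a symmetric Beta(`mt_split_concentration`) draw — summing
exactly to the parent's mt — and sends the daughters off at
±`branch_half_angle` about the parent direction. The RNG is a single
`numpy` generator consuming draws in a fixed documented order (event
uniform; then per event: jitter normals + fa normal for elongation, or
Beta + perpendicular normals + two fa normals for bifurcation), so one
integer seed reproduces a neuron byte-for-byte. Growth stops when all
tips have terminated or `max_compartments` is reached (the neuron is
then flagged truncated).

These functional forms are this package's concrete instantiation of
growth that depends stochastically on cytoskeletal composition; they sit
behind `sample_event`/`event_probabilities` and are swappable without
touching the growth loop.

**Preset calibration.** The termination hazard exp(−k_term·mt) is
negligible until mt ≈ 3/k_term, and bifurcation halves the conserved mt
pool, so expected arbor depth scales as log₂(mt₀·k_term/3). The shipped
presets (JSON files under `cytomorph/presets/`) were chosen from this
reasoning to produce scaled-down arbors of realistic complexity:
`class4` (mt₀ = 200, k_term = 0.5, k_bif = 0.10, mt_decay = 0.01) grows
≈ 480 compartments (≈ 960 μm) with ≈ 40 terminal tips (medians over
seeds); `class1` (mt₀ = 40, k_bif = 0.04) ≈ 130 compartments with ≈ 6
tips; `class4_form3oe` is `class4` with the branch-point F-actin
enrichment reduced to 1.2, mimicking a manipulation that blunts
branch-point actin accumulation. These are calibrated against this
package's own synthetic targets, not claimed to equal any published fit.

Simulated neurons carry no imaging, so their quantification keeps 17 of
the 20 metrics: the two image-intensity normalizations and the
compartment-type column are dropped (simulated trees are all dendrite).
Because the growth model does not represent branch thickness, simulated
compartments use nominal width W = 1; quantity and intensity then
coincide numerically, which also makes the intensity relative-change
columns well defined (equal to the quantity ones).

Real-vs-simulated comparison aligns profiles on a shared axis/binning
(shorter profiles zero-padded), reports per-bin group means, and scores
each bin with |real − sim| / max(|real|, |sim|) — symmetric, 0 iff the
means agree, and scale-free per bin. The overlay plot draws real means
as thick light lines behind thin dark simulated lines.

## Synthetic data: what it emulates and what it does not

`synthdata` generates seeded random binary trees (exactly `n_leaves`
tips, 2 μm node spacing, radii tapering per branch order, growth near
the xy-plane to fit thin confocal stacks), paints a per-compartment
ground truth — microtubule ASI decaying exponentially with path
distance, F-actin ASI uniform except `fa_branch_enrichment`-fold at
bifurcation compartments, F = 1 inside every tube — and renders it into
a two-channel 8-bit stack at the default (0.593, 0.593, 1) μm voxel
size. Painted intensities are integer-rounded and floored above the
detection threshold, so in the noise-free limit acquisition recovers
them exactly; voxel noise is clamped Gaussian (not Poisson — enough to
exercise thresholding, and the noise model is a parameter slot). Tube
voxels are painted per assigned compartment, so the painted truth and
the acquisition share one voxelization.

Consequences for interpreting green tests: passing the recovery loop
shows the assignment/statistics/metrics chain is self-consistent and
exact under the generator's assumptions (piecewise-uniform signal,
known geometry, no optics). It does **not** show robustness to PSF blur,
tracing error, chromatic shift, or signal heterogeneity within a
compartment — none of which the generator models.

## Degenerate inputs and tie-breaks

Zero-length compartments (from multifurcation splitting) contribute 0 to
all length sums and are treated as their parent's location for voxel
assignment. Equal-distance voxel ties go to the smaller node id. Empty
event classes yield empty FΔ curves with a warning rather than an error.
Trees wholly outside a stack, non-positive spacings/factors/bin widths,
channel-count mismatches and paired-file topology mismatches raise
immediately with the offending quantity named.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
sized for exactness rather than scale: oracle stacks ≤ 17³ voxels
(randomized shapes), recovery stacks fitted to ≈ 75-node trees, 10⁵
event draws for the simulator frequency audit, and eight 12-leaf trees
per pooled qualitative group. All are the package's own choices and can
be scaled up through the same parameters.

## Known limitations

Single pre-stitched stacks only (no tile stitching); no image-guided
retracing or interactive editing; no automatic threshold selection; no
hypothesis testing between groups; the growth model is static (no
time-varying dynamics, self-avoidance or scaling); frustum membership is
a voxel-center test, so sub-voxel partial-volume effects are ignored.
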