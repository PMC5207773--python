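# Methods

`striomap` reimplements, as a tested library, the computational chain used
to build mesoscale excitatory input maps of the striatum from anterograde
viral tracing: alignment of sectioned volumes, graded projection-density
classification, input-convergence statistics, multi-criterion thalamic
confidence maps, voxel-clustering parcellation, thresholded circuit-graph
extraction, and optogenetic EPSC metrics. All stages run on synthetic
scenes with planted ground truth, so every quantitative claim in the test
suite is a recovery or oracle-agreement statement, never a comparison to
inaccessible experimental data.

## Volumes and conventions

Volumes live on voxel grids with axis 0 = anterior→posterior (coronal
section index), axis 1 = dorsal→ventral, axis 2 = medial→lateral; voxel
centers at `(i + 0.5) · voxel size`. Projection volumes hold per-voxel
fractions in [0, 1] — the fraction of fine imaging sub-voxels containing
positive fluorescence after binning to 100 µm voxels. Binary masks
(striatum outline, injection volumes, projection fields) share the grid.
The analysis defaults mirror the tracing literature: 100 µm analysis
voxels, a 100 µm injection-core erosion, density-tier thresholds of 0.2 /
0.05 / 0.005, a 150 µm clustering voxel, and network cutoffs of 0.15 /
0.20 / 0.50, all exposed in `RunConfig`.

Morphological erosion uses a discrete L1 ("unit ball under
6-connectivity") structuring element whose radius corresponds to the
physical distance at the mask's voxel size, honoring anisotropic voxels
per axis. On isotropic grids this makes erosion distances additive
(d1 then d2 equals d1+d2), which the tests exploit. Connected components
use face adjacency (6-connectivity) — the conservative notion of
contiguity for coarse voxel grids; both choices are configurable where
they appear. An empty coverage target raises an error instead of
returning 0, because the inclusion criteria downstream divide by it.

## The synthetic scene generator

A scene emulates the study conditions the pipeline was designed for, at
desk scale:

* a bilateral striatum (two mirrored ellipsoids) with a small anterior
  blob playing the anterior commissure's role as an alignment landmark;
* the analyzed hemisphere partitioned into `n_planted_subdivisions`
  (default 4) contiguous Voronoi cells of comparable size — the planted
  analog of anatomical domains. Stray voxelization fragments are
  reabsorbed so each subdivision is one 6-connected component;
* 15 cortical "subregions" by default (the number of analyzed cortical
  subregions in such datasets), each assigned by round robin to exactly
  one subdivision. A subregion paints a dense core (fraction 0.5) on its
  signature subdivisions, a moderate ring (0.1, 2-voxel dilation) and a
  wider diffuse halo (0.02, 5-voxel dilation), emulating the
  dense-core-plus-diffuse-field structure of corticostriatal projections.
  Gaussian observation noise (default SD 0.02, truncated to [0, 1])
  stresses the tier thresholds;
* a unilateral thalamus covered by highly overlapping spherical
  injections on a jittered lattice (default 350 µm radius, 300 µm
  spacing); the radius grows until the union covers the configured
  fraction of the thalamus (default 93%, the coverage regime that makes
  sub-injection localization possible). Each injection carries its full
  mask, a core eroded by 100 µm, and the striatal projection field of the
  planted thalamic zone it falls in; a Voronoi "nuclear atlas" (default 8
  nuclei) supports coverage tables;
* fabricated corticocortical / corticothalamic density tables with
  planted block structure (strong 0.30 within a signature group, weak
  0.05 elsewhere, 0.02 jitter) — these enter the circuit stage
  preprocessed, as they would from an atlas API.

Scenes are deterministic functions of their configuration, including the
seed. What the generator does **not** emulate: axon morphology, imaging
point-spread, partial-volume effects at real tissue boundaries,
inter-animal variability of projection strength, or segmentation errors.
Passing tests therefore demonstrate that the *algorithms* recover planted
structure under controlled noise, not that they would be robust to every
artifact of real histology.

## Section-stack misalignment and its recovery

The forward model treats a section stack the way histology produces one:
an aberrant sectioning angle leaves the anatomy **sheared** along A-P in
the restacked volume (each section is a rigid slab displaced in-plane in
proportion to its A-P position — pitch shears D-V, yaw shears M-L), a
mounting roll is a true in-plane rotation of each section, per-axis
scales model shrinkage/stretch, and independent integer per-section
shifts model mounting jitter. This shear model is what makes
center-of-mass trend estimators unbiased; a volumetric rotation model
would attenuate the trends by a shape-dependent conjugate-diameter factor.

Alignment operates on stacks with fine in-plane resolution (default 25 µm
pixels under 100 µm sections), mirroring the standard practice of
aligning fine-resolution images before coarse voxelization: degree-scale
angles displace boundaries by fractions of a 100 µm voxel and are simply
not observable in coarse binary masks. The generator rasterizes the
misaligned anatomy analytically from its continuous geometry
(`make_alignment_experiment`), because resampling an already-voxelized
mask destroys exactly the sub-voxel information the estimators need — a
nearest-neighbour shear of a binary stack is indistinguishable from
integer jitter.

The correction chain:

1. **Jitter** is recovered template-free with an integer-lattice fit: the
   per-section center-of-mass curve is linear under the shear model, and
   jitter is integer-valued, so the slope is chosen to minimize the
   weighted squared distance of the residuals to the integer lattice
   (fractional offset per candidate slope in closed form via a circular
   mean). Slopes an integer apart are aliases on the lattice, so the
   search is capped below 0.5 voxel/section; the D-V curve uses the whole
   mask, the M-L curve the mean of the two per-hemisphere centers of mass
   (the bilateral-union center is distorted where one hemisphere ends
   before the other). An ordinary least-squares fit is *not* sufficient
   here: part of the true shear trend leaks into the rounded residuals.
2. **Rotation**: yaw from the A-P trend of the per-hemisphere M-L center
   of mass, pitch from the whole-mask D-V trend (both unit gain under the
   shear model), roll from the within-section row-wise M-L center-of-mass
   slope per hemisphere, divided by the conjugate-diameter gain
   (1 − σ²_ML/σ²_DV) computed from the mask's own second moments (roll
   is a true in-plane rotation, so slice-center paths are attenuated).
   Estimates are iterated on linearly-resampled float volumes until the
   residual vanishes (3 passes, 0.05° tolerance).
3. **Scales**: a second-moment ratio against the template normalizes the
   stack before angle estimation (rotation affects variances only at
   second order); the loop alternates normalization and rotation twice
   because the first moment estimate is slightly shear-contaminated.
   The reported scales are refined with the anatomical-landmark method:
   A-P from the ratio of half-peak-area spans of the section-area
   profile (a sub-section surrogate for first/last landmark sections),
   D-V from the averaged top-of-striatum-to-center-of-mass distance, M-L
   from the averaged dorsal width above the center of mass.
4. **Per-section shifts**: iterative center-of-mass alignment to the
   template (default 2 rounds), D-V from the whole-section center, M-L
   from the top half of the mask (rows above the per-section D-V median —
   the ventral outline is the variable one); anterior tip sections with
   under 25% of the peak area align on the anterior-commissure surrogate
   landmark; shifts for empty sections are interpolated from flanking
   sections. A round that would lower the whole-stack Dice is discarded,
   making Dice nondecreasing in the round count. Masks are resampled for
   correction as float volumes with linear interpolation and re-binarized
   at 0.5 (less boundary churn than chained nearest-neighbour lookups).

Recovery under the default conditions (angles up to ±5°, scales 0.9–1.1,
jitter ±4 fine voxels = ±100 µm, 10 seeded scenes): angles within 1°,
scales within 5%, interior per-section shifts (sections with ≥ half the
peak area; tips are landmark-aligned by design) within 1 voxel, Dice
≥ 0.9. Damaged sections are repaired as the voxelwise mean of their
neighbours, re-binarized at a strict > 0.5 (so a present/absent neighbour
pair yields an empty section).

## Density tiers, convergence, confidence maps

Voxel fractions are classified dense / moderate / diffuse at strictly
greater than 0.2 / 0.05 / 0.005 ("over" is read literally; a voxel at
exactly the threshold takes the lower tier). Tier *fields* are cumulative
by default — the diffuse projection field is the outer envelope including
moderate and dense voxels — switchable to exclusive tiers. Per-subregion
maps combine injections by voxelwise ordinal maximum. Axis profiles
normalize each fixed-width slab by its own striatal volume and mark
empty slabs as missing rather than zero.

Pairwise convergence of field B onto field A is the fraction of A's
voxels covered by B (rows = covered, columns = covering; not symmetric).
The per-voxel convergence count splits the striatum at its mean into a
high (>) and low (≤, boundary voxels go low) compartment. The elementwise
claim "diffuse convergence ≥ dense convergence" is exact for noiseless
scenes (dense fields of two subregions are either identical or disjoint
by construction); with boundary speckle noise it holds in the mean, and
the tests assert exactly that split.

Confidence maps localize, at sub-injection resolution, the thalamic
origin of projections to a striatal target. Each injection is scored
against ordered inclusion criteria — for graded targets, covering 10% of
the diffuse target, 5% of the dense target, 50% of the dense target; for
binary targets, covering 10% / 25% of the target and having 10% / 25% of
the projection within it (measures meet their cutoff at ≥). Per
criterion, the injections are combined into **union masks**: the union of
satisfying full volumes adds 1, the union of satisfying cores adds 1, the
union of failing cores subtracts 1, and the union of failing full volumes
subtracts 1 for the two easiest criteria only ("easiest" = most
satisfying injections, ties broken by the declared order — the ordering
is empirical per run and logged). After summation, voxels inside cores of
injections that satisfied no criterion are zeroed, negatives are clipped,
and the map is restricted to the thalamus — yielding exactly 2L levels
for L criteria (6 graded, 8 binary). Nuclear coverage reports, per atlas
nucleus, the fraction of voxels at confidence ≥ ℓ (levels are nested by
construction; == is available as a config switch) plus the across-level
average; overlay maps categorize voxels by per-map threshold exceedance.

## Parcellation

The striatum is rebinned to 150 µm voxels (fine voxels map to bin
`floor(i·fine/coarse)`, handling the non-integral 100→150 ratio with
alternating 1- and 2-voxel bins); the coarse category per input source is
the plurality over the bin's striatal fine voxels, ties to the higher
category (preserving dense cores at boundaries). Voxels are clustered
agglomeratively with average linkage under Spearman rank-correlation
distance (1 − ρ); constant rows, whose rank correlation is undefined, get
distance 0 to identical rows and 1 to everything else so all-zero border
voxels stay clusterable. The agglomeration is implemented in the package
(Lance-Williams average-linkage update with an explicit
lowest-cluster-index tie break) because merge order under ties must be
deterministic across platforms; distances are rounded to 12 decimals so
the many exact ties of ordinal data are invariant to column permutation.
The linkage matrix uses the scipy encoding, so cutting (by cluster count
or height) and cophenetic statistics interoperate with
`scipy.cluster.hierarchy`. Metric selection maximizes the cophenetic
correlation coefficient across candidate metrics. Singleton clusters are
dropped at a cut (their voxels flagged unassigned). Sources are clustered
the same way on the transposed matrix. Contiguity reports per-cluster
connected components and the largest-component fraction; recovered
clusters are "largely contiguous" — small satellites arise where a
boundary voxel's mixed signature matches a non-adjacent cluster. Voxels
with zero input everywhere are included by default (they form a "none"
cluster); a flag excludes them.

Recovery under default conditions: the k = 4 cut of a zero-noise scene
reproduces the planted subdivisions (ARI ≥ 0.95 per scene); at noise SD
0.05 the mean ARI over 20 seeded scenes is ≥ 0.9 (individual scenes range
roughly 0.78–1.0, the spread coming from occasional boundary-region
trades between clusters).

## Circuit graphs

All cutoffs are strict (>): corticocortical edges at density > 0.15 in
the target area; primary corticostriatal inputs to a subdivision by dense
occupancy > 0.20 of the subdivision (route 1) or > 0.50 of the dense
projections within it (route 2), each qualification annotated with its
route and measured fractions; corticostriatal convergence as the mean of
tier-matched coverage fractions (dense in dense, moderate in moderate,
diffuse in diffuse) with empty target tiers omitted from the mean and
logged, qualifying at > 0.50; thalamostriatal / thalamocortical /
corticothalamic edges at > 0.20 of the nucleus volume (corticothalamic
edges run cortex → nucleus). The graph is a typed, weighted
`networkx.DiGraph` with class-legality checks on every edge; exports are
lossless through edge-list CSV (+ node table) and GraphML. Rendering is
out of scope. A synthetic "broad" source projecting densely everywhere
qualifies as a primary input to every subdivision, mirroring how an
amygdala-like source behaves under these criteria.

## EPSC metrics

Traces are negative-going voltage-clamp currents with known stimulus
onsets. The generator sums unit-peak difference-of-exponential kernels
(default 1 ms rise, 5 ms decay constants, −200 pA) with per-stimulus
amplitudes given by an explicit list, a paired-pulse ratio, or a
geometric depression factor, plus an optional sustained slow component
(a plateau building from the first stimulus with a 15 ms constant) and
seeded Gaussian noise.

Responders require a post-stimulus peak strictly exceeding 6× the
baseline SD; a noiseless baseline is degenerate and falls back to an
absolute floor (5 pA, configurable). Peak search windows run from each
onset to the next (50 ms tail after the last) to prevent bleed-through.
Kinetics: amplitude against the 10 ms pre-stimulus baseline; 10–90% rise;
90–10% decay measured against the post-EPSC plateau (mean of the last
10 ms of the window), which subtracts any slow-current offset; crossing
times are linearly interpolated between samples. The paired-pulse ratio
measures the second amplitude against the extrapolated single-exponential
tail of the first EPSC (fit on [onset+20 ms, onset2); switchable to the
simple pre-stimulus mean), and returns nothing for cells failing the
≤ −100 pA first-EPSC inclusion rule (inclusive bound). Train dynamics
(10 stimuli at 20 Hz): per-stimulus amplitudes against the 2 ms
pre-stimulus level (so the slow plateau is subtracted), charge transfer
as the integral of baseline-subtracted current over 50 ms per stimulus,
both normalized to the first stimulus; the slow current is the change in
mean current (10 ms windows) before the tenth versus before the first
stimulus, normalized to the first EPSC peak. All metrics are invariant to
a constant holding-current offset, and noiseless round trips recover
planted PPR, depression factor, and slow fraction within 2%.

## Orchestration and reproducibility

`run_pipeline` executes simulate → align → density → converge → confmap →
cluster → network into a run directory, writing a manifest with the
config hash, library versions, and per-stage content checksums computed
from in-memory arrays (so two runs of one config produce byte-identical
manifests regardless of file timestamps). Stage failures abort with a
stage-tagged error. The `striomap` CLI exposes the stages as subcommands
over NIfTI/CSV/JSON artifacts. Problem sizes used throughout the test and
acceptance suites — 30–40 section scenes, ~4,500 striatal voxels per
hemisphere, 20–50 injections, 10–20 seeds per recovery claim — are the
package's chosen desk-scale study conditions; all thresholds and sizes
are config parameters.

## Known limitations

* The alignment estimators assume a bilateral, roughly ellipsoidal mask
  with both hemispheres present; the roll gain calibration degrades for
  nearly in-plane-isotropic shapes (an explicit error is raised).
* Jitter recovery assumes sectioning-angle slopes below 0.5 voxel per
  section at the alignment resolution (≈ 7° at 4:1 anisotropy) due to
  lattice aliasing.
* The per-injection projection fields of the synthetic thalamus are
  identical within a planted zone; real injections vary continuously.
* Average-linkage clustering is O(n²) memory in the voxel count; the
  150 µm default keeps n in the low thousands.
* The confidence-map algorithm is the integer-mask arithmetic it
  implements — no probabilistic posterior over projection origins.
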