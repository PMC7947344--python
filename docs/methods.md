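# Methods

`ryrclust` quantifies the nanoscale organisation of cardiac ryanodine
receptor (RyR2) clusters from single-molecule localization microscopy
(dSTORM) data, and ships a ground-truth simulator so that every stage of the
analysis can be validated against known geometry.  This note documents the
model behind the simulator, the analysis procedures, the numerical choices,
and what the validation results do and do not show about real tissue data.

## The biological model

RyR2, the sarcoplasmic-reticulum calcium-release channel, is a tetramer with
a ~30 × 30 nm membrane footprint.  In atrial cardiomyocytes the channels
form clusters in the junctional SR membrane, preferentially aligned to the
sarcomeric z-disks (marked by α-actinin), with a strongly right-skewed size
distribution: most clusters contain only a few channels while a long tail
of large clusters dominates the mean.  Clusters whose edge-to-edge distance
falls below ~150 nm are considered functionally coupled — calcium release
from one can trigger release from its neighbour — and are grouped into
super-clusters, also called calcium release units (CRUs).

The morphometric quantities the package computes per image are:

| quantity | definition | units |
|---|---|---|
| cluster size | segmented area / 900 nm² per channel, floored at 1 | # channels |
| packing density | mean rendered intensity over the cluster's pixels | a.u. |
| cluster density | clusters per analysis area | µm⁻² |
| NND | edge-to-edge Euclidean distance to the nearest other cluster | nm |
| % within 150 nm | share of clusters with NND ≤ 150 nm | % |
| clusters / super-cluster | mean members of the 150 nm proximity partition | # |
| super-cluster NND | edge distance between neighbouring group boundaries | nm |
| % z-disk aligned | clusters whose centroid lies on the α-actinin mask | % |
| labelling near z-disk | intensity fraction within 0 / 300 nm of the mask | fraction |

## Ground-truth simulator

### Cluster-size law

The observed order statistics (median ≈ 4 channels, mean ≈ 18) cannot both
be matched by a standard one-parameter discrete law, so cluster sizes are
drawn from a two-component mixture: with weight *w* a uniform draw on
{1…6}, otherwise a geometric tail.  *w* and the tail mean are solved
numerically at configuration time so the population median and mean equal
the configured targets; for the defaults (4, 18) this gives *w* ≈ 0.72 and
a tail mean of ≈ 55 channels.

### Scene geometry

* Channels occupy sites of a square grid at 30 nm pitch inside a randomly
  rotated rectangular patch; an `occupancy` parameter < 1 thins the grid
  (default 1.0).
* The number of clusters is fixed at `round(density × field area)`
  (default 4.3 µm⁻²); placing the count at its expectation rather than a
  Poisson draw keeps the scene-to-scene variance of the density benchmark
  at the detection level, where the interest lies.
* z-disks are straight horizontal bands, width 200 nm, spacing 1.8 µm, with
  a random phase.  A configurable fraction of independently placed clusters
  (default 0.45) is centred on a band; the rest are placed between bands.
* A fraction of clusters (`satellite_fraction`, default 0.15) is placed as
  satellites: an edge gap to a randomly chosen parent drawn uniformly from
  [50 nm, 140 nm].  The default was calibrated once so the realized share
  of clusters within 150 nm of a neighbour is ≈ 70% at the default density
  — chance proximity alone contributes ≈ 63% at 4.3 µm⁻², so the designed
  pairs add the remainder.  This also yields ≈ 2.0 clusters per
  super-cluster.
* A minimum edge gap of 50 nm separates distinct clusters.  Gaps below the
  ~30 nm optical resolution would be unresolvable by construction; 50 nm
  keeps "distinct cluster" a meaningful ground-truth notion while still
  populating the below-150 nm regime densely.
* Ground-truth edge distance between clusters is
  `max(0, min channel-pair centre distance − 30 nm)`, i.e. the gap between
  channel footprints.  All stored true metrics (size, density, NND list,
  % ≤ 150 nm, clusters per super-cluster via union-find at the gap cutoff,
  % z-disk aligned) are recomputed from the stored positions by brute force
  and verified exactly in the tests.

### Acquisition model

Each channel is labelled with probability `labeling_efficiency` (default
0.5; the antibody labelling efficiency of the real experiments is unknown,
so this is an explicit assumption, not an asserted value).  Each label
emits a geometric number of blink events (mean 5), each displaced by
isotropic Gaussian localization error (σ = 15 nm, consistent with ~30 nm
lateral resolution).  Background events form a homogeneous Poisson process
(default 1 µm⁻² per acquisition).  Frame indices are uniform over 20,000
frames and are carried but unused downstream.  Raw-frame movie synthesis
and per-frame photophysics are out of scope — the simulator produces the
localization table that real acquisitions produce after single-molecule
fitting.

Randomness is hierarchical: one master seed spawns independent
`SeedSequence` children for sizes, placement, patch geometry, satellites
(children 0–3) and the event simulator (child 4), so scenes and
acquisitions are reproducible bit-for-bit and independently.

### What the simulator does not emulate

Real tissue adds: curved and branching z-disks, anisotropic cluster shapes,
spatially varying labelling and background, detector artefacts, drift, and
cell boundaries.  Passing recovery tests on these scenes therefore shows
the analysis correctly measures what it claims to measure under ideal,
known-truth conditions — not that its absolute numbers on tissue are free
of labelling- or acquisition-dependent bias.  The efficiency-0.5 default is
the clearest example: at half labelling the recovered channel counts drop
roughly with the labelled fraction of each cluster's extent, which is why
the recovery benchmarks run at efficiency 1.0 and the degradation at 0.5 is
reported rather than asserted.

## Rendering

Events are binned on a 5 nm/pixel grid (0-based pixels, half-open
intervals, x → columns) and each event deposits a unit-mass Gaussian kernel
(σ = 5 nm, reflective boundaries), so pixel intensity is proportional to
local event density and the image mass equals the total event weight
exactly — segmentation can convert intensities back to event counts.  The
kernel is kept below the localization error (total blur
√(15² + 5²) ≈ 15.8 nm) so rendering adds little resolution loss on top of
the physics.  Quantization to 16 bits maps the 99.9th-percentile intensity
to 60,000 counts; the linear scale is stored in the TIFF sidecar and the
round trip is lossless.

## Segmentation and thresholding

The binary mask is `intensity ≥ t` with *t* from a configurable policy
(fixed value, percentile of nonzero pixels, or Otsu).  The pipeline default
is the 60th percentile of nonzero intensities, followed by hole filling and
a 10 nm-radius morphological closing, with 8-connected labelling and a
3-event minimum component mass.  These defaults were calibrated on
ground-truth scenes: the 60th percentile sits near half the interior
plateau density of a typical cluster, which places the mask boundary at the
true cluster edge (the half-maximum criterion) and still detects
single-channel clusters with average blink counts; the small closing
repairs fragmentation caused by blink-count noise without bridging the
50 nm minimum inter-cluster gap.  Higher percentiles (e.g. the 70th) lose
all average single-channel clusters and shrink small clusters' areas by
~15%; lower ones dilate the mask and merge close pairs.

Components touching the image border are flagged and excluded from the NND
distribution (their neighbour may lie outside the field) but remain usable
as neighbours.  The analysis area for cluster density is the ROI when one
is supplied, otherwise the area of a 1 µm-radius morphological closing of
the mask, a proxy for the labelled-cell footprint.

Channel counts are area-based (`round(area / 900 nm²)`, floored at 1).
Packing density is reported as mean intensity in arbitrary units; no
absolute channel-count normalisation of intensity is attempted.

### Known detection limits

At full labelling the pipeline recovers ~91–95% of true clusters: channels
that blink once or twice cannot clear the 3-event floor, so a share of one-
and two-channel clusters is invisible in principle.  This puts recovered
cluster density ~6–9% below truth and is the dominant recovery error; mean
channel count recovers within ~5% and the %-within-150 nm within ~2 points.

## Distances and super-clusters

Inter-cluster distances are Euclidean distances between pixel centres of
the two clusters' mask pixels.  The production NND path computes, per
cluster, an exact Euclidean distance transform of the other clusters on a
window grown adaptively around the cluster's bounding box (the window
doubles until the measured minimum is provably exact); tests verify it
against brute-force minima over boundary-pixel pairs.  Super-clusters are
connected components of the proximity graph with edges at ≤ 150 nm, built
from exact windowed EDTs per cluster — a window extending one cutoff past
the bounding box provably contains every sub-cutoff pair.  A morphological
alternative (dilate by half the cutoff, relabel) is provided for
comparison; it is O(pixels) but only approximately equivalent within ~1.4
px of the cutoff, so the exact graph is the default.  Singleton clusters
count as super-clusters of size one, so "clusters per super-cluster"
averages are well defined.

## z-disk analysis

The widefield α-actinin channel is segmented with Otsu's threshold (the
diffraction-limited ridge against the inter-sarcomeric background), and an
exact Euclidean distance map to the mask is computed.  A cluster is
"aligned" when its intensity-weighted centroid pixel lies on the mask
(an any-overlap criterion is available; centroid is stable across cluster
sizes).  The labelling fraction within a window is intensity-weighted:
Σ intensity over pixels with distance ≤ d divided by total intensity, with
d = 0 giving the co-localized fraction; monotonicity in d holds by
construction.  Note the mask is blur-limited: a 200 nm band under a 250 nm
PSF has a ~605 nm half-maximum width, so the mask area fraction reflects
the optics (≈ 0.34 at 1.8 µm spacing, matching the closed-form erf
prediction), not the underlying 200 nm band, and the distance window is
measured from the mask edge.  Registration between the two channels is
assumed; none is performed.

## Clinical morphometry

Body surface area uses the Du Bois formula,
`BSA = 0.007184 · W^0.425 · H^0.725` (W in kg, H in cm); atrial volumes are
indexed as mL/BSA.  Cardiomyocyte cross-sectional areas come from supplied
label masks (pixel count × (µm/px)²), averaged per patient over whatever
cells are supplied.  Pearson correlation returns r, r², the two-sided
p-value from the t transform and n; zero-variance input yields NaN with a
warning.

## Statistics layer

The patient is the unit of analysis: per-cluster metrics are averaged per
image, per-image values per patient (unweighted by cluster count — a
deliberate convention, asserted by an image-duplication invariance test),
and all group tests run on per-patient values.  Group comparison follows a
decision tree with declared gate tests: Shapiro–Wilk normality per group at
α = 0.05 → Kruskal–Wallis with Dunn post hoc (implemented in-package:
pooled-rank z tests with tie correction and Holm adjustment) when any group
fails; otherwise Brown–Forsythe–Levene at α = 0.05 → Welch ANOVA with
Games–Howell on unequal variances, else one-way ANOVA with Tukey HSD.  The
full path (every gate p-value and the branch taken) is logged in each
result.  The tree's realized type-I error at the study group sizes
(n = 10/9/8) is calibrated to 5% within Monte-Carlo tolerance in the
acceptance tests.  Blinding replaces group labels with opaque random codes
whose key is returned separately; unblinding with a wrong key fails without
partial restoration.

## Problem sizes used in validation

Recovery benchmarks use twenty 6 × 6 µm scenes (~155 clusters each, ~2,800
channels, ~15,000 events) at full labelling; oracle-equivalence checks use
100 random masks up to 512 × 512 px; the statistics calibration uses 1,000
null replicates.  These sizes put Monte-Carlo error comfortably below the
assertion tolerances while keeping the full suite inexpensive to run.

## Known limitations

* Area-based channel counts inherit any mask-boundary bias; the
  intensity-based alternative requires an events-per-channel calibration
  the package does not assume.
* Detection of one- and two-channel clusters is limited by blink
  statistics, biasing recovered cluster density low (see above).
* The z-disk mask is diffraction-limited; alignment percentages are
  mask-definition-dependent and should be compared only within a fixed
  segmentation policy.
* Distances are pixel-grid distances; all distance metrics carry O(1 px)
  = 5 nm discretisation error.
* The simulator's straight z-disks and rectangular patches are idealised;
  no 3D effects are modelled.
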