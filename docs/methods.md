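# Methods

This note records the models, conventions and numerical choices behind
`centriomig`, and what the synthetic validation does and does not establish.

## Coordinate and unit conventions

Images are 5D arrays ordered `(t, c, z, y, x)` with per-axis physical spacing
in µm and the voxel-centre convention (voxel `i` sits at `i × spacing`).
Default spacing is 0.27 µm axially and 0.11 µm laterally, matching spinning-
disk confocal acquisition of expanded tissue. "Apical" is the direction of
decreasing z unless a grid says otherwise; all rates and displacements are
signed with apical positive. All lengths are in the acquisition (expanded-
gel) frame; with ~4-fold expansion, biological lengths are the quoted values
divided by the expansion factor, and the conversion is always left explicit
rather than baked into outputs.

Side-view annotations (apical surface, lower boundary of the sustentacular
nuclei, basal lamina) live in a 2D frame of (apico-basal depth, lateral
position); each polyline is treated as a function of the lateral coordinate
and interpolated linearly between vertices. An annotation is valid only if,
across the shared lateral span, apical ≤ sustentacular ≤ basal.

## Synthetic scenes

The generator is the ground-truth engine for every downstream stage. Its
defaults define the regimes the pipeline is validated in.

**Knob scenes.** A mature dendritic knob is modelled as a gently curved
paraboloid docking surface (lateral radius 7.0 µm, height 2.4 µm at expanded
scale). 36 centrioles are placed on it by rejection sampling with an
anisotropic exclusion zone: pairwise distance measured in units of the
effective PSF sigma per axis must be ≥ 2.6. Measuring crowding in PSF units
rather than µm is what makes nearest neighbours optically resolvable
regardless of whether they are separated laterally (σ = 0.6 µm) or axially
(σ = 1.4 µm). 31 cilia anchor at a maximally spread (farthest-point) subset
of the centrioles and extend as quadratic Bézier tubes, tilted outward in a
cone fan (lateral tilt growing with radial position, up to 0.75 per unit
climb) and bowing gently in a common direction. Shaft-to-shaft separation,
again in PSF-sigma units and ignoring the shared proximal 1.5 µm, is
enforced at ≥ 3.4 σ by retrying directions and, failing that, reassigning
the anchor to a different centriole. Cilium lengths default to 4–7 µm in
the expanded frame — the proximal portions of olfactory cilia that fit a
single field of view; full cilia are far longer and are not modelled.
Puncta are rendered as unit impulses splatted with trilinear weights
(centroid-exact) and blurred by the effective PSF, an anisotropic Gaussian
with sigma = pre-expansion PSF width × expansion factor, default
(1.4, 0.6, 0.6) µm in (z, y, x). Cilia are dense impulse chains with a
per-cilium line density chosen analytically (from the PSF cross-section
perpendicular to the shaft) so every tube reaches the same peak intensity,
80% of the punctum peak, regardless of orientation.

**Noise.** Poisson shot noise on signal-plus-background (default background
100) plus Gaussian read noise (default σ 2). The configured SNR fixes the
punctum peak at `snr × sqrt(background + read²)`. `snr=None`/`inf` yields
the exact noiseless render — used by tests that need analytic ground truth.

**Time-lapses.** Each migrating group is a tight cluster of 3–12 puncta
(cluster σ 0.4 µm, offsets centred so the cluster centroid is exact) whose
centre moves along the apical axis at its configured velocity with i.i.d.
Gaussian positional jitter per frame; a static fiducial cluster is always
present. Cluster trajectories are rejection-sampled to stay ≥ 4 µm apart at
every frame — distinct groups migrate in distinct dendrites, and this keeps
identity unambiguous for any tracker with a ~3 µm gate. Ground truth records
the per-frame rendered centroids (jitter included).

**Count tables.** For each animal × timepoint × compartment, a control and a
drug record are drawn with counts ~ Poisson(density × length/100 ×
multiplier), length uniform in 900–1150 µm and base density 2.9 groups per
100 µm — the scale seen in explanted epithelium. The multiplier map keys on
compartment or (compartment, timepoint); 1.0 everywhere gives a null table
for calibration experiments.

All randomness flows from the mandatory seed; no global RNG state is
touched, and identical configurations are byte-reproducible.

What the generator deliberately does **not** emulate: optical aberrations
beyond a Gaussian PSF, expansion anisotropy or gel distortion,
photobleaching, stage drift beyond what the fiducial test injects, tissue
autofluorescence texture, and cilium geometries that interweave below the
resolution limit. Passing the recovery tests therefore shows the algorithms
are correct and well-calibrated in a resolvable, Gaussian-noise regime; it
does not certify performance on densely interwoven real knobs, where the
original study's counts relied on manual inspection. The review-table
mechanism (a keep/drop CSV applied to detections) exists precisely so that
manual curation remains reproducible.

## Detection

**Puncta.** Scale-normalised Laplacian of Gaussian over 4 geometric scales
(0.4–1.0 µm lateral), with per-axis kernel sigma stretched by an axial
factor of 2.33 (typical confocal PSF elongation). Candidates are local
maxima of the pooled (max-over-scales) response above a threshold, refined
to sub-voxel positions by a background-subtracted intensity centroid in a
±1.2 σ window — kept tight so a resolvable neighbour's core cannot bias the
estimate — and de-duplicated greedily (brightest first) so no two spots lie
within 0.7 × the sum of their scales.

The default threshold is Otsu on the pooled response, floored by a
noise-propagation bound: the raw per-voxel noise σ is estimated with the
robust wavelet estimator, multiplied by the analytic L2 gain of each LoG
kernel (computed from separable 1D Gaussian integrals), and the largest
such response σ times 8.5 is the minimum accepted threshold. The floor is
far below any real-signal Otsu value but prevents the classic Otsu failure
on empty images, where its "foreground" class is just the upper noise tail.
An absolute threshold can be supplied instead, and counts are monotone
non-increasing in it.

**Cilia.** The cilium channel is smoothed at the tube scale (σ 0.2 µm),
resampled to an isotropic 0.2 µm grid — 3D thinning assumes isotropic
connectivity, and steep filaments are squat on the native anisotropic
lattice — then thresholded and skeletonised. The threshold is a fraction
(default 0.75) of the estimated filament core height over background, the
core being the 90th percentile of above-noise voxels selected by a
foreground-restricted Otsu; thresholding relative to the core keeps the mask
narrow enough that neighbouring filaments ≥ ~2 σ apart stay separate.
Skeleton components are traced into one path per distal tip: every skeleton
voxel within 1.2 µm of a reference centriole is a base node, tips are
endpoints farther than that, and each tip takes the shortest physical path
to its nearest base node (via a zero-cost virtual source). This splits
filaments that merge near their bases, including tip-to-tip arcs through a
shared base region. Paths are smoothed (endpoint-preserving moving average,
which also tames lattice staircase inflation), extended at both ends to the
half-maximum level of their own interior intensity — the blurred intensity
of a filament at its true endpoint is half its core — with short
sub-threshold dips crossed if the signal recovers, and finally corrected
for blur along the shaft: the axial σ is read from the 75%→25% end-ramp
width and the blurred-line model is inverted numerically, a correction that
vanishes for resolved filaments and shrinks sub-resolution stubs to their
true extent. Near-duplicate traces (≥ 60% of points within 0.5 µm of a
longer kept path) are dropped, and paths shorter than the minimum cilium
length (default 2 µm, expanded scale) are discarded. When the reference is
a centriole cloud, the proximal end is snapped to the path point nearest a
centriole within the capture distance.

**Association.** One-to-one matching between centrioles and cilium bases
minimising total distance (Hungarian algorithm on a cost matrix with
out-of-radius pairs forbidden), which maximises the number of in-radius
pairs first. The capture radius defaults to 0.5 µm for clean geometry; the
knob-scene analyses use 1.4 µm with the distance measured from the spot to
the nearest point of the cilium's proximal 2 µm segment, since a traced
path runs through its true base even when its refined endpoint over- or
undershoots by a few hundred nm. The association fraction is matched spots
over all spots.

## Grouping and lag

Single-linkage clustering (scipy hierarchical linkage) at a physical cutoff,
default 2.0 µm expanded (≈ 0.5 µm biological): intra-group spacing clusters,
inter-group dendrite spacing (several µm) separates. Clusters smaller than
the minimum group size (default 2) are reported as singletons, matching the
distinction between migrating groups and centrioles travelling singly; both
tallies are exposed. Groups are ordered apically. Lag is the arc distance
along a base→tip dendrite polyline from the orthogonal projection of the
group centroid to the apical endpoint; centroids farther than 2 µm from the
path are a geometry error rather than a silent large lag.

## Tracking and kymographs

Linking is greedy nearest-neighbour, closest pair first, within a 3 µm gate,
with gaps up to 2 frames bridged; greedy linking was chosen over global
assignment for transparency, and the synthetic oracle bounds its error under
the generator's separation guarantee. If a fiducial id is given, its
per-frame position (interpolated where missing; an error if absent from more
than half the frames) is subtracted from every position before rates are
computed, so any common drift cancels exactly. The primary rate is
(last − first observed apical position)/elapsed time — the convention used
when scoring such movies — and a least-squares regression rate over all
observations is reported as a labelled secondary column. Direction is
apical/basal when net displacement exceeds ±0.5 µm (the default threshold
for "no net movement", which has no standard numeric criterion), otherwise
none. Kymographs sample a side-view projection along a polyline with
bilinear interpolation, averaging across a perpendicular width, one row per
frame; the ridge velocity is recovered by regressing per-row argmax
positions against time.

## Compartments

A side-view point is subapical if its depth lies between the apical surface
and the sustentacular lower boundary at its lateral position, middle/basal
between that boundary and the basal lamina. Intervals are closed on the
apical side: a point exactly on a boundary belongs to the more apical
compartment (boundary points are not addressed by the field's verbal
definitions, so the convention is fixed here and tested). Counts are
normalised per 100 µm of basal-lamina arc length; EdU-positive nuclei use
the same normalisation, with nuclei detected as coarse isotropic blobs in
the DAPI channel gated by mean EdU intensity above an Otsu threshold.

## Statistics

Summaries use the sample SD (n−1) and SEM = SD/√n; a single observation has
undefined SD/SEM and is flagged rather than silently zeroed. The paired
permutation test statistic is the mean paired difference of normalised
counts; the test is two-sided by default (|T| tail), one-sided available.
Exact enumeration switches on automatically when 2^n_pairs fits within the
resampling budget (default 10,000), making p-values exact multiples of
1/2^n_pairs; Monte-Carlo mode uses the add-one correction (1 + hits)/(1 + B)
so p is never zero, with ties counted into the tail at 1e-12 slack. The
pairing key (which categories form a drug/control pair) is an explicit
argument everywhere, never hard-coded, because pooling choices change the
test. Traversal time is distance/rate converted to hours and reported to
2 decimals; fold change is the ratio of drug to control normalised
densities and is undefined for a zero control.

## Problem sizes used in validation

The shipped tests and the acceptance script validate detection on 50 and 12
knob scenes respectively (36 centrioles, 31 cilia each), tracking on
noiseless and jittered cohorts of up to 22 single-group movies, the
permutation test on 500–1000 null tables and 200–300 enriched tables, and
the clustering oracle on 200 random instances of up to 40 spots. These sizes
give stable estimates of the recovery statistics while keeping a full run in
the minutes range on one CPU.

## Known limitations

- Cilium counting assumes filaments are resolvable over most of their
  length; fully co-linear bundles below the PSF scale are counted as one.
- The greedy tracker can swap identities if two real groups approach within
  the gating radius; the generator's separation constraint encodes the
  assumption that they do not.
- Compartment classification treats landmark polylines as single-valued
  functions of the lateral coordinate; strongly folded epithelium would
  need a richer annotation model.
- The EdU gate is a global Otsu on the EdU channel; section-to-section
  staining variation would call for per-region thresholds or manual review.
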