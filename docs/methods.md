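# Methods

This note documents the models implemented in `smlmq`, the defaults and
their units, what the synthetic generators do and do not emulate, the
numerical choices, and known limitations.

## Coordinate and unit conventions

All coordinates inside the package are nanometres; camera-pixel inputs are
converted exactly once, at the file-reading boundary, using the camera
pixel size (default 129 nm). Raster images are 0-based with the origin at
the top-left pixel corner and half-open pixels: position *p* falls into
pixel `floor((p − origin)/pixel)`. Intensities are opaque "counts"
(photons vs AD counts is metadata). The FWHM convention is
FWHM = 2.35·σ throughout (the truncated value of 2√(2 ln 2), as is
customary in this field).

## Drift correction

Fiducial beads are found as spatial candidates whose localization count is
a large fraction of the frame count, confirmed when the localizations
within the gather radius (default 500 nm) cover at least `min_presence`
(default 0.9) of all frames. Per-frame bead positions are
intensity-weighted means — beads are orders of magnitude brighter than
single fluorophores, so stray sample localizations inside the gather
radius barely perturb the track — and localizations dimmer than half the
median intensity of the gathered set are discarded outright. Missing
frames are linearly interpolated. The drift curve is the mean over beads
of (position − position at the reference frame), smoothed by a moving
average (default 10 frames; the smoothing trades single-frame localization
noise, reduced by √window, against lag on fast drift). Correction
subtracts the curve; counts and intensities are conserved exactly.

## NeNA localization precision

For each localization the distance to its nearest neighbor among the
*following* frame's localizations (search radius 500 nm) is collected.
If both localizations of a re-blinking molecule have isotropic precision
σ, their difference vector is Gaussian with per-axis scale σ√2, so the
same-molecule distances follow

    p(d) = d/(2σ²) · exp(−d² / 4σ²).

The histogram (2-nm bins over 0–200 nm) is fitted with this model plus a
background of a linear-in-d term and one broad Gaussian (unrelated
neighbors at short range grow ∝ d; the broad Gaussian absorbs
structure-induced correlation). The fit is flagged unreliable when the
same-molecule component carries < 20% of the histogram mass or when its σ
exceeds 20% of the histogram range — in that regime the term has merely
imitated the background (e.g. on data with no re-localizations) and the
returned σ is not a precision.

## Blink merging

Localizations appearing within a radius (customarily the NeNA value) on
consecutive frames (frame gap ≤ `max_gap`, default 0) are chained; each
chain becomes one record with intensity-weighted mean position, summed
intensity and the chain's first frame. Within a frame, each active chain
absorbs at most one localization; the nearest candidate wins and ties go
to the lower record index, making the result deterministic. This is a
deliberate, documented replacement of upstream Kalman-filter grouping by a
transparent chain rule; for well-separated emitters the two agree (tested
against a union-find oracle). Total intensity is conserved exactly.

## Reconstruction and FIRE resolution

Reconstruction is a 2D histogram of positions at 10 nm/px (pixel values
are localization counts, so the image sums to the record count). The
optional visualization blur is a normalized Gaussian with σ equal to the
NeNA value; the image is padded by 6σ so that blurring conserves total
mass to better than 10⁻⁶.

FIRE splits the table by frame parity (deterministic, no random split),
rasterizes both halves on a common square grid (default 2048 px across the
data extent), and computes the Fourier ring correlation with a ring width
of one frequency pixel. The resolution is the inverse spatial frequency at
the first crossing of the fixed 1/7 threshold, linearly interpolated
between rings; a curve that never crosses yields an "unresolved" sentinel
(`resolution_nm = inf`) with the curve attached. The FRC is invariant
under global translation (phases cancel in F₁·conj F₂). The upstream
plugin's "sampling factor" and "Fourier image scale" knobs have no exact
native counterpart here; the grid size parameter (`image_scale`) is the
nearest equivalent and is the only sampling control.

## Filament morphometry

Polylines (drawn along filaments, thickness adjusted to the filament) are
straightened by sampling perpendicular profiles at 1-px steps along the
arclength with bilinear interpolation. The transverse profile is the mean
across the strip length, fitted with Gaussian + offset by least squares;
width = 2.35·σ̂·pixel. Lengthwise coverage is the filled fraction of the
middle 3 pixel rows after binarization — on unblurred reconstructions the
threshold is "> 0 counts"; for blurred images a threshold at a fraction of
the profile peak is appropriate (exposed as a parameter). Coverage is
measured before any blur by default. Each measurement is repeated with the
line wobbled ±0.5 px in x and y and the five results averaged; failed
sub-fits are dropped and flagged. For batch work, images are divided into
10 × 10 µm tiles and up to 15 filaments per tile are sampled (seeded,
without replacement); a filament belongs to the tile containing its
arclength midpoint (the tie rule for lines spanning tiles). Widths are
categorized into thin [0, 75), medium [75, 150) and thick [150, ∞) nm and
compared across conditions with a standard χ² homogeneity test (no
continuity correction); a two-category variant ([0, 150), [150, ∞)) is
available.

The apparent width of a structure of true width *w* imaged at precision
σ_loc follows √(w² + (2.35 σ_loc)²); the width-recovery tests check
exactly this convolution across w ∈ {40, 75, 150, 300} nm.

## Cluster analysis

DBSCAN with Euclidean distances in nm; the neighborhood count that defines
a core point *includes the point itself* (the common convention —
documented because implementations differ). Defaults: ε = 40 nm,
MinPts = 6 for counting individual multi-blink probes ("nanobody
density", clusters per µm² in a ROI); ε = 50 nm, MinPts = 40 for
LC3B-type cluster analysis. Cluster size is the mean distance of member
localizations from the cluster's center of mass (for points on a circle of
radius r this is exactly r; for an isotropic Gaussian of scale σ it
converges to σ√(π/2)); sizes are histogrammed at 100 nm. Note the size is
a radius-like quantity, not a diameter, even where axes are labeled
"cluster diameter" in common usage. The degree of clustering is the
clustered (core + border) fraction of all localizations. Border points
reachable from two clusters are assigned to one of them
(implementation-defined in classical DBSCAN; the test oracle checks
membership validity rather than a specific choice). Probe counting can
optionally be preceded by blink merging (default off).

## Stoichiometry / completeness of labeling

Single-fluorophore calibration: blink events are detected in the last 100
frames of each 200-frame ROI trace (baseline = window median, noise = MAD;
events rise > 3·noise above baseline, runs closer than 3 frames merge —
an explicit rule replacing by-eye event selection). Traces with fewer than
2 events are rejected; amplitudes are baseline-to-peak. Amplitudes are
binned at 100 AD counts as relative frequencies and fitted with the
log-normal

    f(x) = 1/(xσ√2π) · exp(−(ln x − µ)²/2σ²)

by least squares on bin probabilities (CDF differences, so wide bins do
not bias σ). Reference calibration values: µ = 5.68, σ = 0.4.

Fully-labeled model: with n = 24 subunits and degree of labeling p
(0.7 ± 0.15 for the bivalent nanobody, 0.95 ± 0.05 for the SNAP
substrate), the fluorophore count is k ~ Binomial(n, p). The intensity
density of a k-labeled oligomer is the k-fold discrete self-convolution of
the single-fluorophore density on a uniform grid (step 10 AD counts,
nodes at integer multiples of the step so convolution is exactly
lattice-aligned; upper bound 40·e^(µ+3σ); FFT convolution with mass-loss
check at 10⁻⁴). The observable mixture is Σₖ P(k)·conv_k for k ≥ 1,
renormalized: unlabeled oligomers produce no selectable spot, so k = 0 is
excluded by construction. The model median is read off the trapezoid CDF.

Measured oligomer intensities are the second-frame (index 1) integrated
ROI values — at that point all fluorophores are still on — minus a
per-trace baseline estimated as the 0.2 quantile of the last 100 frames
(a low quantile, not the median, because sparse blink pulses occupy that
window; baseline subtraction is switchable). Completeness is
100 · median(measured)/median(model), reported with a percentile-bootstrap
95% CI over the measured set and a sensitivity band re-evaluating the
model at p ± Δp. The estimate is scale-equivariant: rescaling intensities
and e^µ together leaves the percentage unchanged.

## Tracking and mobility

Greedy nearest-neighbor linking, frame by frame: localizations in record
order claim the nearest active track within `max_disp` (default 500 nm at
40-ms frames) whose last frame is within `max_gap` (default 1); ties go to
the lower index. This transparent rule stands in for unpublished custom
tracking software; multi-hypothesis association is out of scope.
Trajectories with fewer than 5 steps are discarded. The apparent D comes
from the time-averaged MSD at lags 1–4: by default a through-origin fit of
MSD(τ) = 4Dτ (negative slopes clip to 0); an optional offset fit absorbs
the 4σ_loc² localization-noise plateau and is the better estimator when
σ_loc is large relative to the step size. Particles split into immobile
(D < 0.02 µm² s⁻¹) and mobile (D ≥ 0.02; the threshold value itself
counts as mobile — a documented tie rule).

## Synthetic data generators

The generators emulate the statistical structure each analysis assumes,
with complete truth annotations (every localization links to an emitter,
particle, cluster or "background"; a fixed seed reproduces outputs
byte-identically).

- **Filament fields**: a nominal width *w* is realized as a transverse
  Gaussian of σ = w/2.35 about the centerline, so the FWHM analysis
  recovers *w* by construction; a fraction (1 − coverage) of contiguous
  200-nm centerline segments (length configurable) carries no emitters.
  Emitters are Poisson along the labeled length; each produces ≥ 1 blink
  (Poisson count), blinks last a geometric number of frames (memoryless —
  the simplest defensible photoswitching model), each on-frame yields one
  localization with isotropic Gaussian error, and a blink's log-normal
  integrated intensity is spread evenly over its on-frames.
- **Microtubules**: emitters uniform on a cylinder surface (diameter
  25 nm), displaced radially outward by Uniform(0, 5 nm) — an assumption;
  only the *maximum* probe displacement is physically constrained — then
  projected (r·cos θ) and blurred with 10-nm localization error. At these
  defaults the fitted apparent width is ≈ 38–39 nm.
- **Cluster fields**: Gaussian clusters (σ = "radius") over homogeneous
  Poisson background — real background need not be spatially homogeneous.
- **Fiducials**: beads present in ≥ 99% of frames with small scatter and
  ~10⁴-count intensity; one drift curve (none/linear/random-walk/custom)
  displaces beads and sample alike.
- **Oligomer traces**: k ~ Binomial(24, p) fluorophores all on during the
  first 5 frames (so frame 2 integrates the full complement), then
  individual blinks in the last 100 frames; Gaussian camera noise
  (default baseline 1000, σ 30 AD counts) throughout.
- **Membrane diffusion**: per-axis steps Normal(0, √(2·D·dt)), plus
  localization noise; no confinement, binding kinetics or motion blur.

What passing tests therefore show: the estimators are unbiased and
correctly calibrated *under these generative models* — Gaussian transverse
profiles, memoryless blinking, homogeneous background, free diffusion.
They do not certify behavior on real data with structured background,
heavy-tailed photophysics, sample-drift nonlinearities between frames, or
anisotropic structures.

## Numerical choices and problem sizes

- Gaussian fits use `scipy.optimize.curve_fit` with bounded parameters and
  moment-based initial values; non-convergent profile fits are flagged and
  excluded (and counted), not silently dropped.
- DBSCAN is delegated to scikit-learn (`min_samples` counts the point
  itself, matching the convention above); the test suite carries an
  independent O(n²) brute-force reference and asserts equivalence on
  hundreds of random instances.
- The χ² homogeneity test is `scipy.stats.chi2_contingency` without
  continuity correction; empty categories are dropped to keep the test
  defined, and expected counts < 1 attach a warning.
- Convolutions use FFT (`scipy.signal.fftconvolve`) with truncation-mass
  checks; distribution medians come from trapezoid CDFs.
- Tests and the acceptance script run at deliberately moderate problem
  sizes — 10⁵ localizations for the microtubule benchmark, ~4·10⁴ for
  NeNA recovery, 10⁶ draws for Monte-Carlo oracles, 400 oligomers or
  particles for closure and classification checks — chosen so the full
  suite completes in a couple of minutes while keeping Monte-Carlo error
  well inside the asserted tolerances.

## Known limitations

- 2D only; no astigmatic/3D localization, no sCMOS pixel-noise maps.
- Drift correction requires fiducials (no redundant cross-correlation
  fallback); with zero beads the pipeline aborts explicitly.
- The stoichiometry model assumes independent, identically distributed
  fluorophore intensities; quenching/FRET between nearby dyes and
  day-to-day calibration drift are not modeled.
- The greedy linker underperforms at high particle densities
  (D·dt approaching the nearest-neighbor spacing); links are then biased
  toward shorter steps.
- FIRE on very sparse data inherits the usual spurious high-frequency
  correlations of FRC; the fixed 1/7 threshold is applied without
  curve smoothing.
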