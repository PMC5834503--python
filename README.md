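# smlmq

Quantitative analysis of single-molecule localization microscopy (SMLM)
experiments — the computational stack behind labeling-quality studies in
dSTORM/PALM imaging. `smlmq` is aimed at microscopists and image analysts
who need to turn raw localization tables into defensible numbers about
**how well a labeling strategy performs**: how precisely molecules were
localized, how completely a target was decorated with fluorophores, how
broad a filament appears, how clustered a protein is, and how mobile
membrane molecules are.

## What it computes

**Post-processing** (`smlmq.postproc`) — the shared preprocessing chain:

- Fiducial-based drift correction: bright beads are detected as spots
  present in ≥90% of frames; the mean bead displacement, smoothed by a
  moving average, is subtracted per frame.
- NeNA localization precision: distances *d* between each localization and
  its nearest neighbor in the *next* frame are histogrammed and fitted with
  the same-molecule model
  `p(d) = d/(2σ²) · exp(−d²/4σ²)` plus a background term; σ is the average
  localization precision.
- Blink merging: localizations re-appearing within the NeNA radius on
  consecutive frames are grouped into one record (intensity-weighted
  position, summed intensity).
- Reconstruction at 10 nm/px and Fourier ring correlation (FIRE)
  resolution at the fixed 1/7 threshold, splitting by alternating frames.

**Filament morphometry** (`smlmq.filaments`) — polyline profiles on the
reconstructed image: Gaussian fit of the straightened transverse profile
with FWHM = 2.35·σ·pixel; lengthwise labeling coverage as the filled
fraction of the middle 3 binarized pixel rows; 0.5-px wobble averaging;
width categories thin/medium/thick ([0, 75), [75, 150), [150, ∞) nm) with
a χ² homogeneity test across labeling conditions.

**Cluster analysis** (`smlmq.clusters`) — DBSCAN (ε = 40 nm/MinPts = 6 for
single-probe counting, ε = 50 nm/MinPts = 40 for LC3B-type clusters),
cluster size as mean member distance to the center of mass, degree of
clustering, probe and localization densities per µm².

**Stoichiometry** (`smlmq.stoich`) — completeness of labeling against a
24-subunit ferritin (FtnA) standard. Single-fluorophore blink amplitudes
are fitted with the log-normal `f(x) = 1/(xσ√2π)·exp(−(ln x − µ)²/2σ²)`;
the fully-labeled oligomer intensity distribution is the binomial mixture
`Σₖ B(k; n, p) · conv_k` of k-fold self-convolutions of that density
(k ≥ 1, n = 24, p = degree of labeling); completeness is
100 · median(measured) / median(model).

**Tracking** (`smlmq.tracking`) — greedy nearest-neighbor linking, the
≥5-step trajectory filter, apparent diffusion coefficients from the first
four MSD lags (MSD(τ) = 4Dτ), and the immobile/mobile split at
0.02 µm² s⁻¹.

**Synthetic data** (`smlmq.synth`) — ground-truth-annotated generators for
every input above: blinking emitters on filament centerlines, microtubule
cylinders with probe linkage error, Gaussian clusters over Poisson
background, fiducial beads riding a drift curve, binomially-labeled
oligomer intensity traces, and 2D Brownian trajectories. Fixed seeds give
byte-identical outputs; every localization carries a truth label.

The fit/transform-shaped stages are scikit-learn-style estimators
(`DriftCorrector`, `NenaEstimator`, `BlinkMerger`, `DensityClusterer`,
`SingleFluorophoreCalibrator`, `MobilityClassifier`, `FilamentAnalyzer`)
with plain functions as thin wrappers.

## Worked example

Simulate a nanobody-labeled microtubule — emitters on a 25-nm-diameter
cylinder, radial probe displacement up to 5 nm, 10-nm localization
precision — and measure its apparent fiber width:

```bash
$ smlmq simulate microtubule --n 100000 --seed 1 --out mt.csv
wrote 100000 localizations to mt.csv
$ smlmq render --table mt.csv --pixel-nm 10 --out mt.tif
wrote 506x12 image to mt.tif
```

```python
import numpy as np
from smlmq import core_io, postproc, filaments

table = core_io.read_localization_table("mt.csv")
img = postproc.reconstruct_image(table, 10.0)
axis = core_io.Polyline(np.array([[500., 0.], [4500., 0.]]), thickness_px=21)
m = filaments.wobble_measure(img, axis, 21)
print(f"apparent width: {m.width_nm:.1f} nm")
```

```
apparent width: 38.6 nm
```

The 25-nm tubule reads back at ~39 nm: the probe displacement and the
10-nm localization error each broaden the profile, and
`sqrt(w² + (2.35·σ_loc)²)`-style convolution sets the apparent width — the
measurable fingerprint of linkage error.

The fully-labeled 24-mer intensity model at a degree of labeling of 0.7:

```bash
$ smlmq stoich simulate --mu 5.68 --sigma 0.4 --dol 0.7 --out mixture.csv
median of fully-labeled mixture = 5317.2 AD counts
```

Dividing the median of measured FtnA spot intensities by this number (and
multiplying by 100) gives the completeness of labeling in percent.

## Command-line interface

```
smlmq simulate {microtubule,filaments,clusters,oligomers,diffusion}
smlmq drift | nena | merge | render | fire
smlmq filaments | clusters | track
smlmq stoich {calibrate,simulate,completeness}
smlmq pipeline --name {filaments,clusters,stoich,tracking} --config cfg.yaml
```

Every pipeline run writes a `run_log.yaml` with all parameters and the
seed; a run is reproducible from its log. See `docs/methods.md` for the
models, defaults, assumptions and limitations.
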