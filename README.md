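# mitoquant

Quantitative analysis of mitochondrial fluorescence microscopy: 3D
morphometry of mitochondrial networks, mitophagy-reporter puncta assays,
vesselness-based live-cell segmentation and tracking, and the accompanying
group-comparison statistics — together with a synthetic-microscopy generator
that renders scenes with known ground truth, so every stage of the pipeline
can be validated end to end without any raw imaging data.

It is written for cell biologists quantifying mitochondrial phenotypes
(morphology, mitophagy flux, fission/fusion machinery localization, motility)
from confocal or spinning-disk stacks, and for method developers who need a
calibrated test bed for spot detection, 3D segmentation, or particle-tracking
code.

## What it computes

**3D morphometry** (`mitoquant.morphometry`). Mitochondria are segmented from
a single-channel z-stack by intensity thresholding, 26-connected component
labeling, and a minimum-size clean step. Each object is reduced to volume
*V* (μm³), ellipsoid-equivalent principal axis lengths
*a₁ ≥ a₂ ≥ a₃* (aᵢ = 2√(5λᵢ), with λᵢ the eigenvalues of the voxel-center
covariance), elongation

    E = a1 / ((a2 + a3) / 2)        (E = 1 for a sphere)

and a size class: **MDV-sized** (*V* < 0.03 μm³, mitochondria-derived-vesicle
scale), **network** (*V* > 1 μm³), or intermediate. Per-cell summaries report
the median elongation, total volume, and class counts.

**Puncta assays** (`mitoquant.puncta`). Maximum-intensity projection,
rolling-ball background subtraction, intensity-threshold spot segmentation
with a strict size filter (> 0.01 μm²), and per-assay readouts: puncta counts
(autophagosome reporters), thresholded positive area per cell (Parkin
recruitment), spot density per μm² of mitochondrial mask (Drp1/Mfn2), ROI
mean intensity (TMRE/MitoSOX), cargo-selective co-localization of two spot
channels by greedy nearest-pair matching, and FWHM linescans
(FWHM = 2√(2 ln 2)·σ for a Gaussian spot). The tandem mitophagy reporter is
classified per punctum from 1-μm line profiles: a punctum is counted as
acidified (mCherry-only) when (peak − background)/background ≥ 2 on the
mCherry channel while the GFP profile stays flat.

**Dynamics** (`mitoquant.dynamics`). Histogram-matching bleaching correction;
multiscale Frangi vesselness for bright tubules with a Frobenius-norm
efficiency gate (voxels whose Hessian norm falls below the square root of the
image maximum are zeroed); semantic segmentation at a normalized-vesselness
threshold of 1e-05; connected-component instances; Lee skeletonization with
branch decomposition by junction/tip traversal; and Hungarian frame-to-frame
tracking with a normalized distance/volume/length cost and a hard speed gate.

**Statistics** (`mitoquant.stats`). ROUT outlier removal (robust
median/RSDR fit plus an FDR screen at rate Q), Shapiro–Wilk normality
gating, then Student's t or one-way ANOVA with Dunnett's or Tukey's post hoc
for Gaussian data, Mann–Whitney or Kruskal–Wallis with Dunn's post hoc
otherwise, and per-replicate normalization to the control mean.

**Synthetic scenes** (`mitoquant.synth`). Persistent-random-walk tubes,
PSF-shaped puncta, Parkin-like accumulations and MDV-sized cargo spots,
rendered with Gaussian PSF blur, Poisson photon statistics, read noise and a
camera baseline on an anisotropic grid. Named presets encode
condition-dependent effect sizes (e.g. `lc3`: ×2 puncta; `parkin`: ×25
positive area; `cox8_48h`: ×10 mCherry-only puncta) with full ground truth.

## Worked example

```python
import numpy as np
from mitoquant import generate_scene, preset
from mitoquant.morphometry import segment_3d, measure_objects, summarize_cell

vol, truth = generate_scene(preset("morpho", "control", seed=0))
labels = segment_3d(vol.channel("tom20"), vol.voxel_size, threshold="halfmax")
cell = summarize_cell(measure_objects(labels), "cell0")
print(f"objects: {cell.n_objects} (truth {len(truth.objects)})")
print(f"total volume: {cell.total_volume:.2f} um^3 (truth {truth.total_volume():.2f})")
print(f"median elongation: {cell.median_elongation:.2f}")
```

prints

```
objects: 10 (truth 10)
total volume: 3.97 um^3 (truth 3.99)
median elongation: 3.93
```

— the segmentation recovers every generated mitochondrion, the summed volume
matches the rasterized truth to ~1%, and the median elongation of ~4 reflects
the short-tube geometry of the control-like preset.

The same flows are available from the shell:

```bash
mitoquant simulate --preset morpho --seed 0 --out scene/
mitoquant morpho --input scene/scene.ome.tif --channel tom20 --threshold halfmax --out results/
mitoquant stats --table results/cells.csv --value median_elongation --group cell_id --out stats/
```

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, and the limits of what synthetic-data validation can show.
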