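# Methods

This note records the models behind each stage of the pipeline, the
parameters that matter, the numerical conventions, and the design choices
made where the design was genuinely open.

## Synthetic scenes

The generator renders single-cell fields that mimic super-resolution
spinning-disk acquisitions of labeled mitochondria. A scene is composed in
"relative intensity" units, convolved with a Gaussian point-spread function,
scaled to expected photon counts, Poisson sampled, and offset by a camera
baseline with Gaussian read noise:

    image = Poisson(PSF * scene × photon_scale) + baseline + N(0, read_noise²)

**Geometry.** Mitochondria are persistent random walks in physical
coordinates (step 0.1 μm; direction updated as a convex combination of the
previous direction and an isotropic jitter weighted by `persistence`),
dilated to tubes of radius `tube_radius` by a distance test: a voxel is
foreground when its center lies within the radius of the densely sampled
polyline. Tube lengths are lognormal. Walks reflect at the cell boundary
(one convex elliptical footprint per scene) and are confined to a central
z band. New tubes are rejected until they keep `placement_clearance` μm from
existing ones, so instances remain resolvable after blur; a tube that cannot
be placed in 50 attempts is dropped and the realized count is what the
ground truth records.

**Puncta** are sub-voxel impulses deposited by trilinear splatting with mass
`peak × (2π)^{3/2} σz σy σx` (voxel units), so the PSF-convolved spot attains
approximately `peak` relative counts at its center; sub-voxel placement and
the discreteness of the kernel lower the realized peak by tens of percent,
which is why nominal peaks are specified ~3× the tube intensity —
diffraction-limited reporter puncta are markedly brighter than the
cytoskeletal-scale tubules around them. Parkin-like accumulations are
painted as disks in a mid-z slab until a per-cell target area (area fraction
× lognormal cell-to-cell factor, CV 0.25) is covered; the final disk is sized
to land on the target, so painted area tracks the target up to pixelation.
MDV-sized spots carry a cargo label (A-only / B-only / dual) and render into
the corresponding marker channels.

**Defaults** approximate the modeled acquisition: voxels 0.1 × 0.1 × 0.3 μm,
PSF σ 0.08 μm lateral / 0.25 μm axial (~150 nm-resolution class optics
without modeling the pupil), photon scale 200 counts, baseline 100 counts,
read noise 2 counts. Randomness is split into independent named streams
(tubes, puncta, parkin, MDV, noise, motion) spawned from one seed, so
changing the puncta rate cannot perturb tube geometry; identical
(config, seed) pairs are bit-for-bit reproducible.

**Presets** encode the effect sizes the assays must recover. The reported
contrasts are fold changes, not absolute counts, so absolute rates are this
package's choice of realistic magnitudes: LC3-like puncta 6 → 12 per cell
(×2), Parkin-positive area fraction 0.002 → 0.05 of the cell (×25),
mCherry-only reporter puncta 1.5 → 15 per cell (×10), and a morphology pair
with median tube length 1.5 → 3.0 μm. The time-lapse preset moves 10 rigid
tubes at lognormal speeds (median 0.15 μm/s, shape 0.4 — typical perinuclear
mitochondrial motility) in a 25.6 μm field sampled every 2 s, with optional
per-frame multiplicative bleaching.

**Ground truth** records every rendered object before blur and noise:
rasterized voxel count and volume, principal axes and elongation of the true
voxel set, centroid, size class, per-punctum position/channel/cargo, painted
Parkin area, the instance label volume, and per-frame identities and
displacements for time-lapses.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical aberrations and spectral bleed-through
(PSF is a separable Gaussian), cristae-scale substructure, fission/fusion
events (motion is rigid per object), multi-cell fields, autofluorescence
gradients, and the over-dispersion of real per-cell counts (puncta counts
are Poisson). Recovery results here demonstrate correctness of the
measurement operators under a known forward model, not robustness to every
property of real microscopy.

## 3D morphometry

Segmentation thresholds the stack (voxels ≥ t), labels 26-connected
components (thin diagonal tubes fragment under 6-connectivity), and removes
components below `clean_min_voxels` (default 5) — a documented stand-in for
the proprietary "clean" filter of the modeled workflow, whose cutoff is not
published. Three threshold modes exist: a numeric value (the analyst's
manual choice, applied identically across conditions), `"auto"` (Otsu), and
`"halfmax"` (midpoint between the median background and the 99.8th-percentile
signal). Otsu on blurred tubes includes much of the PSF halo and
overestimates volume by tens of percent; the half-maximum contour of a
blurred object tracks its true boundary, so `halfmax` is the volume-faithful
automated choice and is what the validation suites use.

Axis lengths use the ellipsoid-equivalent convention aᵢ = 2√(5λᵢ) from the
covariance of physical voxel centers; the constant cancels in elongation but
keeps lengths interpretable (a uniform ellipsoid recovers its true full
axes). A single-voxel object is assigned equal axes (equivalent-sphere
diameter) and elongation 1 with a degeneracy flag, as is any object with
a₂ = a₃ = 0. Size classes partition objects exactly: V < 0.03 μm³ MDV-sized,
V > 1 μm³ network, else intermediate; boundary values are intermediate.

## Puncta assays

Background subtraction is greyscale opening with a disk (rolling-ball
equivalent), radius 0.5 μm by default — several punctum radii, small enough
to follow cell-scale background. Detection takes suprathreshold 8-connected
components with area strictly greater than `min_area` (0.01 μm² default) and
reports intensity-weighted centroids, peak, and a local background (median
of an annulus one pixel outside the component's equivalent radius, three
pixels wide — robust to neighboring puncta).

The acid-quenched reporter classification follows the line-profile
procedure: a 1 μm line through the punctum centroid, oriented toward the
brightest neighboring pixel, sampled at pixel pitch on the raw (not
background-subtracted) projections of both channels; background is the mean
of the line ends, and ρ = (peak − background)/background. A punctum is
mCherry-only when ρ_mCherry ≥ 2.0 and ρ_GFP < 0.5. Two readings of the
"2:1 over background" criterion exist (ρ ≥ 1 if 2:1 refers to peak:background
after subtraction, ρ ≥ 2 if the subtracted peak must be twice the
background); this package defaults to the stricter ρ ≥ 2 and both are
configurable. The GFP-absence cutoff 0.5 is a package choice; no number is
published. A non-positive background excludes the punctum with a reason code
rather than producing an unbounded ratio.

Cargo co-localization matches spot centroids greedily, closest pair first,
within 0.15 μm — the scale of the structures themselves (FWHM ≈ 0.15 μm) —
because pixel-overlap tests are unstable for objects at the diffraction
limit. FWHM linescans subtract the profile minimum and interpolate the two
half-maximum crossings bracketing the global peak; a profile without both
crossings is flagged undefined rather than extrapolated.

## Dynamics

Frames are bleach-corrected by histogram matching to the first frame.
Because the modeled workflow denoises and deconvolves stacks before analysis
(steps this package does not replicate), the pipeline applies a light
Gaussian prefilter (σ = 1 px, configurable, 0 to disable) before vesselness
filtering; without it, shot noise percolates through the tiny semantic
threshold.

Vesselness is the Frangi bright-ridge response, maximum over scales
(defaults 1.0–2.5 px, matching the tube radius), α = β = 0.5, and the
response normalization c set to half the maximum Hessian norm per scale.
Second derivatives are γ-normalized (×σ²) and computed with nearest-edge
padding so a flat field stays flat at the image border (constant-zero
padding would manufacture enormous border ridges). The efficiency gate
zeroes voxels whose Hessian Frobenius norm falls below the square root of
the image's maximum norm, per scale, before the response is kept; since the
response is pointwise in the eigenvalues, the gate provably never alters the
response at voxels that pass it (tested), matching its stated role as a
computational shortcut. The gate sentence in the source workflow is
ambiguous; it is implemented literally with a flag to disable. Whether the
1e-05 semantic threshold applies to raw or normalized vesselness is also
unstated; normalized is assumed (raw Frangi magnitudes are
contrast-dependent, which would make a fixed threshold meaningless across
images).

Skeletons come from Lee thinning; skeleton voxels with degree 1 are tips,
degree ≥ 3 junctions, and branches are traced through degree-2 chains
between nodes (pure cycles are emitted as closed branches). Branch length is
the sum of physical inter-voxel steps. The partition invariant — every
skeleton voxel is a node or interior to exactly one branch — is enforced by
tests.

Tracking solves a global assignment per consecutive frame pair with cost

    c(i,j) = d/(v_max Δt) + |ΔV|/(V_i+V_j) + |Δa1|/(a1_i+a1_j)

links with d > v_max·Δt forbidden, and birth/death costs just above the
maximum admissible link cost, so an object is left unmatched rather than
linked implausibly. The exact cost weights of the original tracker are not
published; this normalized three-term form is the documented stand-in, with
each term in [0, 1]. No gap closing: a missed detection ends a track (the
simplest contract; gap closing is an extension point). Track speed is path
length over elapsed time, not net displacement over time.

## Statistics

ROUT is implemented for the single-sample location model (the only use in
per-cell distributions here): location = median, scale = RSDR (68.27th
percentile of absolute residuals, small-sample corrected by n/(n−1)),
per-point two-sided t p-values (df = n−1), screened by a Benjamini–Hochberg
step at rate Q from the most extreme point inward. Q defaults to 1%
(the method's convention; no value is published for the modeled analyses).
On clean normal samples of n = 50 the realized false-flag rate is well under
the 2% budget. Regression ROUT is out of scope.

The decision tree: Shapiro–Wilk per group at α; all Gaussian → Student's t
(pooled variance, as named in the modeled workflow) or one-way ANOVA with
Dunnett's post hoc against a named control (multivariate-t, via
scipy; verified against R multcomp to 4 decimals on a frozen fixture) or
Tukey's HSD otherwise; any non-Gaussian group → Mann–Whitney or
Kruskal–Wallis with Dunn's post hoc (mid-ranks, tie-corrected variance,
Holm adjustment — the correction used is not published, Holm is the
conservative default). Constant samples are treated as non-normal. Rank
branches are exactly invariant under strictly monotone transforms (tested).
Per-replicate normalization divides every observation by its replicate's
control mean and refuses replicates without controls.

## Validation scale and variability

The recovery suites run the full pipelines on synthetic cohorts of 30 cells
per condition per the assay design; cohort seeds are split deterministically
from one base seed. The fold-change estimates inherit the generator's
Poisson sampling: with 1.5 expected reporter puncta per control cell, the
control cohort total (~45 spots) dominates the variance of the ×10 ratio
(≈15% CV), so run-to-run values of that fold change legitimately span
roughly 8–13. Detection efficiencies are condition-symmetric (~0.85), which
is why the ratio tracks the generating truth.

The tracking recall/speed suite runs the image pipeline once (10 objects,
20 frames, 256² pixels); the 200-run null calibration of condition
comparisons (identical speed distributions → ~5% Mann–Whitney rejections)
is run at the measurement level — ground-truth centroids with 0.03 μm
localization jitter fed to the tracker — which isolates the tracking and
testing stages while keeping the suite fast. Monte-Carlo statistical suites
(type-I error, ROUT false flags) use 1000 replicates.

## Known limitations

Objects that touch after PSF blur merge into one instance (no watershed
splitting); tracks of merging mitochondria end rather than bridge. The
Frangi response underestimates very short tubes (length ≲ 2× radius, nearly
blob-like). 2D tracking operates on maximum projections; the 3D path shares
the code but is unexercised by the validation presets. Elongation of 2D
instances uses the two in-plane axes. The generator's convex single-cell
mask cannot produce the occlusions of confluent fields.
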