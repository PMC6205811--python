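# Methods

## Pipeline overview

The tool quantifies N-cadherin polarization in confocal stacks of
micropatterned neuroepithelial tissues. A stack (by convention 7 z-planes at
1.5 µm, 1024×1024 px) is reduced to two 2-D views of the N-cadherin
channel: a maximum-intensity projection for detection and a mean-intensity
projection for intensity-based descriptors. Both are median-filtered (3×3,
reflect padding) before use. Pixel size is a required input — the area
exclusion is defined in µm² and has no meaning without it.

## Region detection

Bright N-cadherin-dense regions are found with maximally stable extremal
regions (MSER). The implementation is in-package: the (lightly
Gaussian-smoothed, σ = 2 px) projection is min–max normalized and quantized
to 256 gray levels, upper level sets `{I ≥ t}` are labelled per level with
8-connectivity, components are chained across levels, and a component's
*variation* is its relative area growth against the enclosing component
Δ = 5 levels lower. Each chain contributes its minimum-variation member,
subject to area bounds (60 px ≤ area ≤ ¼ of the image) and a variation
ceiling (0.5). Working on normalized levels makes the detected region set
exactly invariant under positive affine rescaling of intensities, which is
also enforced by tests.

Nested candidates are then pruned by stability: when two candidates overlap
by more than half of the smaller one, only the lower-variation candidate
survives. This is the standard MSER diversity criterion, and it is what
keeps a compact, very stable ring from being swallowed by the looser
component that envelops it (ring plus surrounding texture) a few gray
levels above background. A second, area-based suppression pass
(`suppress_nested_regions`, keep-the-larger) remains available as the
public de-duplication operation.

Geometry per region: area = pixel count × (pixel size)²; an ellipse is
fitted from second central image moments (major axis = 4·√λ₁ of the
per-pixel covariance, eccentricity = √(1 − λ₂/λ₁)), matching the
`regionprops` convention; the *radius* used for tendril sampling is half
the fitted major axis, in pixels. Regions with area strictly below
176 µm² are excluded; an area exactly at the threshold is retained.

## Descriptors

Eight values per region, in fixed order: area, major axis, eccentricity,
halo intensity ratio, tendril density 1 and 2, tendril angle incoherence 1
and 2.

**Halo intensity ratio** (mean projection): internal mean over the region
mask eroded by 5 px (the full mask if the erosion empties it, as happens
for thin rings), divided by the external mean over the annulus between the
5 px and 10 px dilations of the mask, excluding pixels of other detected
regions. Regions whose external annulus is empty (image border) are
flagged, not scored. The ratio is exactly invariant under global intensity
scaling.

**Tendril sampling**: 16 equally spaced angles per ring, rings at 1.5× and
2× the region radius (ring index 1 ↔ 1.5×, 2 ↔ 2×), 20×20 px patches on
the mean projection; patches crossing the image border are dropped.

**Tendril density**: mean patch intensity normalized by the maximum of the
(median-filtered) mean projection, clipped to [0, 1]. The maximum rather
than a high percentile is used because the structures of interest can
occupy an arbitrarily small fraction of the field; a percentile reference
collapses to background exactly when a field is sparse.

**Tendril angle incoherence**: the patch is smoothed (Gaussian, σ = 1 px),
gradients are taken with 3×3 Sobel kernels, and the dominant orientation is
the axial (period-180°) circular mean of gradient orientations weighted by
squared gradient magnitude — equivalently the structure-tensor orientation.
The descriptor is the acute angle between the implied ridge direction
(gradient orientation + 90°) and the radial ray from the region centroid
through the patch center, folded into [0°, 90°]. A perfectly radial
tendril — i.e. perpendicular to the halo tangent — scores 0°; the scale is
therefore *incoherence*: larger is less rosette-like. Flat patches have no
orientation; they are flagged and excluded from the ring mean. Isotropic
noise patches average 45° by symmetry, which the tests verify.

Ring statistics are arithmetic means over the valid samples of each ring.
A vector with any undefined field (unassessable halo, no valid samples on
some ring) is marked unscorable and excluded from classification, with the
reason recorded — never silently dropped.

## Classifier and consensus

Ground truth is 4-of-5 quorum voting over independent rater annotations;
raters who did not mark a region implicitly vote *absent*, and regions
where no class reaches quorum are excluded from training. The classifier is
a logistic regression on the standardized eight-vector (training-set mean
and SD; constant features neutralized with a warning), fitted with lbfgs
under light L2 regularization — penalty strength 1/n in the average-loss
parameterization (`C = 1` in scikit-learn terms), i.e. near-MLE at the
hundreds-of-regions scale the tool targets. Ties at the 0.5 decision
threshold go to *rosette*. Model files are plain JSON containing weights,
intercept, standardization parameters, threshold and a config hash, so
predictions are reproducible bit for bit.

Error rates against consensus: the *foci identification error* is
(missed consensus areas + spurious detections) / total consensus areas; the
*rosette error* is (consensus rosettes missed or called focus + non-rosette
areas called rosette) over the same denominator, so both error types share
one scale. Rates are capped at 100% and flagged when spurious detections
outnumber the consensus areas.

## Tissue categories

`0 Rosette` — no rosette, regardless of focus count; `1 Rosette` — exactly
one rosette and zero foci; `+1 Rosette` — everything else (≥ 2 rosettes, or
a rosette with ≥ 1 additional polarization area). The two count pairs the
three verbal rules do not literally cover are resolved as: multiple foci
without a rosette remain `0 Rosette` (the category tracks rosettes), and a
second rosette counts as an additional polarization area, hence
`+1 Rosette`. The rule is total and is property-tested over all count pairs.

## Synthetic data generator

The generator draws circular micropatterned tissues with the morphologies
the descriptors are built to distinguish:

- **Rosette**: a ring with annular Gaussian cross-section (radius 15–20 µm,
  width σ 3–5 px, peak 200 intensity units) plus 28 thin (σ = 1.5 px,
  peak 90) exactly radial tendril segments spanning 2.0–3.6 ring radii.
  The exact radial geometry is the analytic oracle for the incoherence
  descriptor. The tendril stand-off from the ring keeps the ring its own
  stable extremal region while individual tendrils stay below the area
  exclusion; tendrils that touch the ring would fuse with it into a single
  stable component, which is a rendering artifact rather than a property
  of real staining.
- **Focus**: an isotropic plateau blob, `I·exp(−(d/σ)⁴)` with σ ≈ 12–14 µm
  — dense punctate staining with a soft shoulder but no ring and no
  radial alignment.
- A nuclei channel of random blobs inside the footprint, replication
  across 7 z-planes with ~3% per-plane intensity jitter, and pinned noise
  regimes: `none` (σ = 0), `clean` (Gaussian σ = 2 on the ~0–200 intensity
  scale), `realistic` (Gaussian σ = 8 plus Poisson shot noise). `clean` is
  deliberately not noise-free: real acquisitions always carry shot noise,
  and a perfectly flat patch has no gradient orientation at all.

Random tissues place structures by rejection sampling with a 1.8× margin on
the contact distance — two plateau blobs placed at bare contact render as a
single connected structure, which would falsify the drawn ground-truth
count, not the detector. Defaults mirror the target acquisitions (1024 px
at 0.5 µm/px, 200 µm tissue); multi-structure test batches use 300 µm
tissues — the morphology on which the classifier is meant to be trained —
in 768 px fields, and single-structure training fixtures use 200 µm tissues
in 512 px fields. These sizes are the package's test-scale choice; the
µm-scale geometry is identical at 1024 px.

What the generator does *not* emulate: optical PSF and z-dependent blur,
diffuse inter-rosette membrane texture, partially formed or fused rings,
rater disagreement structure. Passing the synthetic recovery tests
therefore demonstrates the algorithm's correctness on well-defined
morphologies, not its error rate on real acquisitions — on real data the
classifier must be retrained against expert consensus, and the error-rate
machinery exists for exactly that comparison.

## Numerical choices and degenerate inputs

- Median filter: reflect padding (no border darkening of peripheral
  samples); kernel 1 is the identity; even kernels are rejected.
- MSER: uniform images yield no regions; single-pixel-wide images are
  errors; ties in suppression keep the first-listed region.
- Moments: single-pixel masks have zero major axis and zero eccentricity.
- Halo: zero external mean reports an infinite ratio and a flag.
- Incoherence: exactly isotropic structure tensors (c₂ = s₂ = 0) are
  treated as unoriented.
- Training requires at least two examples per class; duplicated datasets
  reproduce the same decision function when the regularization is scaled
  accordingly.
- All randomness in the generator and the acceptance script flows from a
  single integer seed; sub-seeds stay below 2³¹.

## Known limitations

- MSER is run on 256 quantized levels; images whose meaningful contrast
  occupies a tiny fraction of their dynamic range (e.g. a few hot pixels
  over a dim scene) will lose detection resolution to quantization.
- Merged or touching rosettes are detected as one region (no watershed
  splitting), consistent with projection-based 2-D analysis.
- The halo ratio of regions at the image border is undefined and flagged;
  such regions never enter counts silently.
- The classifier is linear in the eight descriptors by design; no attempt
  is made to learn features.
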