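# rosettequant

Automated quantification of neural rosette emergence in micropatterned
hPSC-derived neuroepithelial tissue images.

## The problem

When human pluripotent stem cells are differentiated to neuroepithelial
cells on micropatterned substrates, the tissues polarize N-cadherin into
discrete structures: *polarization foci* (punctate N-cadherin accumulations)
and *neural rosettes* (a coherent N-cadherin ring — the "halo" — surrounded
by radially aligned membrane staining — "tendrils" — reflecting apico-basal
cell polarity). Whether a tissue develops exactly one rosette is the key
readout of morphology screens that tune micropattern size and shape, and
scoring thousands of confocal images by eye is slow and rater-dependent.

`rosettequant` implements the full scoring workflow:

1. **Detection** — maximum-intensity projection of the N-cadherin channel,
   median filter, then maximally stable extremal regions (MSER) to find
   N-cadherin-dense blobs; regions with area < 176 µm² are excluded.
2. **Description** — each region is scored with an eight-element vector:
   area (µm²), fitted-ellipse major axis (µm), eccentricity, halo intensity
   ratio (mean fluorescence inside the region over the mean just outside
   its boundary, on the mean projection), and — from 20-pixel squares
   sampled at 1.5× and 2× the region radius — tendril density 1/2 and
   tendril angle incoherence 1/2 (deviation of local gradient-orientation
   structure from the radial direction; 0° = perfectly radial tendrils,
   90° = tangential).
3. **Classification** — a logistic regression over the standardized
   descriptors separates foci from rosettes. Ground truth for training is
   built by 4-of-5 quorum voting over independent expert annotations, and
   identification error rates can be computed against that consensus.
4. **Tissue categories** — each tissue is binned by its counts:
   `0 Rosette` (no rosette), `1 Rosette` (one rosette and nothing else),
   `+1 Rosette` (a rosette plus any additional polarization area), and
   screens are aggregated per micropattern condition.

A fully seeded synthetic-image generator (circular tissue footprints with
rosette rings, radial tendrils, punctate foci, nuclei, z-stacks and noise)
provides ground truth for every stage, so the whole pipeline is testable
without any real acquisitions.

## Worked example

```python
import numpy as np
from rosettequant import (
    analyze_tissue, train_classifier, random_tissue_spec,
    generate_tissue_image, synthetic_training_set,
)

# train a focus-vs-rosette classifier on single-structure fixtures
vectors, labels = synthetic_training_set(n_per_class=8, seed=42)
model = train_classifier(vectors, labels, seed=0)

# a tissue with one rosette and two foci, clean noise regime
spec = random_tissue_spec(22, n_rosettes=1, n_foci=2, noise="clean",
                          image_size_px=768, tissue_diameter_um=300.0)
stack, truth = generate_tissue_image(spec)
report = analyze_tissue(stack, model, tissue_id="demo")
print(report.n_rosettes, report.n_foci, report.category)
for r in report.regions:
    print(f"{r['predicted_label']:>8}  area={r['area_um2']:7.1f} um^2  "
          f"halo={r['halo_intensity_ratio']:5.2f}  "
          f"incoherence1={r['tendril_angle_incoherence_1']:5.1f} deg")
```

prints

```
1 2 +1 Rosette
   focus  area=  638.2 um^2  halo= 7.27  incoherence1= 89.1 deg
   focus  area=  430.5 um^2  halo= 7.17  incoherence1= 89.1 deg
 rosette  area=  482.8 um^2  halo=14.81  incoherence1=  1.4 deg
```

— the rosette is the region with the bright coherent ring (halo ratio ≈ 15)
and radial tendrils (incoherence ≈ 1°); the foci have weaker boundary
contrast and no radial alignment, and one rosette plus two additional
polarization areas makes the tissue `+1 Rosette`.

The same workflow is available from the shell:

```bash
rosettequant make-fixtures --out tissues/ --n 10 --seed 1
rosettequant detect --input tissues/ --pixel-size-um 0.5 --model model.json --out results/
rosettequant screen --reports results/tissue_reports.csv \
    --condition-map conditions.csv --out screen.csv
```

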