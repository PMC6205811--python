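"""Per-tissue rosette counting, categorization, and screen aggregation.

Each micropatterned tissue is summarized by the number of classified neural
rosettes and residual polarization foci it contains and binned into one of
three categories used for morphology screens:

- ``0 Rosette``  — no rosette (zero or more foci alone do not qualify);
- ``1 Rosette``  — exactly one rosette and nothing else;
- ``+1 Rosette`` — a rosette plus at least one additional polarization area
  (a second rosette counts as an additional polarization area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify
from .classify import ClassifierModel
from .descriptors import DescriptorConfig, extract_descriptor_vector
from .detection import (
    DetectionConfig,
    detect_mser_regions,
    filter_regions_by_area,
    suppress_nested_regions,
)
from .image_io import ImageStack, median_filter, project

__all__ = [
    "CATEGORY_0",
    "CATEGORY_1",
    "CATEGORY_PLUS",
    "CATEGORIES",
    "TissueReport",
    "ScreenSummary",
    "categorize_tissue",
    "analyze_tissue",
    "summarize_screen",
]

CATEGORY_0 = "0 Rosette"
CATEGORY_1 = "1 Rosette"
CATEGORY_PLUS = "+1 Rosette"
CATEGORIES = (CATEGORY_0, CATEGORY_1, CATEGORY_PLUS)


def categorize_tissue(n_rosettes: int, n_foci: int) -> str:
    """Map (rosette count, focus count) to the screen category.

    Total over all nonnegative count pairs: no rosette → ``0 Rosette``;
    one rosette alone → ``1 Rosette``; anything more → ``+1 Rosette``.
    """
    if n_rosettes < 0 or n_foci < 0:
        raise ValueError(f"counts must be >= 0, got ({n_rosettes}, {n_foci})")
    if n_rosettes == 0:
        return CATEGORY_0
    if n_rosettes == 1 and n_foci == 0:
        return CATEGORY_1
    return CATEGORY_PLUS


@dataclass(frozen=True)
class TissueReport:
    tissue_id: str
    n_rosettes: int
    n_foci: int
    category: str
    regions: tuple[dict, ...] = ()
    n_unscorable: int = 0

    def __post_init__(self) -> None:
        if self.category != categorize_tissue(self.n_rosettes, self.n_foci):
            raise ValueError("category inconsistent with counts")


@dataclass(frozen=True)
class ScreenSummary:
    """Per-condition category counts and fractions of a screen."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def analyze_tissue(
    stack: ImageStack,
    model: ClassifierModel,
    detection_cfg: DetectionConfig = DetectionConfig(),
    descriptor_cfg: DescriptorConfig = DescriptorConfig(),
    median_kernel_px: int = 3,
    tissue_id: str = "tissue",
    channel: str = "ncadherin",
) -> TissueReport:
    """Run the full pipeline on one stack and report counts and category.

    Projection → median filter → MSER → area exclusion → nested-region
    suppression → descriptors → classification → counts. Unscorable regions
    (flagged descriptors) are excluded from the counts but listed in the
    per-region records. Deterministic given inputs and configuration.
    """
    max_proj = median_filter(project(stack, channel, "max"), median_kernel_px)
    mean_proj = median_filter(project(stack, channel, "mean"), median_kernel_px)

    regions = detect_mser_regions(max_proj, detection_cfg, stack.pixel_size_um)
    regions = filter_regions_by_area(regions, detection_cfg.min_area_um2)
    regions = suppress_nested_regions(regions, detection_cfg.overlap_suppression_threshold)

    all_masks = np.zeros(max_proj.image.shape, dtype=bool)
    for r in regions:
        all_masks[r.pixels[:, 0], r.pixels[:, 1]] = True

    records: list[dict] = []
    n_rosettes = n_foci = n_unscorable = 0
    for r in regions:
        others = all_masks.copy()
        others[r.pixels[:, 0], r.pixels[:, 1]] = False
        vec = extract_descriptor_vector(
            max_proj, mean_proj, r, descriptor_cfg, other_masks=others
        )
        rec = {
            "tissue_id": tissue_id,
            "region_label": r.label,
            "centroid_row": r.centroid_px[0],
            "centroid_col": r.centroid_px[1],
            "radius_px": r.radius_px,
            "scorable": vec.scorable,
            "flags": ";".join(vec.flags),
        }
        rec.update({name: getattr(vec, name) for name in vec.__dataclass_fields__ if name in
                    ("area_um2", "major_axis_um", "eccentricity", "halo_intensity_ratio",
                     "tendril_density_1", "tendril_density_2",
                     "tendril_angle_incoherence_1", "tendril_angle_incoherence_2")})
        if vec.scorable:
            label, prob = classify.predict(model, vec)
            rec["predicted_label"] = label
            rec["rosette_probability"] = prob
            if label == classify.ROSETTE:
                n_rosettes += 1
            else:
                n_foci += 1
        else:
            rec["predicted_label"] = "unscorable"
            rec["rosette_probability"] = float("nan")
            n_unscorable += 1
        records.append(rec)

    return TissueReport(
        tissue_id=tissue_id,
        n_rosettes=n_rosettes,
        n_foci=n_foci,
        category=categorize_tissue(n_rosettes, n_foci),
        regions=tuple(records),
        n_unscorable=n_unscorable,
    )


def summarize_screen(
    reports: Sequence[TissueReport],
    condition_map: Mapping[str, str],
) -> ScreenSummary:
    """Aggregate tissue reports into per-condition category fractions.

    Conditions appear in the order of their first occurrence in
    ``condition_map``; an unmapped tissue id is an error.
    """
    if not reports:
        raise ValueError("no tissue reports to summarize")
    unmapped = [r.tissue_id for r in reports if r.tissue_id not in condition_map]
    if unmapped:
        raise KeyError(f"tissue id(s) not in condition map: {unmapped}")
    cond_order = list(dict.fromkeys(condition_map.values()))
    rows = []
    by_cond: dict[str, list[TissueReport]] = {c: [] for c in cond_order}
    for r in reports:
        by_cond[condition_map[r.tissue_id]].append(r)
    for cond in cond_order:
        group = by_cond[cond]
        if not group:
            continue
        n = len(group)
        counts = {cat: sum(1 for g in group if g.category == cat) for cat in CATEGORIES}
        row = {"condition": cond, "n_tissues": n}
        for cat in CATEGORIES:
            key = cat.replace(" ", "_").replace("+", "plus_")
            row[f"count_{key}"] = counts[cat]
            row[f"fraction_{key}"] = counts[cat] / n
        rows.append(row)
    return ScreenSummary(table=pd.DataFrame(rows))
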