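"""Detection of N-cadherin polarization regions.

Candidate regions of dense N-cadherin staining are found on the
median-filtered maximum-intensity projection with maximally stable extremal
regions (MSER): bright-on-dark connected components of upper level sets whose
pixel area is stable across a band of gray levels. The projection is lightly
Gaussian-smoothed before level-set extraction, each surviving component is
measured (area, fitted-ellipse major axis, eccentricity), regions smaller
than the area exclusion threshold (176 µm² by default) are dropped, and
nested near-duplicates from the component tree are suppressed.

The MSER sweep runs on a min–max normalized, 256-level quantization of the
smoothed projection, so the detected region set is exactly invariant under
positive affine rescaling of the input intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .image_io import Projection

__all__ = [
    "DetectionConfig",
    "PolarizationRegion",
    "detect_mser_regions",
    "measure_region",
    "filter_regions_by_area",
    "suppress_nested_regions",
]

_N_LEVELS = 256
_STRUCTURE8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the region detector.

    ``min_area_um2`` carries the printed exclusion threshold: regions with
    area strictly below it are discarded (areas exactly equal are retained).
    MSER parameters are permissive by design; the area filter does the real
    exclusion work.
    """

    mser_delta: int = 5
    mser_min_area_px: int = 60
    mser_max_area_px: int | None = None  # None -> 1/4 of the image pixels
    mser_max_variation: float = 0.5
    min_area_um2: float = 176.0
    overlap_suppression_threshold: float = 0.5
    smoothing_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.mser_max_area_px is not None and self.mser_min_area_px >= self.mser_max_area_px:
            raise ValueError("mser_min_area_px must be < mser_max_area_px")
        if not 0 < self.overlap_suppression_threshold <= 1:
            raise ValueError("overlap_suppression_threshold must lie in (0, 1]")
        if self.mser_delta < 1:
            raise ValueError("mser_delta must be >= 1")


@dataclass(frozen=True)
class PolarizationRegion:
    """A detected region of polarized N-cadherin.

    ``pixels`` holds 0-based (row, col) mask coordinates; ``shape`` is the
    source image shape so the mask can be rasterized. ``radius_px`` is half
    the fitted-ellipse major axis and is the sampling radius used by the
    tendril descriptors.
    """

    pixels: np.ndarray  # (n, 2) int
    shape: tuple[int, int]
    centroid_px: tuple[float, float]
    area_um2: float
    major_axis_um: float
    eccentricity: float
    radius_px: float
    label: int = 0

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.shape[0])

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[self.pixels[:, 0], self.pixels[:, 1]] = True
        return mask

    def flat_indices(self) -> np.ndarray:
        """Sorted raveled pixel indices (overlap computations)."""
        return np.sort(self.pixels[:, 0] * self.shape[1] + self.pixels[:, 1])


def measure_region(
    mask: np.ndarray, pixel_size_um: float
) -> tuple[float, float, float, tuple[float, float]]:
    """Area, eccentricity, major axis and centroid of a pixel mask.

    The ellipse is fitted from second central image moments with the usual
    normalization (major axis length = 4·sqrt of the largest eigenvalue of
    the per-pixel covariance), so a solid ellipse of semi-axes a >= b yields
    major axis 2a and eccentricity sqrt(1 - (b/a)²).

    ``mask`` may be a 2-D boolean raster or an (n, 2) array of coordinates.

    Returns ``(area_um2, eccentricity, major_axis_um, centroid_px)``.
    """
    mask = np.asarray(mask)
    if mask.ndim == 2 and mask.dtype != bool and mask.shape[1] == 2:
        coords = mask.astype(np.float64)
    elif mask.ndim == 2:
        coords = np.argwhere(mask).astype(np.float64)
    else:
        raise ValueError("mask must be 2-D boolean or (n, 2) coordinates")
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    n = coords.shape[0]
    centroid = coords.mean(axis=0)
    d = coords - centroid
    mu20 = float(np.dot(d[:, 0], d[:, 0])) / n
    mu02 = float(np.dot(d[:, 1], d[:, 1])) / n
    mu11 = float(np.dot(d[:, 0], d[:, 1])) / n
    # eigenvalues of [[mu20, mu11], [mu11, mu02]]
    tr = mu20 + mu02
    det = mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + np.sqrt(disc)
    l2 = tr / 2.0 - np.sqrt(disc)
    major_px = 4.0 * np.sqrt(max(l1, 0.0))
    ecc = float(np.sqrt(1.0 - l2 / l1)) if l1 > 0 else 0.0
    area = n * pixel_size_um**2
    return area, ecc, major_px * pixel_size_um, (float(centroid[0]), float(centroid[1]))


def _make_region(pixels: np.ndarray, shape: tuple[int, int], pixel_size_um: float, label: int) -> PolarizationRegion:
    area, ecc, major_um, centroid = measure_region(pixels, pixel_size_um)
    return PolarizationRegion(
        pixels=np.ascontiguousarray(pixels, dtype=np.int64),
        shape=shape,
        centroid_px=centroid,
        area_um2=area,
        major_axis_um=major_um,
        eccentricity=ecc,
        radius_px=major_um / pixel_size_um / 2.0,
        label=label,
    )


def _mser_sweep(
    q: np.ndarray, cfg: DetectionConfig, max_area_px: int
) -> list[tuple[np.ndarray, float]]:
    """Core MSER pass over the 0..255 quantized image ``q``.

    Upper level sets {q >= t} are labelled for t = 1..255 (ascending, so
    components only split). Components are chained across consecutive levels;
    each component's variation is its area growth relative to its enclosing
    component ``delta`` levels lower. Each chain contributes at most one
    candidate: the member with minimal variation, provided it meets the area
    and variation bounds. Returns ``(pixels, variation)`` pairs.
    """
    delta = cfg.mser_delta
    min_a, max_v = cfg.mser_min_area_px, cfg.mser_max_variation

    # ring buffer of (labels, areas) for levels t-delta .. t-1
    whole = np.ones(q.shape, dtype=np.int32)
    buffer: list[tuple[np.ndarray, np.ndarray]] = [
        (whole, np.array([0, q.size], dtype=np.int64))
    ] * delta
    prev_lab, prev_n = whole, 1
    prev_chain = np.array([0, 0], dtype=np.int64)  # comp id -> chain id (index 0 unused)

    chains_best_var: list[float] = [np.inf]  # chain 0 = root
    chains_best_pixels: list[np.ndarray | None] = [None]

    for t in range(1, _N_LEVELS):
        mask = q >= t
        lab, nlab = ndi.label(mask, structure=_STRUCTURE8)
        if nlab == 0:
            break
        flat_lab = lab.ravel()
        sel = np.flatnonzero(flat_lab)
        comp_of = flat_lab[sel]
        areas = np.bincount(comp_of, minlength=nlab + 1)

        # parent component one level down, and the reference delta levels down
        parent = np.zeros(nlab + 1, dtype=np.int64)
        parent[comp_of] = prev_lab.ravel()[sel]
        low_lab, low_areas = buffer[0]
        low_of = np.zeros(nlab + 1, dtype=np.int64)
        low_of[comp_of] = low_lab.ravel()[sel]
        variation = (low_areas[low_of] - areas) / np.maximum(areas, 1)

        # chain bookkeeping: a component continues its parent's chain iff it
        # is the parent's only child at this level; otherwise it starts anew
        child_count = np.bincount(parent[1:], minlength=prev_n + 1)
        chain = np.zeros(nlab + 1, dtype=np.int64)
        cont = child_count[parent] == 1
        cont[0] = False
        chain[cont] = prev_chain[parent[cont]]
        fresh = np.flatnonzero(~cont[1:]) + 1
        first_new = len(chains_best_var)
        chain[fresh] = np.arange(first_new, first_new + fresh.size)
        chains_best_var.extend([np.inf] * fresh.size)
        chains_best_pixels.extend([None] * fresh.size)

        ok = np.flatnonzero(
            (areas >= min_a) & (areas <= max_area_px) & (variation <= max_v)
        )
        for c in ok:
            if c == 0:
                continue
            ch = chain[c]
            if variation[c] < chains_best_var[ch]:
                chains_best_var[ch] = float(variation[c])
                idx = sel[comp_of == c]
                chains_best_pixels[ch] = idx

        buffer.append((lab, areas))
        buffer.pop(0)
        prev_lab, prev_n, prev_chain = lab, nlab, chain

    out = []
    for px, var in zip(chains_best_pixels, chains_best_var):
        if px is not None:
            out.append((np.column_stack(np.unravel_index(px, q.shape)), var))
    return out


def _prune_by_stability(
    candidates: list[tuple[np.ndarray, float]],
    shape: tuple[int, int],
    overlap_threshold: float,
) -> list[np.ndarray]:
    """Diversity pruning of the nested candidate set.

    Candidates from one extremal-region lineage overlap heavily (the same
    structure re-emitted at different levels, or a structure inside the
    looser component that envelops it at low gray levels). Among candidates
    whose intersection exceeds ``overlap_threshold`` of the smaller mask,
    only the most stable (lowest-variation) one survives — the standard
    MSER diversity criterion.
    """
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i][1], i))
    flats = [np.sort(px[:, 0] * shape[1] + px[:, 1]) for px, _ in candidates]
    kept: list[int] = []
    for i in order:
        fi = flats[i]
        if all(
            np.intersect1d(fi, flats[j], assume_unique=True).size
            / min(fi.size, flats[j].size)
            <= overlap_threshold
            for j in kept
        ):
            kept.append(i)
    return [candidates[i][0] for i in sorted(kept)]


def detect_mser_regions(
    image: Projection | np.ndarray,
    cfg: DetectionConfig,
    pixel_size_um: float,
) -> list[PolarizationRegion]:
    """Detect bright stable extremal regions on a (filtered) max projection.

    Returns measured regions sorted by centroid for determinism. A uniform
    image yields an empty list; a degenerate (single-pixel-wide) image is an
    error.
    """
    img = np.asarray(image.image if isinstance(image, Projection) else image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("detection image must be 2-D")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"degenerate image of shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("detection image contains non-finite values")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    if cfg.smoothing_sigma_px > 0:
        img = ndi.gaussian_filter(img, cfg.smoothing_sigma_px, mode="reflect")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return []
    q = np.rint((img - lo) / (hi - lo) * (_N_LEVELS - 1)).astype(np.int16)

    max_area_px = cfg.mser_max_area_px if cfg.mser_max_area_px is not None else img.size // 4
    candidates = _mser_sweep(q, cfg, max_area_px)
    pixel_sets = _prune_by_stability(candidates, img.shape, cfg.overlap_suppression_threshold)
    regions = [
        _make_region(px, img.shape, pixel_size_um, label=i + 1)
        for i, px in enumerate(pixel_sets)
    ]
    regions.sort(key=lambda r: (r.centroid_px[0], r.centroid_px[1], -r.area_um2))
    return [replace(r, label=i + 1) for i, r in enumerate(regions)]


def filter_regions_by_area(
    regions: Sequence[PolarizationRegion], min_area_um2: float
) -> list[PolarizationRegion]:
    """Retain regions with area >= ``min_area_um2`` (order preserved).

    The exclusion is strict below the threshold: a region whose area equals
    the threshold exactly is kept.
    """
    return [r for r in regions if r.area_um2 >= min_area_um2]


def suppress_nested_regions(
    regions: Sequence[PolarizationRegion], overlap_threshold: float = 0.5
) -> list[PolarizationRegion]:
    """Collapse nested/duplicated component-tree output.

    When two regions' intersection exceeds ``overlap_threshold`` as a
    fraction of the smaller region's area, only the larger-area region is
    kept (first occurrence wins on exact ties). The result contains no such
    pair.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must lie in (0, 1]")
    order = sorted(range(len(regions)), key=lambda i: (-regions[i].n_pixels, i))
    kept: list[int] = []
    flats = {i: regions[i].flat_indices() for i in order}
    for i in order:
        fi = flats[i]
        suppressed = False
        for j in kept:
            inter = np.intersect1d(fi, flats[j], assume_unique=True).size
            if inter / min(fi.size, flats[j].size) > overlap_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(i)
    kept.sort()
    return [regions[i] for i in kept]
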