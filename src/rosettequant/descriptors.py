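"""The eight-element descriptor vector of a polarization region.

A neural rosette is distinguished from a mere polarization focus by a
coherent N-cadherin ring (the *halo*) with radially aligned membrane staining
(*tendrils*) around it. Each detected region is scored with:

1. area (µm²), 2. fitted-ellipse major axis (µm), 3. eccentricity — shape of
the N-cadherin-dense zone;
4. halo intensity ratio — mean fluorescence inside the region over the mean
just outside its boundary, measured on the median-filtered mean projection;
5–6. tendril densities at the two sampling rings;
7–8. tendril angle incoherences at the two sampling rings.

Tendril descriptors come from 20-pixel square patches sampled around the
region epicenter at 1.5× (ring 1) and 2× (ring 2) the region radius (half
the fitted major axis). Density is the normalized mean patch intensity;
incoherence is the acute angle between the patch's dominant structure
orientation (structure-tensor estimate) and the radial ray, so a perfectly
radial tendril — perpendicular to the halo tangent — scores 0° and a
tangential one 90°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import scipy.ndimage as ndi

from .detection import PolarizationRegion
from .image_io import Projection

__all__ = [
    "DescriptorConfig",
    "HaloAssessment",
    "TendrilSample",
    "DescriptorVector",
    "DESCRIPTOR_NAMES",
    "assess_halo",
    "place_tendril_samples",
    "tendril_density",
    "tendril_angle_incoherence",
    "extract_descriptor_vector",
]

DESCRIPTOR_NAMES = (
    "area_um2",
    "major_axis_um",
    "eccentricity",
    "halo_intensity_ratio",
    "tendril_density_1",
    "tendril_density_2",
    "tendril_angle_incoherence_1",
    "tendril_angle_incoherence_2",
)


@dataclass(frozen=True)
class DescriptorConfig:
    ring_multipliers: tuple[float, float] = (1.5, 2.0)
    sampling_square_px: int = 20
    n_sample_angles: int = 16
    halo_margin_px: int = 5
    density_percentile: float = 100.0

    def __post_init__(self) -> None:
        if any(m <= 1 for m in self.ring_multipliers):
            raise ValueError("ring multipliers must be > 1")
        if self.sampling_square_px < 3:
            raise ValueError("sampling_square_px must be >= 3")
        if self.n_sample_angles < 1:
            raise ValueError("n_sample_angles must be >= 1")
        if self.halo_margin_px < 1:
            raise ValueError("halo_margin_px must be >= 1")


@dataclass(frozen=True)
class HaloAssessment:
    boundary: np.ndarray  # (n, 2) outer boundary pixel coordinates
    intensity_ratio: float | None
    margin_px: int
    flags: tuple[str, ...] = ()

    @property
    def scorable(self) -> bool:
        return self.intensity_ratio is not None and math.isfinite(self.intensity_ratio)


@dataclass(frozen=True)
class TendrilSample:
    center_px: tuple[int, int]
    ring_index: int  # 1 -> 1.5x radius, 2 -> 2x radius
    radial_direction: float  # radians; ray from region centroid through center
    patch: np.ndarray | None = None

    def with_patch(self, image: np.ndarray, size: int) -> "TendrilSample":
        half = size // 2
        r, c = self.center_px
        patch = np.asarray(image, dtype=np.float64)[r - half : r - half + size, c - half : c - half + size]
        return TendrilSample(self.center_px, self.ring_index, self.radial_direction, patch)


@dataclass(frozen=True)
class DescriptorVector:
    area_um2: float
    major_axis_um: float
    eccentricity: float
    halo_intensity_ratio: float
    tendril_density_1: float
    tendril_density_2: float
    tendril_angle_incoherence_1: float
    tendril_angle_incoherence_2: float
    scorable: bool = True
    flags: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=np.float64)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy * yy + xx * xx <= r * r


def assess_halo(
    mean_projection: Projection | np.ndarray,
    region: PolarizationRegion,
    margin_px: int = 5,
    other_masks: np.ndarray | None = None,
) -> HaloAssessment:
    """Internal/external mean-intensity ratio across the region boundary.

    Internal mean: over the region mask eroded by ``margin_px`` (the full
    mask if erosion empties it, e.g. for thin rings). External mean: over
    the annulus between the ``margin_px`` and ``2·margin_px`` dilations of
    the mask, excluding pixels belonging to other detected regions. A region
    whose external annulus is empty, or whose surroundings have zero mean,
    is flagged and left unscored (ratio ``None`` / ``inf``).
    """
    img = np.asarray(
        mean_projection.image if isinstance(mean_projection, Projection) else mean_projection,
        dtype=np.float64,
    )
    mask = region.to_mask()
    flags: list[str] = []
    if (
        region.pixels[:, 0].min() == 0
        or region.pixels[:, 1].min() == 0
        or region.pixels[:, 0].max() == mask.shape[0] - 1
        or region.pixels[:, 1].max() == mask.shape[1] - 1
    ):
        flags.append("touches_border")

    inner = ndi.binary_erosion(mask, structure=_disk(margin_px))
    if not inner.any():
        inner = mask
        flags.append("erosion_fallback")
    d1 = ndi.binary_dilation(mask, structure=_disk(margin_px))
    d2 = ndi.binary_dilation(d1, structure=_disk(margin_px))
    annulus = d2 & ~d1
    if other_masks is not None:
        annulus &= ~other_masks

    # outer boundary: mask pixels not interior under 8-connectivity
    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    boundary = np.argwhere(mask & ~interior)

    if not annulus.any():
        flags.append("empty_external_annulus")
        return HaloAssessment(boundary, None, margin_px, tuple(flags))
    internal = float(img[inner].mean())
    external = float(img[annulus].mean())
    if external <= 0:
        flags.append("zero_external_mean")
        return HaloAssessment(boundary, math.inf, margin_px, tuple(flags))
    return HaloAssessment(boundary, internal / external, margin_px, tuple(flags))


def place_tendril_samples(
    region: PolarizationRegion,
    cfg: DescriptorConfig,
    image_shape: tuple[int, int],
) -> list[TendrilSample]:
    """Lay out sampling squares on the two rings around the region epicenter.

    ``n_sample_angles`` equally spaced rays per ring; a sample whose square
    would cross the image border is dropped. Angle 0 points along +col and
    angles increase towards +row.
    """
    if region.radius_px <= 0:
        raise ValueError("region radius must be > 0")
    size = cfg.sampling_square_px
    half = size // 2
    nrow, ncol = image_shape
    cr, cc = region.centroid_px
    samples: list[TendrilSample] = []
    for ring_index, mult in enumerate(cfg.ring_multipliers, start=1):
        r = mult * region.radius_px
        for k in range(cfg.n_sample_angles):
            theta = 2.0 * math.pi * k / cfg.n_sample_angles
            pr = int(round(cr + r * math.sin(theta)))
            pc = int(round(cc + r * math.cos(theta)))
            if pr - half < 0 or pc - half < 0 or pr - half + size > nrow or pc - half + size > ncol:
                continue
            samples.append(TendrilSample((pr, pc), ring_index, theta))
    return samples


def tendril_density(sample: TendrilSample, normalization: float) -> float:
    """Mean patch intensity over the normalization reference, clipped to [0, 1]."""
    if sample.patch is None or sample.patch.size == 0:
        raise ValueError("sample carries no patch")
    if normalization <= 0:
        raise ValueError("normalization reference must be > 0")
    return float(np.clip(sample.patch.mean() / normalization, 0.0, 1.0))


def tendril_angle_incoherence(sample: TendrilSample, smooth_sigma: float = 1.0) -> float | None:
    """Acute angle (degrees) between local structure orientation and the radial ray.

    Gradients are taken with 3×3 Sobel kernels after Gaussian smoothing
    (σ = 1 px). The dominant orientation is the axial (period-180°) circular
    mean of gradient orientations weighted by squared gradient magnitude —
    the structure-tensor orientation — rotated 90° to give the ridge
    direction. A flat patch has no orientation and returns ``None``.
    """
    patch = sample.patch
    if patch is None or patch.size == 0:
        raise ValueError("sample carries no patch")
    patch = np.asarray(patch, dtype=np.float64)
    if patch.max() == patch.min():
        return None
    sm = ndi.gaussian_filter(patch, smooth_sigma, mode="reflect")
    gr = ndi.sobel(sm, axis=0, mode="reflect")
    gc = ndi.sobel(sm, axis=1, mode="reflect")
    # axial mean of gradient orientation: sum of |g|^2 (cos 2phi, sin 2phi)
    c2 = float(np.sum(gc * gc - gr * gr))
    s2 = float(np.sum(2.0 * gc * gr))
    if c2 == 0.0 and s2 == 0.0:
        return None
    grad_orient = 0.5 * math.atan2(s2, c2)
    ridge_orient = grad_orient + math.pi / 2.0
    diff = ridge_orient - sample.radial_direction
    # fold to the acute axial difference in [0, 90] degrees
    folded = abs((diff + math.pi / 2.0) % math.pi - math.pi / 2.0)
    return math.degrees(folded)


def extract_descriptor_vector(
    max_proj: Projection | np.ndarray,
    mean_proj: Projection | np.ndarray,
    region: PolarizationRegion,
    cfg: DescriptorConfig = DescriptorConfig(),
    other_masks: np.ndarray | None = None,
    density_reference: float | None = None,
) -> DescriptorVector:
    """Assemble the eight descriptors for one region.

    Halo, tendril density and tendril incoherence are measured on the
    (median-filtered) mean projection; geometry comes from the detection on
    the max projection. Ring statistics are arithmetic means over the valid
    samples of each ring. A vector with any undefined field is returned with
    ``scorable=False`` and the reason in ``flags``.
    """
    mean_img = np.asarray(
        mean_proj.image if isinstance(mean_proj, Projection) else mean_proj, dtype=np.float64
    )
    flags: list[str] = []

    halo = assess_halo(mean_proj, region, cfg.halo_margin_px, other_masks)
    flags.extend(halo.flags)
    halo_ratio = halo.intensity_ratio if halo.intensity_ratio is not None else math.nan
    if not halo.scorable:
        flags.append("halo_unscorable")

    if density_reference is None:
        # the projection maximum (percentile 100) is robust to how small a
        # fraction of the field the structures cover; a percentile reference
        # would fall back to background on sparse fields
        if cfg.density_percentile >= 100.0:
            density_reference = float(mean_img.max())
        else:
            density_reference = float(np.percentile(mean_img, cfg.density_percentile))
    samples = [
        s.with_patch(mean_img, cfg.sampling_square_px)
        for s in place_tendril_samples(region, cfg, mean_img.shape)
    ]
    densities: dict[int, list[float]] = {1: [], 2: []}
    angles: dict[int, list[float]] = {1: [], 2: []}
    n_flat = 0
    for s in samples:
        densities[s.ring_index].append(tendril_density(s, density_reference))
        a = tendril_angle_incoherence(s)
        if a is None:
            n_flat += 1
        else:
            angles[s.ring_index].append(a)
    if n_flat:
        flags.append(f"flat_patches:{n_flat}")

    vals: dict[str, float] = {}
    for ring in (1, 2):
        if densities[ring]:
            vals[f"tendril_density_{ring}"] = float(np.mean(densities[ring]))
        else:
            vals[f"tendril_density_{ring}"] = math.nan
            flags.append(f"no_samples_ring_{ring}")
        if angles[ring]:
            vals[f"tendril_angle_incoherence_{ring}"] = float(np.mean(angles[ring]))
        else:
            vals[f"tendril_angle_incoherence_{ring}"] = math.nan
            if f"no_samples_ring_{ring}" not in flags:
                flags.append(f"no_oriented_samples_ring_{ring}")

    vec = DescriptorVector(
        area_um2=region.area_um2,
        major_axis_um=region.major_axis_um,
        eccentricity=region.eccentricity,
        halo_intensity_ratio=halo_ratio,
        tendril_density_1=vals["tendril_density_1"],
        tendril_density_2=vals["tendril_density_2"],
        tendril_angle_incoherence_1=vals["tendril_angle_incoherence_1"],
        tendril_angle_incoherence_2=vals["tendril_angle_incoherence_2"],
        scorable=True,
        flags=tuple(flags),
    )
    if not np.all(np.isfinite(vec.as_array())):
        vec = DescriptorVector(
            **{n: getattr(vec, n) for n in DESCRIPTOR_NAMES}, scorable=False, flags=tuple(flags)
        )
    return vec
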