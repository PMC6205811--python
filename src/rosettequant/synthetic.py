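"""Synthetic micropatterned-tissue images with known ground truth.

The generator emulates the fluorescence phenotypes the pipeline is built to
score: a circular micropatterned tissue footprint containing

- *rosettes*: a bright N-cadherin ring (annular Gaussian cross-section) with
  straight, exactly radial tendrils of Gaussian cross-section emanating from
  it — the radial geometry gives an analytic orientation oracle for the
  tendril-incoherence descriptor;
- *foci*: isotropic plateau blobs of punctate N-cadherin without a ring;

plus a nuclei channel of dense random blobs, replication across z-planes
with small per-plane intensity jitter, and Gaussian and/or Poisson noise.
Two pinned noise regimes, ``clean`` (low Gaussian noise) and ``realistic``
(higher Gaussian plus Poisson), keep test conditions unambiguous.

Everything is deterministic per seed. The default geometry mirrors the
acquisitions the method targets: 1024×1024 px at 0.5 µm/px, 7 z-planes at
1.5 µm, a 200 µm diameter circular tissue, ring radii 15–20 µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .classify import FOCUS, ROSETTE
from .descriptors import DescriptorConfig, extract_descriptor_vector
from .detection import (
    DetectionConfig,
    detect_mser_regions,
    filter_regions_by_area,
    suppress_nested_regions,
)
from .image_io import ImageStack, median_filter, project
from .tissue import categorize_tissue

__all__ = [
    "HALF_MAX",
    "NOISE_REGIMES",
    "RosetteSpec",
    "FocusSpec",
    "SyntheticTissueSpec",
    "StructureTruth",
    "GroundTruth",
    "generate_tissue_image",
    "random_tissue_spec",
    "generate_descriptor_dataset",
    "synthetic_training_set",
]

HALF_MAX = math.sqrt(2.0 * math.log(2.0))  # half-width at half max, in sigmas

#: Pinned noise regimes: Gaussian sigma (intensity units on the 0-255-ish
#: scale the generator draws on) and whether Poisson shot noise is applied.
NOISE_REGIMES: dict[str, tuple[float, bool]] = {
    "none": (0.0, False),
    "clean": (2.0, False),
    "realistic": (8.0, True),
}


@dataclass(frozen=True)
class RosetteSpec:
    """A rosette: bright ring plus detached radial tendrils.

    Tendrils are thin radial lines starting well outside the ring (2.0 ×
    ring radius by default) and reaching to 3.6 × ring radius, the zone the
    descriptor extractor samples (its rings sit at roughly 2.1 and 2.8 ring
    radii, since the detected annulus has fitted radius ≈ 1.41 × ring
    radius). The stand-off keeps each tendril a separate faint component so
    the bright ring is detected as its own stable region; individual
    tendrils fall below the region-area exclusion.
    """

    center_px: tuple[float, float]  # (row, col)
    ring_radius_px: float
    ring_width_px: float = 4.0
    ring_intensity: float = 200.0
    n_tendrils: int = 28
    tendril_inner_px: float | None = None  # None -> 2.0 * ring_radius_px
    tendril_length_px: float | None = None  # None -> 1.6 * ring_radius_px
    tendril_intensity: float = 90.0
    tendril_width_px: float = 1.5
    tendril_angle_offset: float = 0.0

    @property
    def tendril_length(self) -> float:
        return (
            self.tendril_length_px
            if self.tendril_length_px is not None
            else 1.6 * self.ring_radius_px
        )

    @property
    def tendril_start_px(self) -> float:
        return (
            self.tendril_inner_px
            if self.tendril_inner_px is not None
            else 2.0 * self.ring_radius_px
        )

    @property
    def full_extent_px(self) -> float:
        """Outer reach including tendril tips."""
        return self.tendril_start_px + self.tendril_length

    @property
    def nominal_radius_px(self) -> float:
        """Outer radius of the bright ring at half maximum."""
        return self.ring_radius_px + HALF_MAX * self.ring_width_px

    @property
    def nominal_area_px2(self) -> float:
        """Area of the above-half-max annulus."""
        h = HALF_MAX * self.ring_width_px
        return math.pi * ((self.ring_radius_px + h) ** 2 - (self.ring_radius_px - h) ** 2)


_FOCUS_EXPONENT = 4  # steep plateau profile: exp(-(d/sigma)^4)
_FOCUS_HALF_MAX = math.log(2.0) ** 0.25  # half-max radius in sigmas


@dataclass(frozen=True)
class FocusSpec:
    """A punctate polarization focus: compact plateau blob, no ring.

    Rendered as ``intensity · exp(−(d/σ)⁴)`` — a steep-shouldered plateau —
    so the staining is dense but stops abruptly, as punctate N-cadherin
    accumulations do; by the tendril-sampling rings (1.5–2 region radii
    out) the profile has decayed to background.
    """

    center_px: tuple[float, float]
    blob_sigma_px: float = 25.0
    intensity: float = 180.0

    @property
    def nominal_radius_px(self) -> float:
        return _FOCUS_HALF_MAX * self.blob_sigma_px

    @property
    def nominal_area_px2(self) -> float:
        return math.pi * self.nominal_radius_px**2


@dataclass(frozen=True)
class SyntheticTissueSpec:
    image_size_px: int = 1024
    pixel_size_um: float = 0.5
    tissue_diameter_um: float = 200.0
    tissue_center_px: tuple[float, float] | None = None  # None -> image center
    rosettes: tuple[RosetteSpec, ...] = ()
    foci: tuple[FocusSpec, ...] = ()
    background_intensity: float = 10.0
    outside_intensity: float = 2.0
    noise_sigma: float = 0.0
    poisson: bool = False
    n_planes: int = 7
    z_step_um: float = 1.5
    plane_jitter: float = 0.03
    seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        if self.tissue_center_px is not None:
            return self.tissue_center_px
        c = (self.image_size_px - 1) / 2.0
        return (c, c)

    @property
    def tissue_radius_px(self) -> float:
        return self.tissue_diameter_um / self.pixel_size_um / 2.0

    def validate(self) -> None:
        if self.image_size_px < 16:
            raise ValueError("image_size_px too small")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        structs = self._structures()
        tc = np.asarray(self.center)
        for kind, c, rad, s in structs:
            reach = float(np.linalg.norm(np.asarray(c) - tc))
            extent = s.full_extent_px if isinstance(s, RosetteSpec) else rad
            if reach + extent > self.tissue_radius_px:
                raise ValueError(f"{kind} at {c} extends outside the tissue footprint")
        for i in range(len(structs)):
            for j in range(i + 1, len(structs)):
                d = float(np.linalg.norm(np.asarray(structs[i][1]) - np.asarray(structs[j][1])))
                if d < structs[i][2] + structs[j][2]:
                    raise ValueError(
                        f"structures at {structs[i][1]} and {structs[j][1]} overlap"
                    )

    def _structures(self):
        out = [(ROSETTE, r.center_px, r.nominal_radius_px, r) for r in self.rosettes]
        out += [(FOCUS, f.center_px, f.nominal_radius_px, f) for f in self.foci]
        return out


@dataclass(frozen=True)
class StructureTruth:
    kind: str  # rosette | focus
    center_px: tuple[float, float]
    nominal_radius_px: float
    nominal_area_um2: float


@dataclass(frozen=True)
class GroundTruth:
    structures: tuple[StructureTruth, ...]
    expected_category: str

    @property
    def n_rosettes(self) -> int:
        return sum(1 for s in self.structures if s.kind == ROSETTE)

    @property
    def n_foci(self) -> int:
        return sum(1 for s in self.structures if s.kind == FOCUS)


def _render_ring(img: np.ndarray, r: RosetteSpec) -> None:
    cr, cc = r.center_px
    pad = r.ring_radius_px + 4 * r.ring_width_px
    r0 = max(int(cr - pad), 0)
    r1 = min(int(cr + pad) + 2, img.shape[0])
    c0 = max(int(cc - pad), 0)
    c1 = min(int(cc + pad) + 2, img.shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - cr, xx - cc)
    img[r0:r1, c0:c1] += r.ring_intensity * np.exp(
        -((d - r.ring_radius_px) ** 2) / (2.0 * r.ring_width_px**2)
    )


def _render_segment(
    img: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    intensity: float,
    width: float,
) -> None:
    pad = 4.0 * width
    r0 = max(int(min(a[0], b[0]) - pad), 0)
    r1 = min(int(max(a[0], b[0]) + pad) + 2, img.shape[0])
    c0 = max(int(min(a[1], b[1]) - pad), 0)
    c1 = min(int(max(a[1], b[1]) + pad) + 2, img.shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    p = np.stack([yy - a[0], xx - a[1]], axis=-1).astype(np.float64)
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = np.clip((p @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(p.shape[:2])
    d2 = np.sum((p - t[..., None] * ab) ** 2, axis=-1)
    img[r0:r1, c0:c1] += intensity * np.exp(-d2 / (2.0 * width**2))


def _render_blob(
    img: np.ndarray,
    center: tuple[float, float],
    sigma: float,
    intensity: float,
    exponent: float = 2.0,
) -> None:
    cr, cc = center
    pad = 4 * sigma
    r0 = max(int(cr - pad), 0)
    r1 = min(int(cr + pad) + 2, img.shape[0])
    c0 = max(int(cc - pad), 0)
    c1 = min(int(cc + pad) + 2, img.shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - cr, xx - cc)
    if exponent == 2.0:
        img[r0:r1, c0:c1] += intensity * np.exp(-(d**2) / (2.0 * sigma**2))
    else:
        img[r0:r1, c0:c1] += intensity * np.exp(-((d / sigma) ** exponent))


def generate_tissue_image(spec: SyntheticTissueSpec) -> tuple[ImageStack, GroundTruth]:
    """Render the stack and its ground truth for one synthetic tissue."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size_px
    yy, xx = np.mgrid[0:n, 0:n]
    tc = spec.center
    footprint = np.hypot(yy - tc[0], xx - tc[1]) <= spec.tissue_radius_px

    base = np.where(footprint, spec.background_intensity, spec.outside_intensity).astype(np.float64)
    for r in spec.rosettes:
        _render_ring(base, r)
        a0 = np.asarray(r.center_px, dtype=np.float64)
        for k in range(r.n_tendrils):
            phi = r.tendril_angle_offset + 2.0 * math.pi * k / r.n_tendrils
            u = np.array([math.sin(phi), math.cos(phi)])
            _render_segment(
                base,
                a0 + r.tendril_start_px * u,
                a0 + (r.tendril_start_px + r.tendril_length) * u,
                r.tendril_intensity,
                r.tendril_width_px,
            )
    for f in spec.foci:
        _render_blob(base, f.center_px, f.blob_sigma_px, f.intensity, exponent=_FOCUS_EXPONENT)

    # nuclei: dense random blobs confined to the footprint
    nuc_base = np.where(footprint, 5.0, 0.0).astype(np.float64)
    n_nuclei = max(int(footprint.sum() / 900), 10)
    for _ in range(n_nuclei):
        while True:
            pos = tc + (rng.random(2) * 2 - 1) * spec.tissue_radius_px
            if np.hypot(pos[0] - tc[0], pos[1] - tc[1]) <= spec.tissue_radius_px - 4:
                break
        _render_blob(nuc_base, (pos[0], pos[1]), 3.0, float(rng.uniform(40, 120)))

    ncad_planes = np.empty((spec.n_planes, n, n), dtype=np.float64)
    nuc_planes = np.empty_like(ncad_planes)
    for z in range(spec.n_planes):
        for planes, src in ((ncad_planes, base), (nuc_planes, nuc_base)):
            plane = src * (1.0 + spec.plane_jitter * rng.standard_normal())
            if spec.noise_sigma > 0:
                plane = plane + rng.normal(0.0, spec.noise_sigma, src.shape)
            if spec.poisson:
                plane = rng.poisson(np.clip(plane, 0.0, None)).astype(np.float64)
            planes[z] = np.clip(plane, 0.0, None)

    stack = ImageStack(
        channels={"ncadherin": ncad_planes, "nuclei": nuc_planes},
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
    )
    px2 = spec.pixel_size_um**2
    structures = tuple(
        StructureTruth(kind, c, rad, s.nominal_area_px2 * px2)
        for kind, c, rad, s in spec._structures()
    )
    truth = GroundTruth(
        structures=structures,
        expected_category=categorize_tissue(
            sum(1 for s in structures if s.kind == ROSETTE),
            sum(1 for s in structures if s.kind == FOCUS),
        ),
    )
    return stack, truth


def random_tissue_spec(
    seed: int,
    n_rosettes: int,
    n_foci: int,
    noise: str = "clean",
    image_size_px: int = 1024,
    pixel_size_um: float = 0.5,
    tissue_diameter_um: float = 300.0,
    max_tries: int = 200,
) -> SyntheticTissueSpec:
    """Draw a valid random tissue spec with the requested structure counts.

    Ring radii are drawn from 15–20 µm and focus sigmas from 12–14 µm (so
    every structure comfortably clears the area exclusion); placement is
    rejection-sampled until the structures — tendril tips included — fit in
    the footprint without overlap. The default 300 µm tissue diameter is the
    morphology on which the focus-vs-rosette classifier is meant to be
    trained; pass 200 µm for the singular-rosette-optimal circles.
    """
    if noise not in NOISE_REGIMES:
        raise ValueError(f"unknown noise regime {noise!r}; choose from {sorted(NOISE_REGIMES)}")
    sigma, poisson = NOISE_REGIMES[noise]
    rng = np.random.default_rng(seed)
    tissue_radius = tissue_diameter_um / pixel_size_um / 2.0
    center = ((image_size_px - 1) / 2.0,) * 2

    for _ in range(max_tries):
        placed: list[tuple[tuple[float, float], float]] = []
        rosettes: list[RosetteSpec] = []
        foci: list[FocusSpec] = []
        ok = True
        for kind in [ROSETTE] * n_rosettes + [FOCUS] * n_foci:
            if kind == ROSETTE:
                ring_r = float(rng.uniform(15.0, 20.0)) / pixel_size_um
                width = float(rng.uniform(3.0, 5.0))
                proto = RosetteSpec(
                    center_px=(0.0, 0.0), ring_radius_px=ring_r, ring_width_px=width
                )
                nominal = proto.nominal_radius_px
                extent = proto.full_extent_px
            else:
                blob_sigma = float(rng.uniform(12.0, 14.0)) / pixel_size_um
                nominal = _FOCUS_HALF_MAX * blob_sigma
                extent = nominal
            pos = None
            for _ in range(400):
                ang = rng.uniform(0, 2 * math.pi)
                rad = (tissue_radius - extent - 4.0) * math.sqrt(rng.random())
                cand = (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
                # 1.8x the contact distance: blobs placed at bare contact
                # render as one connected structure, which would make the
                # drawn ground-truth count wrong, not the detector
                if all(
                    math.hypot(cand[0] - p[0], cand[1] - p[1]) >= 1.8 * (nominal + pr)
                    for p, pr in placed
                ):
                    pos = cand
                    break
            if pos is None:
                ok = False
                break
            placed.append((pos, nominal))
            if kind == ROSETTE:
                rosettes.append(
                    RosetteSpec(
                        center_px=pos,
                        ring_radius_px=ring_r,
                        ring_width_px=width,
                        tendril_angle_offset=float(rng.uniform(0, 2 * math.pi)),
                    )
                )
            else:
                foci.append(FocusSpec(center_px=pos, blob_sigma_px=blob_sigma))
        if not ok:
            continue
        spec = SyntheticTissueSpec(
            image_size_px=image_size_px,
            pixel_size_um=pixel_size_um,
            tissue_diameter_um=tissue_diameter_um,
            rosettes=tuple(rosettes),
            foci=tuple(foci),
            noise_sigma=sigma,
            poisson=poisson,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            spec.validate()
        except ValueError:
            continue
        return spec
    raise RuntimeError(
        f"could not place {n_rosettes} rosettes and {n_foci} foci in a "
        f"{tissue_diameter_um} um tissue after {max_tries} tries"
    )


def generate_descriptor_dataset(
    n_per_class: int,
    separation: float,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Two 8-D Gaussian classes with a known Bayes-optimal linear boundary.

    Class means sit at ±(separation/2)·u for a seed-drawn unit direction u
    with identity covariance, so the Bayes boundary is the hyperplane with
    normal u through the origin. Returns ``(X, labels, u)``.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(8)
    u /= np.linalg.norm(u)
    X0 = rng.standard_normal((n_per_class, 8)) - (separation / 2.0) * u
    X1 = rng.standard_normal((n_per_class, 8)) + (separation / 2.0) * u
    X = np.vstack([X0, X1])
    labels = [FOCUS] * n_per_class + [ROSETTE] * n_per_class
    return X, labels, u


def synthetic_training_set(
    n_per_class: int = 10,
    seed: int = 0,
    noise: str = "clean",
    image_size_px: int = 512,
    pixel_size_um: float = 0.5,
    tissue_diameter_um: float = 200.0,
    detection_cfg: DetectionConfig = DetectionConfig(),
    descriptor_cfg: DescriptorConfig = DescriptorConfig(),
):
    """Descriptor vectors with truth labels from single-structure fixtures.

    Generates ``n_per_class`` rosette-only and focus-only tissues, runs
    detection and descriptor extraction, and labels the detected region
    nearest each structure center with the structure's kind. Returns
    ``(vectors, labels)`` of the scorable matches, for classifier training.
    """
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for kind in (ROSETTE, FOCUS):
        for _ in range(n_per_class):
            sub = int(rng.integers(0, 2**31 - 1))
            spec = random_tissue_spec(
                sub,
                n_rosettes=1 if kind == ROSETTE else 0,
                n_foci=0 if kind == ROSETTE else 1,
                noise=noise,
                image_size_px=image_size_px,
                pixel_size_um=pixel_size_um,
                tissue_diameter_um=tissue_diameter_um,
            )
            stack, truth = generate_tissue_image(spec)
            max_proj = median_filter(project(stack, "ncadherin", "max"))
            mean_proj = median_filter(project(stack, "ncadherin", "mean"))
            regions = detect_mser_regions(max_proj, detection_cfg, pixel_size_um)
            regions = filter_regions_by_area(regions, detection_cfg.min_area_um2)
            regions = suppress_nested_regions(
                regions, detection_cfg.overlap_suppression_threshold
            )
            if not regions:
                continue
            target = np.asarray(truth.structures[0].center_px)
            best = min(
                regions,
                key=lambda r: float(np.linalg.norm(np.asarray(r.centroid_px) - target)),
            )
            vec = extract_descriptor_vector(max_proj, mean_proj, best, descriptor_cfg)
            if vec.scorable:
                vectors.append(vec)
                labels.append(kind)
    return vectors, labels
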