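import math

import numpy as np
import pytest

from rosettequant.descriptors import (
    DESCRIPTOR_NAMES,
    DescriptorConfig,
    TendrilSample,
    assess_halo,
    extract_descriptor_vector,
    place_tendril_samples,
    tendril_angle_incoherence,
    tendril_density,
)
from rosettequant.detection import _make_region

from conftest import make_disk_image


def disk_region(shape=(256, 256), center=(128, 128), radius=30):
    mask = make_disk_image(shape, centers=[center], radius=radius, fg=1, bg=0).astype(bool)
    return _make_region(np.argwhere(mask), shape, 1.0, 1)


def ridge_patch(direction, size=20, spacing=6, amplitude=100.0):
    """Straight parallel ridges along ``direction`` (radians)."""
    yy, xx = np.mgrid[0:size, 0:size]
    # signed distance to the family of lines with orientation `direction`
    d = (yy - size / 2) * math.cos(direction) - (xx - size / 2) * math.sin(direction)
    return amplitude * np.exp(-((d % spacing - spacing / 2) ** 2) / 2.0)


class TestHalo:
    def test_uniform_image_gives_unit_ratio(self):
        region = disk_region()
        halo = assess_halo(np.full((256, 256), 42.0), region, margin_px=5)
        assert halo.intensity_ratio == pytest.approx(1.0, abs=1e-12)

    def test_bright_disk_ratio_matches_plateau_ratio(self):
        img = make_disk_image((256, 256), centers=[(128, 128)], radius=30, fg=100, bg=10)
        halo = assess_halo(img, disk_region(), margin_px=5)
        assert halo.intensity_ratio == pytest.approx(10.0, rel=0.05)

    def test_ratio_invariant_under_intensity_scaling(self):
        img = make_disk_image((256, 256), centers=[(128, 128)], radius=30, fg=137, bg=11)
        r1 = assess_halo(img, disk_region(), 5).intensity_ratio
        r3 = assess_halo(img * 3.0, disk_region(), 5).intensity_ratio
        assert r3 == pytest.approx(r1, rel=1e-9)

    def test_region_on_border_without_annulus_is_flagged(self):
        # region fills the image: no room for an external annulus
        mask = np.ones((40, 40), dtype=bool)
        region = _make_region(np.argwhere(mask), (40, 40), 1.0, 1)
        halo = assess_halo(np.ones((40, 40)), region, 5)
        assert halo.intensity_ratio is None
        assert "empty_external_annulus" in halo.flags
        assert "touches_border" in halo.flags

    def test_zero_external_mean_reports_infinity(self):
        img = make_disk_image((256, 256), centers=[(128, 128)], radius=30, fg=50, bg=0)
        halo = assess_halo(img, disk_region(), 5)
        assert halo.intensity_ratio == math.inf
        assert "zero_external_mean" in halo.flags

    def test_other_regions_excluded_from_annulus(self):
        img = make_disk_image((256, 256), centers=[(128, 128)], radius=30, fg=100, bg=10)
        # a second bright blob right in the annulus would bias the ratio down
        img[128 - 3 : 128 + 3, 168 : 176] = 500.0
        other = np.zeros((256, 256), dtype=bool)
        other[128 - 3 : 128 + 3, 168 : 176] = True
        with_excl = assess_halo(img, disk_region(), 5, other_masks=other)
        without = assess_halo(img, disk_region(), 5)
        assert with_excl.intensity_ratio == pytest.approx(10.0, rel=0.05)
        assert without.intensity_ratio < with_excl.intensity_ratio


class TestSamplePlacement:
    def region_at(self, centroid, radius_px, shape=(1024, 1024)):
        from rosettequant.detection import PolarizationRegion

        return PolarizationRegion(
            pixels=np.array([[int(centroid[0]), int(centroid[1])]]),
            shape=shape,
            centroid_px=centroid,
            area_um2=1.0,
            major_axis_um=2 * radius_px,
            eccentricity=0.0,
            radius_px=radius_px,
        )

    def test_sample_at_angle_zero_lies_along_columns(self):
        cfg = DescriptorConfig(n_sample_angles=1)
        samples = place_tendril_samples(self.region_at((512, 512), 40.0), cfg, (1024, 1024))
        ring1 = [s for s in samples if s.ring_index == 1]
        assert ring1[0].center_px == (512, 572)  # 1.5 x 40 px along +col
        ring2 = [s for s in samples if s.ring_index == 2]
        assert ring2[0].center_px == (512, 592)  # 2 x 40 px along +col

    def test_four_angles_are_equally_spaced(self):
        cfg = DescriptorConfig(n_sample_angles=4)
        samples = place_tendril_samples(self.region_at((512, 512), 40.0), cfg, (1024, 1024))
        ring1 = sorted(s.center_px for s in samples if s.ring_index == 1)
        assert ring1 == sorted([(512, 572), (572, 512), (512, 452), (452, 512)])

    def test_edge_crossing_squares_are_dropped(self):
        cfg = DescriptorConfig(n_sample_angles=8)
        samples = place_tendril_samples(self.region_at((5, 128), 40.0), cfg, (256, 256))
        full = place_tendril_samples(self.region_at((128, 128), 40.0), cfg, (256, 256))
        assert 0 < len(samples) < len(full) == 16


class TestTendrilDensity:
    def patch(self, values):
        return TendrilSample((0, 0), 1, 0.0, np.asarray(values, dtype=float))

    def test_zero_full_and_half(self):
        assert tendril_density(self.patch(np.zeros((20, 20))), 100.0) == 0.0
        assert tendril_density(self.patch(np.full((20, 20), 100.0)), 100.0) == 1.0
        half = np.zeros((20, 20))
        half[:10] = 100.0
        assert tendril_density(self.patch(half), 100.0) == pytest.approx(0.5)

    def test_values_above_reference_clip_to_one(self):
        assert tendril_density(self.patch(np.full((20, 20), 900.0)), 100.0) == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            tendril_density(self.patch(np.ones((20, 20))), 0.0)


class TestTendrilIncoherence:
    def test_radial_ridges_score_near_zero(self):
        for theta in (0.0, math.pi / 4, 1.1):
            patch = ridge_patch(theta)
            sample = TendrilSample((0, 0), 1, theta, patch)
            assert tendril_angle_incoherence(sample) < 5.0

    def test_perpendicular_ridges_score_near_ninety(self):
        for theta in (0.0, math.pi / 3):
            patch = ridge_patch(theta + math.pi / 2)
            sample = TendrilSample((0, 0), 1, theta, patch)
            assert tendril_angle_incoherence(sample) > 85.0

    def test_isotropic_noise_averages_to_45_degrees(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(128):
            sample = TendrilSample((0, 0), 1, 0.3, rng.normal(0, 1, (20, 20)))
            a = tendril_angle_incoherence(sample)
            if a is not None:
                vals.append(a)
        assert len(vals) >= 64
        assert np.mean(vals) == pytest.approx(45.0, abs=5.0)

    def test_flat_patch_has_no_orientation(self):
        sample = TendrilSample((0, 0), 1, 0.0, np.full((20, 20), 3.0))
        assert tendril_angle_incoherence(sample) is None

    def test_result_always_within_axial_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sample = TendrilSample(
                (0, 0), 1, float(rng.uniform(0, 2 * math.pi)), rng.normal(0, 1, (20, 20))
            )
            a = tendril_angle_incoherence(sample)
            assert a is None or 0.0 <= a <= 90.0


@pytest.fixture(scope="module")
def fixture_pair():
    """Ideal (noise-free) single-rosette and single-focus tissues, processed
    through detection up to descriptor extraction."""
    from rosettequant.detection import (
        DetectionConfig,
        detect_mser_regions,
        filter_regions_by_area,
        suppress_nested_regions,
    )
    from rosettequant.image_io import median_filter, project
    from rosettequant.synthetic import generate_tissue_image, random_tissue_spec

    out = {}
    for kind, (nr, nf), seed in (("rosette", (1, 0), 11), ("focus", (0, 1), 12)):
        spec = random_tissue_spec(
            seed, nr, nf, noise="none", image_size_px=512, tissue_diameter_um=200.0
        )
        stack, _ = generate_tissue_image(spec)
        maxp = median_filter(project(stack, "ncadherin", "max"))
        meanp = median_filter(project(stack, "ncadherin", "mean"))
        regions = suppress_nested_regions(
            filter_regions_by_area(detect_mser_regions(maxp, DetectionConfig(), 0.5), 176.0),
            0.5,
        )
        assert len(regions) == 1
        out[kind] = (maxp, meanp, regions[0])
    return out


class TestDescriptorVector:
    def test_vector_has_eight_fields_in_fixed_order(self, fixture_pair):
        maxp, meanp, region = fixture_pair["rosette"]
        vec = extract_descriptor_vector(maxp, meanp, region)
        assert len(DESCRIPTOR_NAMES) == 8
        arr = vec.as_array()
        assert arr.shape == (8,)
        assert arr[0] == vec.area_um2 and arr[3] == vec.halo_intensity_ratio
        assert arr[7] == vec.tendril_angle_incoherence_2

    def test_ideal_rosette_signature(self, fixture_pair):
        maxp, meanp, region = fixture_pair["rosette"]
        vec = extract_descriptor_vector(maxp, meanp, region)
        assert vec.scorable
        assert vec.halo_intensity_ratio > 1.5
        assert vec.tendril_angle_incoherence_1 < 15.0
        assert vec.tendril_angle_incoherence_2 < 15.0

    def test_ideal_focus_contrasts_with_rosette(self, fixture_pair):
        rosette = extract_descriptor_vector(*fixture_pair["rosette"])
        focus = extract_descriptor_vector(*fixture_pair["focus"])
        assert focus.scorable
        assert focus.halo_intensity_ratio < rosette.halo_intensity_ratio
        assert focus.tendril_angle_incoherence_1 > rosette.tendril_angle_incoherence_1
        assert focus.tendril_angle_incoherence_2 > rosette.tendril_angle_incoherence_2
        assert focus.tendril_density_1 < rosette.tendril_density_1
        assert focus.tendril_density_2 < rosette.tendril_density_2

    def test_bounds_hold(self, fixture_pair):
        for kind in ("rosette", "focus"):
            vec = extract_descriptor_vector(*fixture_pair[kind])
            assert 0.0 <= vec.tendril_density_1 <= 1.0
            assert 0.0 <= vec.tendril_density_2 <= 1.0
            assert 0.0 <= vec.tendril_angle_incoherence_1 <= 90.0
            assert 0.0 <= vec.tendril_angle_incoherence_2 <= 90.0

    def test_halo_scale_invariance_through_extraction(self, fixture_pair):
        maxp, meanp, region = fixture_pair["rosette"]
        v1 = extract_descriptor_vector(maxp, meanp, region)
        v3 = extract_descriptor_vector(maxp, np.asarray(meanp.image) * 3.0, region)
        assert v3.halo_intensity_ratio == pytest.approx(v1.halo_intensity_ratio, rel=1e-9)

    def test_sampling_convergence_with_more_angles(self, fixture_pair):
        maxp, meanp, region = fixture_pair["rosette"]
        v16 = extract_descriptor_vector(maxp, meanp, region, DescriptorConfig(n_sample_angles=16))
        v32 = extract_descriptor_vector(maxp, meanp, region, DescriptorConfig(n_sample_angles=32))
        for name in ("tendril_density_1", "tendril_density_2"):
            assert getattr(v32, name) == pytest.approx(getattr(v16, name), rel=0.03)

    def test_descriptors_invariant_under_90_degree_rotation(self, fixture_pair):
        from rosettequant.detection import (
            DetectionConfig,
            detect_mser_regions,
            filter_regions_by_area,
            suppress_nested_regions,
        )

        maxp, meanp, region = fixture_pair["rosette"]
        v = extract_descriptor_vector(maxp, meanp, region)
        rot_max = np.rot90(np.asarray(maxp.image))
        rot_mean = np.rot90(np.asarray(meanp.image))
        regions = suppress_nested_regions(
            filter_regions_by_area(detect_mser_regions(rot_max, DetectionConfig(), 0.5), 176.0),
            0.5,
        )
        assert len(regions) == 1
        vr = extract_descriptor_vector(rot_max, rot_mean, regions[0])
        assert vr.area_um2 == v.area_um2
        assert vr.eccentricity == pytest.approx(v.eccentricity, abs=1e-12)
        assert vr.halo_intensity_ratio == pytest.approx(v.halo_intensity_ratio, rel=0.02)
        assert vr.tendril_density_1 == pytest.approx(v.tendril_density_1, rel=0.02)
        # incoherences sit near 0 degrees; 2% of the 90-degree scale
        assert vr.tendril_angle_incoherence_1 == pytest.approx(
            v.tendril_angle_incoherence_1, abs=1.8
        )
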