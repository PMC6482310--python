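"""Vessel quantification: projection, noise, denoising, binarisation, skeleton, PVD."""

import numpy as np
import pytest

from ocapdt.angiography import OCAVolume, reconstruct
from ocapdt.phantom import PhantomSpec, VesselSegment, generate_oct_volume
from ocapdt.quantify import (
    BinarizationParams,
    OCAImage,
    binarize,
    compute_pvd,
    denoise_tv,
    estimate_noise_sd,
    make_region_masks,
    project_mip,
    quantify_regions,
    skeletonize,
    subtract_background,
)

VOX = (0.02, 0.02, 0.02)


def img_of(data, pixel_size=0.02):
    return OCAImage(data=np.asarray(data, dtype=float), pixel_size=pixel_size)


class TestMIP:
    def test_single_bright_voxel(self):
        data = np.zeros((5, 8, 8))
        data[3, 2, 6] = 7.0
        img = project_mip(OCAVolume(data, VOX))
        assert img.data[2, 6] == 7.0
        assert img.data.sum() == 7.0

    def test_all_zero_volume(self):
        img = project_mip(OCAVolume(np.zeros((4, 6, 6)), VOX))
        assert not img.data.any()

    def test_matches_direct_max_oracle(self, rng):
        data = rng.uniform(size=(10, 12, 12))
        img = project_mip(OCAVolume(data, VOX), depth_range=(2, 9))
        expected = np.max(data[2:9], axis=0)  # independent per-column max
        np.testing.assert_array_equal(img.data, expected)

    def test_empty_depth_range_rejected(self):
        vol = OCAVolume(np.zeros((4, 6, 6)), VOX)
        with pytest.raises(ValueError, match="depth range"):
            project_mip(vol, depth_range=(3, 3))

    def test_non_square_pixels_rejected(self):
        vol = OCAVolume(np.zeros((4, 6, 6)), (0.02, 0.02, 0.03))
        with pytest.raises(ValueError, match="square"):
            project_mip(vol)


class TestNoiseSD:
    def test_gaussian_noise_recovered(self, rng):
        """Estimate within 10% of the true sigma on a flat Gaussian background."""
        sigma = 2.5
        img = img_of(rng.normal(20.0, sigma, size=(300, 300)))
        assert estimate_noise_sd(img) == pytest.approx(sigma, rel=0.10)

    def test_constant_image_gives_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            sd = estimate_noise_sd(img_of(np.full((10, 10), 4.0)))
        assert sd == 0.0
        assert "constant" in caplog.text.lower()

    def test_sparse_vessels_do_not_inflate_estimate(self, rng):
        """Bright vessels on <5% of pixels leave the background estimate within 15%."""
        sigma = 1.5
        data = rng.normal(10.0, sigma, size=(200, 200))
        data[::25, :] += 40.0  # 4% of rows are bright vessel pixels
        assert estimate_noise_sd(img_of(data)) == pytest.approx(sigma, rel=0.15)


class TestTVDenoise:
    def test_weight_zero_is_identity(self, rng):
        img = img_of(rng.uniform(size=(20, 20)))
        out = denoise_tv(img, 0.0)
        np.testing.assert_array_equal(out.data, img.data)

    def test_constant_image_unchanged(self):
        img = img_of(np.full((16, 16), 3.0))
        out = denoise_tv(img, 0.4)
        np.testing.assert_allclose(out.data, img.data, atol=1e-8)

    def test_total_variation_strictly_reduced(self, rng):
        step = np.zeros((32, 32))
        step[:, 16:] = 1.0
        noisy = np.clip(step + rng.normal(0, 0.2, step.shape), 0, None)
        out = denoise_tv(img_of(noisy), 0.2)

        def tv(x):  # direct anisotropic total variation
            return np.abs(np.diff(x, axis=0)).sum() + np.abs(np.diff(x, axis=1)).sum()

        assert tv(out.data) < tv(noisy)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            denoise_tv(img_of(np.ones((4, 4))), -0.1)


class TestBinarizeSkeletonize:
    def test_all_below_threshold_empty(self):
        img = img_of(np.full((8, 8), 0.5))
        assert not binarize(img, noise_sd=1.0).any()

    def test_zero_threshold_keeps_all_nonzero(self, rng):
        data = rng.uniform(size=(8, 8))
        data[0, 0] = 0.0
        mask = binarize(img_of(data), noise_sd=0.0)
        assert mask.sum() == 63

    def test_skeleton_of_bar_has_expected_length(self):
        bar = np.zeros((20, 60), dtype=bool)
        bar[8:13, 5:55] = True  # 5 px wide, 50 px long
        skel = skeletonize(bar)
        assert abs(int(skel.sum()) - 50) <= 2

    def test_skeleton_trivia(self):
        empty = np.zeros((10, 10), dtype=bool)
        assert not skeletonize(empty).any()
        single = np.zeros((10, 10), dtype=bool)
        single[4, 4] = True
        assert np.array_equal(skeletonize(single), single)

    def test_skeleton_preserves_component_count(self, rng):
        from skimage.measure import label

        mask = np.zeros((40, 40), dtype=bool)
        mask[5:10, 5:35] = True
        mask[25:35, 10:14] = True
        skel = skeletonize(mask)
        assert label(mask).max() == label(skel).max() == 2


class TestRegionMasks:
    def test_annulus_area_matches_analytic(self):
        """Disc r=1 mm, margin 2 mm, 0.1 mm pixels: annulus area ~ pi(3^2-1^2) mm^2."""
        yy, xx = np.meshgrid(np.arange(100), np.arange(100), indexing="ij")
        disc = (yy - 49.5) ** 2 + (xx - 49.5) ** 2 <= 10.0**2
        regions = make_region_masks(disc, margin_mm=2.0, pixel_size=0.1)
        area_mm2 = regions.peri_tumour.sum() * 0.1**2
        assert area_mm2 == pytest.approx(np.pi * (3.0**2 - 1.0**2), rel=0.05)
        assert not (regions.tumour & regions.peri_tumour).any()

    def test_empty_tumour_mask_warns(self, caplog):
        with caplog.at_level("WARNING"):
            regions = make_region_masks(np.zeros((20, 20), dtype=bool),
                                        margin_mm=0.5, pixel_size=0.1)
        assert not regions.peri_tumour.any()
        assert "empty" in caplog.text.lower()

    def test_edge_tumour_clipped_in_bounds(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[0:5, 0:5] = True
        regions = make_region_masks(mask, margin_mm=1.0, pixel_size=0.1)
        assert regions.peri_tumour.shape == (30, 30)
        assert regions.peri_tumour.any()

    def test_submpixel_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            make_region_masks(np.ones((10, 10), dtype=bool), margin_mm=0.05, pixel_size=0.1)


class TestPVD:
    def test_line_in_region_arithmetic(self):
        """A 100-pixel skeleton inside a 200x200 region is exactly 0.25%."""
        skel = np.zeros((200, 200), dtype=bool)
        skel[100, 50:150] = True
        region = np.ones((200, 200), dtype=bool)
        res = compute_pvd(skel, region)
        assert res.pvd_percent == 100.0 * 100 / 40000 == 0.25
        assert res.skeleton_pixel_count == 100

    def test_empty_and_full_skeletons(self):
        region = np.ones((10, 10), dtype=bool)
        assert compute_pvd(np.zeros((10, 10), dtype=bool), region).pvd_percent == 0.0
        assert compute_pvd(region, region).pvd_percent == 100.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_pvd(np.zeros((5, 5), dtype=bool), np.zeros((5, 5), dtype=bool))


@pytest.fixture(scope="module")
def phantom_mip(default_phantom):
    vol, truth = default_phantom
    oca = reconstruct(vol, motion_compensation=False)
    return project_mip(oca), truth


class TestPipelineProperties:
    def test_binarized_phantom_dice(self, phantom_mip):
        """Thresholded en-face image overlaps the projected vessel truth (Dice >= 0.7)."""
        img, truth = phantom_mip
        sd = estimate_noise_sd(img)
        den = denoise_tv(subtract_background(img), sd)
        mask = binarize(den, sd)
        dice = 2 * (mask & truth.mask2d).sum() / (mask.sum() + truth.mask2d.sum())
        assert dice >= 0.7

    def test_binary_masks_nested_in_multiplier(self, phantom_mip):
        """Raising the binarisation multiplier only ever removes pixels."""
        from ocapdt.quantify import denoise_tv, estimate_noise_sd, subtract_background

        img, _ = phantom_mip
        sd = estimate_noise_sd(img)
        den = denoise_tv(subtract_background(img), 5 * sd)
        prev = None
        for m in (1.0, 2.0, 3.0, 5.0, 8.0):
            mask = binarize(den, sd, BinarizationParams(m))
            if prev is not None:
                assert not (mask & ~prev).any()  # strict set inclusion
            prev = mask

    def test_pvd_monotone_in_multiplier(self, rng):
        """Raising the multiplier never increases PVD: dimmer vessels drop out first."""
        data = rng.normal(1.0, 0.2, size=(120, 120)).clip(0)
        for i, level in enumerate((2.0, 4.0, 8.0, 16.0)):  # graded vessel intensities
            data[20 + 25 * i, 10:110] += level  # 1-px-wide graded bars
        img = img_of(data)
        tumour = np.zeros_like(data, dtype=bool)
        tumour[:, :60] = True
        regions = make_region_masks_split(tumour)
        pvds = [
            quantify_regions(img, regions, params=BinarizationParams(m)).pvd_percent("tumour")
            for m in (1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 96.0)
        ]
        assert all(a >= b for a, b in zip(pvds, pvds[1:]))
        assert pvds[0] > 0 and pvds[-1] == 0.0

    def test_scale_invariance_of_pvd(self, phantom_mip):
        img, truth = phantom_mip
        regions = make_region_masks(truth.mask2d, margin_mm=0.3, pixel_size=img.pixel_size)
        r1 = quantify_regions(img, regions)
        scaled = OCAImage(37.0 * img.data, img.pixel_size)
        r2 = quantify_regions(scaled, regions)
        assert r1.pvd_percent("tumour") == pytest.approx(r2.pvd_percent("tumour"), abs=1e-9)
        assert r1.pvd_percent("peri-tumour") == pytest.approx(
            r2.pvd_percent("peri-tumour"), abs=1e-9
        )

    def test_region_exclusivity_and_additivity(self, phantom_mip):
        img, truth = phantom_mip
        regions = make_region_masks(truth.mask2d, margin_mm=0.3, pixel_size=img.pixel_size)
        from ocapdt.quantify import DEFAULT_TV_WEIGHT

        res = quantify_regions(img, regions)
        combined = regions.tumour | regions.peri_tumour
        sd = estimate_noise_sd(img)
        skel = skeletonize(
            binarize(denoise_tv(subtract_background(img), DEFAULT_TV_WEIGHT * sd), sd)
        )
        total = compute_pvd(skel, combined)
        assert (
            res.per_region["tumour"].skeleton_pixel_count
            + res.per_region["peri-tumour"].skeleton_pixel_count
            == total.skeleton_pixel_count
        )

    def test_pvd_tracks_ground_truth_density(self):
        """PVD correlates with true skeleton density across phantoms of varying vessel count."""
        measured, true_density = [], []
        for k in range(1, 11):
            # sparse parallel vessels so the background stays estimable
            tree = [
                VesselSegment((0.75, 0.2, 0.4 + 0.15 * j), (0.75, 2.2, 0.4 + 0.15 * j), 0.02)
                for j in range(k)
            ]
            vol, truth = generate_oct_volume(PhantomSpec(vessel_tree=tree, seed=k))
            img = project_mip(reconstruct(vol, motion_compensation=False))
            region = np.ones(img.data.shape, dtype=bool)
            res = quantify_regions(img, make_region_masks_full(region))
            measured.append(res.pvd_percent("tumour"))
            gt_skel = skeletonize(truth.mask2d)
            true_density.append(100.0 * gt_skel.sum() / gt_skel.size)
        r = np.corrcoef(measured, true_density)[0, 1]
        assert r >= 0.9


def make_region_masks_full(region):
    """Near-whole-field 'tumour' region with a one-pixel disjoint annulus placeholder."""
    from ocapdt.quantify import RegionMasks

    tumour = region.copy()
    peri = np.zeros_like(region)
    tumour[0, 0] = False
    peri[0, 0] = True
    return RegionMasks(tumour=tumour, peri_tumour=peri, margin_mm=0.1)


def make_region_masks_split(tumour):
    """Given-tumour mask with the complement as the second analysis region."""
    from ocapdt.quantify import RegionMasks

    return RegionMasks(tumour=tumour, peri_tumour=~tumour, margin_mm=0.1)
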