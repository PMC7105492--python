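"""Sholl counting against a brute-force oracle, radial-profile machinery,
branch excision, background estimation and volume-fraction recovery."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import circle_perimeter, disk

import gliaquant as gq
from gliaquant import morphometry as m


def sholl_oracle(mask: np.ndarray, cy: int, cx: int, r: int) -> int:
    """Brute force: connected components (8-connectivity) of the foreground
    pixels on the rasterized circle."""
    rr, cc = circle_perimeter(cy, cx, r, method="bresenham")
    ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    ring = np.zeros_like(mask)
    ring[rr[ok], cc[ok]] = mask[rr[ok], cc[ok]]
    return ndimage.label(ring, structure=np.ones((3, 3)))[1]


class TestShollProfile:
    def test_empty_mask_all_zero(self):
        mask = m.BinaryMask(np.zeros((100, 100), bool), 1.0)
        prof = m.sholl_profile(mask, (50.0, 50.0), np.arange(3.0, 40.0, 2.0))
        assert np.all(prof.intersections == 0)

    def test_six_radial_arms(self):
        # 6 straight arms: 6 intersections at every radius between soma and tip
        n = 400
        mask = np.zeros((n, n), bool)
        cy = cx = n // 2
        for ang in np.deg2rad([0, 60, 120, 180, 240, 300]):
            for t in np.linspace(0, 160, 2000):
                y = int(round(cy + t * np.sin(ang)))
                x = int(round(cx + t * np.cos(ang)))
                mask[max(y - 1, 0):y + 2, max(x - 1, 0):x + 2] = True
        prof = m.sholl_profile(mask, ((cx + 0.5), (cy + 0.5)),
                               np.arange(5.0, 155.0, 5.0), pixel_size_um=1.0)
        assert np.all(prof.intersections == 6)

    def test_solid_disk_connectivity(self):
        n = 200
        mask = np.zeros((n, n), bool)
        rr, cc = disk((100, 100), 40)
        mask[rr, cc] = True
        prof = m.sholl_profile(mask, (100.5, 100.5), np.array([10.0, 30.0, 60.0]),
                               pixel_size_um=1.0)
        assert list(prof.intersections) == [1.0, 1.0, 0.0]

    def test_radius_exceeding_frame_reported_missing(self):
        mask = np.ones((50, 50), bool)
        prof = m.sholl_profile(mask, (25.0, 25.0), np.array([10.0, 40.0]),
                               pixel_size_um=1.0)
        assert prof.intersections[0] == 1.0
        assert np.isnan(prof.intersections[1])

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        # the circle-walk run count must equal component counting on the ring
        for _ in range(120):
            n = int(rng.integers(32, 128))
            mask = ndimage.binary_dilation(
                rng.random((n, n)) > 0.9, iterations=int(rng.integers(0, 3)))
            cy, cx = (int(v) for v in rng.integers(8, n - 8, 2))
            rmax = min(cy, cx, n - 1 - cy, n - 1 - cx)
            radii = np.arange(2.0, rmax, 1.0)
            if radii.size == 0:
                continue
            prof = m.sholl_profile(mask, ((cx + 0.5), (cy + 0.5)), radii,
                                   pixel_size_um=1.0)
            expected = [sholl_oracle(mask, cy, cx, int(r)) for r in radii]
            assert list(prof.intersections) == expected


class TestPreprocessMask:
    def test_all_zero_stack_gives_empty_mask(self):
        mask = m.preprocess_mask(np.zeros((2, 64, 64)), pixel_size_um=0.25)
        assert not mask.mask.any()

    def test_identity_resampling_at_target_pixel_size(self):
        img = np.zeros((1, 64, 64))
        mask = m.preprocess_mask(img, pixel_size_um=0.25)
        assert mask.mask.shape == (64, 64)
        assert mask.provenance["resample_factor"] == pytest.approx(1.0)

    def test_resampling_to_quarter_micron(self):
        mask = m.preprocess_mask(np.zeros((1, 64, 64)), pixel_size_um=0.5)
        assert mask.mask.shape == (128, 128)

    def test_star_image_branch_recall(self, noiseless_astro_image):
        mask = m.preprocess_mask(noiseless_astro_image)
        branches = noiseless_astro_image.truth_masks["branches"]
        recall = (mask.mask & branches).sum() / branches.sum()
        assert recall >= 0.90

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.preprocess_mask(np.zeros((0, 10, 10)), pixel_size_um=0.25)


class TestRadialProfiles:
    def test_radially_symmetric_image_gives_identical_profiles(self):
        n = 200
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - 99.5, yy - 99.5)
        img = 100.0 * np.exp(-r / 40.0)
        profs = m.radial_profiles(img, 1.0, (100.0, 100.0))
        assert len(profs) == 8
        ref = profs[0].values
        for p in profs[1:]:
            assert np.allclose(p.values, ref, atol=0.5)

    def test_constant_image_constant_profiles(self):
        profs = m.radial_profiles(np.full((100, 100), 7.0), 1.0, (50.0, 50.0))
        for p in profs:
            assert np.allclose(p.values, 7.0)

    def test_profile_peaks_at_annotated_branch_crossing(self):
        img = gq.gen_astrocyte_image(gq.ImagingParams(leaflet_vf=0.03,
                                                      noise_sd=0.0, seed=12))
        t = img.ground_truth
        ang = t["branch_angles_rad"][0]
        profs = m.radial_profiles(img.plane(), img.pixel_size_um,
                                  tuple(t["soma_center_um"]), n_lines=1,
                                  angle0_deg=np.rad2deg(ang))
        p = profs[0]
        mid = (p.distances_um > 8) & (p.distances_um < t["branch_length_um"] - 2)
        assert p.values[mid].max() == pytest.approx(t["soma_peak"], rel=0.05)

    def test_center_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="center"):
            m.radial_profiles(np.zeros((50, 50)), 1.0, (200.0, 10.0))


class TestExciseBranches:
    def _profile(self, values):
        d = np.arange(len(values)) * 0.25
        return m.IntensityProfile(d, np.asarray(values, float),
                                  np.zeros(len(values), bool))

    def test_flat_profile_nothing_excised(self):
        p = self._profile(np.full(200, 5.0))
        out = m.excise_branches(p, f_max=100.0, f_0=0.0)
        assert not out.excised.any()

    def test_rectangular_bump_excised(self):
        vals = np.full(200, 10.0)
        vals[80:90] = 10.0 + 0.5 * 100.0  # half the dynamic range
        out = m.excise_branches(self._profile(vals), f_max=110.0, f_0=10.0)
        assert out.excised[80:90].all()
        assert not out.excised[:70].any() and not out.excised[100:].any()

    def test_subthreshold_bump_kept(self):
        vals = np.full(200, 10.0)
        vals[80:90] = 10.0 + 0.05 * 100.0  # 5% of the range: below threshold
        out = m.excise_branches(self._profile(vals), f_max=110.0, f_0=10.0)
        assert not out.excised.any()

    def test_external_baseline_catches_on_branch_line(self):
        # a line running along a branch is elevated everywhere; only the
        # cross-line reference baseline can flag it
        vals = np.full(200, 180.0)
        ref = np.full(200, 16.0)
        out = m.excise_branches(self._profile(vals), f_max=200.0, f_0=10.0,
                                baseline=ref)
        assert out.excised.all()


class TestBackground:
    def test_uniform_background_recovered(self):
        f0, _ = m.estimate_background(np.full((200, 200), 7.0), 0.25)
        assert f0 == pytest.approx(7.0)

    def test_automatic_circle_lands_in_annotated_dye_free_region(self):
        img = gq.gen_astrocyte_image(gq.ImagingParams(leaflet_vf=0.05,
                                                      noise_sd=0.0, seed=4))
        t = img.ground_truth
        arbor = t["arbor_radius_um"]
        cx, cy = t["soma_center_um"]
        f0, center = m.estimate_background(img.plane(), img.pixel_size_um)
        assert f0 == pytest.approx(t["background"], abs=1e-6)
        # the chosen circle lies outside the arbor, like the annotated one
        assert np.hypot(center[0] - cx, center[1] - cy) > arbor

    def test_fully_excluded_frame_rejected(self):
        with pytest.raises(ValueError, match="feasible"):
            m.estimate_background(np.zeros((100, 100)), 0.25,
                                  exclusion_mask=np.ones((100, 100), bool))


class TestEstimateVF:
    def _flat_profiles(self, level, n=8):
        d = np.arange(0, 140) * 0.25
        return [m.IntensityProfile(d, np.full(d.size, float(level)),
                                   np.zeros(d.size, bool)) for _ in range(n)]

    def test_background_level_gives_zero(self):
        res = m.estimate_vf(self._flat_profiles(10.0), f_max=200.0, f_0=10.0)
        assert res.mean_vf == pytest.approx(0.0)

    def test_soma_level_gives_one(self):
        res = m.estimate_vf(self._flat_profiles(200.0), f_max=200.0, f_0=10.0)
        assert res.mean_vf == pytest.approx(1.0)

    def test_fmax_not_above_f0_rejected(self):
        with pytest.raises(ValueError, match="F_max"):
            m.estimate_vf(self._flat_profiles(5.0), f_max=1.0, f_0=1.0)

    def test_noiseless_pipeline_recovers_ground_truth(self, noiseless_astro_image):
        res = m.leaflet_vf(noiseless_astro_image)
        assert res.mean_vf == pytest.approx(0.045, abs=0.002)

    def test_affine_intensity_invariance(self, noiseless_astro_image):
        # VF is a ratio of differences: gain/offset of the whole image cancel
        img = noiseless_astro_image
        res = m.leaflet_vf(img)
        scaled = gq.LabeledImage(img.data * 3.7 + 55.0, img.pixel_size_um,
                                 img.ground_truth, img.truth_masks)
        res2 = m.leaflet_vf(scaled)
        assert res2.mean_vf == pytest.approx(res.mean_vf, abs=1e-9)

    @pytest.mark.parametrize("vf_true", [0.01, 0.045, 0.10])
    def test_parameter_recovery_under_noise(self, vf_true):
        # noise at 5% of the soma peak: bias below 10% of the true vf
        est = []
        for seed in range(12):
            img = gq.gen_astrocyte_image(gq.ImagingParams(
                leaflet_vf=vf_true, noise_sd=10.0, seed=seed))
            est.append(m.leaflet_vf(img).mean_vf)
        assert abs(np.mean(est) - vf_true) < 0.1 * vf_true
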