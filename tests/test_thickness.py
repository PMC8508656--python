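"""Rim segmentation, perpendicular profiles, and Gaussian FWHM fitting."""

import numpy as np
import pytest

from laminq import (
    GAUSS_FWHM_FACTOR,
    LineProfile,
    OpticsConfig,
    SceneConfig,
    build_lamina_scene,
    expected_apparent_fwhm,
    fit_gaussian_profile,
    fwhm_to_sigma,
    measure_thickness,
    render_image,
    sample_profiles,
    segment_rim,
)


def make_profile(x, y, spacing):
    return LineProfile(distance=x, intensity=y, sample_spacing=spacing)


class TestGaussianFit:
    def test_pure_gaussian_sigma_100_gives_fwhm_235_48(self):
        x = np.arange(-500.0, 501.0, 10.0)
        y = 7.0 * np.exp(-(x**2) / (2 * 100.0**2))
        fit = fit_gaussian_profile(make_profile(x, y, 10.0))
        assert fit.converged
        assert fit.fwhm == pytest.approx(235.48, abs=0.01)

    def test_fwhm_sigma_ratio_is_exact_for_every_converged_fit(self):
        rng = np.random.default_rng(5)
        x = np.arange(-400.0, 401.0, 10.0)
        for sigma in (40.0, 90.0, 150.0):
            y = 10.0 * np.exp(-(x**2) / (2 * sigma**2)) + rng.normal(0, 0.1, x.size)
            fit = fit_gaussian_profile(make_profile(x, y, 10.0))
            assert fit.converged
            assert fit.fwhm / fit.sigma == pytest.approx(GAUSS_FWHM_FACTOR, rel=1e-12)

    def test_constant_profile_does_not_converge(self):
        x = np.arange(-100.0, 101.0, 10.0)
        fit = fit_gaussian_profile(make_profile(x, np.full_like(x, 3.0), 10.0))
        assert not fit.converged

    def test_two_sided_baseline_recovers_interior_signal(self):
        x = np.arange(-400.0, 401.0, 10.0)
        from scipy.special import ndtr

        y = 5.0 * np.exp(-(x**2) / (2 * 80.0**2)) + 2.0 + (0.5 - 2.0) * ndtr(x / 80.0)
        fit = fit_gaussian_profile(make_profile(x, y, 10.0))
        assert fit.converged
        assert fit.baseline_in == pytest.approx(2.0, abs=0.05)
        assert fit.baseline_out == pytest.approx(0.5, abs=0.05)
        assert fit.sigma == pytest.approx(80.0, rel=0.02)

    def test_tophat_convolved_with_psf_matches_numeric_oracle(self):
        """Fit on a 14 nm top-hat blurred to 60 nm vs brute-force convolution."""
        dx = 0.5
        grid = np.arange(-600.0, 600.0 + dx, dx)
        tophat = ((grid >= -7.0) & (grid <= 7.0)).astype(float)
        sigma = fwhm_to_sigma(60.0)
        kernel = np.exp(-(grid**2) / (2 * sigma**2))
        dense = np.convolve(tophat, kernel, mode="same")
        # independent half-maximum measurement on the dense profile
        half = dense.max() / 2.0
        above = np.where(dense >= half)[0]
        lo, hi = above[0], above[-1]
        left = lo - (dense[lo] - half) / (dense[lo] - dense[lo - 1])
        right = hi + (dense[hi] - half) / (dense[hi] - dense[hi + 1])
        oracle_fwhm = (right - left) * dx
        # fit on realistically spaced samples
        sel = slice(None, None, 20)  # 10 nm spacing
        fit = fit_gaussian_profile(make_profile(grid[sel], dense[sel], dx * 20))
        assert fit.converged
        assert fit.fwhm == pytest.approx(oracle_fwhm, rel=0.02)
        assert expected_apparent_fwhm(14.0, 60.0) == pytest.approx(oracle_fwhm, rel=0.01)


class TestSegmentation:
    def test_traced_boundary_close_to_true_rim(self, small_mid_gt, sted_noiseless_mid):
        rim = segment_rim(sted_noiseless_mid.plane(0))
        true_px = small_mid_gt.rim_polygon_px(sted_noiseless_mid.pixel_size)
        d = np.linalg.norm(
            rim.boundary_points[:, None, :] - true_px[None, :, :], axis=2
        ).min(axis=1)
        assert d.mean() < 1.0

    def test_blank_image_raises_no_nucleus(self):
        with pytest.raises(ValueError, match="no nucleus found"):
            segment_rim(np.zeros((64, 64)))

    def test_circle_normals_are_radial(self):
        cfg = SceneConfig(view="mid_plane", nucleus_semi_axes=(1.8, 1.8), margin_um=0.8)
        gt = build_lamina_scene(cfg, seed=0)
        stack = render_image(gt, OpticsConfig(modality="sted"), noiseless=True)
        rim = segment_rim(stack.plane(0))
        centre = rim.boundary_points.mean(axis=0)
        radial = rim.boundary_points - centre
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosang = np.einsum("ij,ij->i", radial, rim.outward_normals)
        angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert angles.max() < 3.0


class TestProfiles:
    def test_anchors_equally_spaced_in_arc_length(self, sted_noiseless_mid):
        rim = segment_rim(sted_noiseless_mid.plane(0))
        profiles = sample_profiles(
            sted_noiseless_mid.plane(0), rim, 30.0, n_positions=5, half_length_nm=200.0
        )
        anchors = np.array([p.anchor for p in profiles])
        # consecutive anchors subtend ~1/5 of the rim: check pairwise chord
        # lengths are similar (equal arc-length spacing on a smooth convex rim)
        chords = np.linalg.norm(np.diff(np.vstack([anchors, anchors[:1]]), axis=0), axis=1)
        assert chords.std() / chords.mean() < 0.35  # ellipse: arcs equal, chords vary mildly

    def test_constant_image_gives_constant_profiles(self, sted_noiseless_mid):
        rim = segment_rim(sted_noiseless_mid.plane(0))
        flat = np.full_like(sted_noiseless_mid.plane(0), 4.2)
        for prof in sample_profiles(flat, rim, 30.0, half_length_nm=200.0):
            np.testing.assert_allclose(prof.intensity, 4.2, rtol=1e-12)

    def test_profile_peak_within_half_psf_of_rim(self, sted_noiseless_mid):
        plane = sted_noiseless_mid.plane(0)
        rim = segment_rim(plane)
        for prof in sample_profiles(plane, rim, 30.0, half_length_nm=300.0):
            peak_at = prof.distance[np.argmax(prof.intensity)]
            assert abs(peak_at) <= 30.0  # PSF FWHM / 2

    def test_out_of_bounds_profile_is_flagged(self, sted_noiseless_mid):
        plane = sted_noiseless_mid.plane(0)
        rim = segment_rim(plane)
        profiles = sample_profiles(plane, rim, 30.0, half_length_nm=1e5)
        assert all(not p.in_bounds for p in profiles)


class TestMeasureThickness:
    def test_confocal_apparent_thickness_exceeds_sted(self, small_mid_gt):
        means = {}
        for modality, psf in (("confocal", 241.0), ("sted", 60.0)):
            stack = render_image(small_mid_gt, OpticsConfig(modality=modality), noiseless=True)
            means[modality] = measure_thickness(stack.plane(0), 30.0, psf_fwhm_nm=psf).mean
        assert means["confocal"] > means["sted"]

    def test_measured_fwhm_monotone_in_psf_width(self, small_mid_gt):
        vals = []
        for fwhm in (60.0, 120.0, 241.0):
            stack = render_image(
                small_mid_gt,
                OpticsConfig(modality="sted", psf_fwhm_lateral=fwhm),
                noiseless=True,
            )
            vals.append(measure_thickness(stack.plane(0), 30.0, psf_fwhm_nm=fwhm).mean)
        assert vals[0] < vals[1] < vals[2]

    def test_broadening_quadrature_closed_form(self):
        """Gaussian rim sigma_t imaged with PSF sigma_p fits sqrt(sum of squares).

        Rendered on a fine 10 nm detector so that digitization is negligible
        relative to the 2% tolerance of the closed form.
        """
        for sigma_t, psf_fwhm in ((30.0, 100.0), (60.0, 150.0)):
            cfg = SceneConfig(
                view="mid_plane", nucleus_semi_axes=(1.6, 1.2), margin_um=0.8,
                rim_sigma_nm=sigma_t, supersample_nm=2.5, nucleoplasm_level=0.0,
            )
            gt = build_lamina_scene(cfg, seed=0)
            optics = OpticsConfig(
                modality="sted", psf_fwhm_lateral=psf_fwhm, pixel_size=10.0, z_slices=1
            )
            stack = render_image(gt, optics, noiseless=True)
            res = measure_thickness(stack.plane(0), 10.0, psf_fwhm_nm=psf_fwhm)
            expected = np.hypot(sigma_t, fwhm_to_sigma(psf_fwhm)) * GAUSS_FWHM_FACTOR
            assert res.mean == pytest.approx(expected, rel=0.02)

    def test_sub_resolution_thickness_reports_psf_width(self, sted_noiseless_mid):
        res = measure_thickness(sted_noiseless_mid.plane(0), 30.0, psf_fwhm_nm=60.0)
        assert res.mean == pytest.approx(expected_apparent_fwhm(14.0, 60.0), rel=0.05)
        assert res.mean == pytest.approx(60.0, rel=0.10)

    def test_noisy_replicate_stability(self, small_mid_gt):
        means = []
        for seed in range(10):
            stack = render_image(small_mid_gt, OpticsConfig(modality="sted", seed=seed))
            means.append(measure_thickness(stack.plane(0), 30.0, psf_fwhm_nm=60.0).mean)
        means = np.array(means)
        assert means.std() / means.mean() < 0.10

    def test_bookkeeping_counts_unused_positions(self, sted_noiseless_mid):
        res = measure_thickness(
            sted_noiseless_mid.plane(0), 30.0, psf_fwhm_nm=60.0, n_positions=5
        )
        assert res.n_used <= res.n_attempted == 5
        assert len(res.per_position_fwhm) == res.n_used
        if res.n_used > 1:
            assert res.sd == pytest.approx(np.std(res.per_position_fwhm, ddof=1))

    def test_identical_positions_have_zero_sd(self):
        x = np.arange(-300.0, 301.0, 10.0)
        y = np.exp(-(x**2) / (2 * 50.0**2))
        fits = [fit_gaussian_profile(make_profile(x, y, 10.0)) for _ in range(5)]
        fwhms = [f.fwhm for f in fits]
        assert np.std(fwhms) == 0.0
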