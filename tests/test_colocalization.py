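"""Pearson coefficient, Costes automatic thresholds, and dual-channel profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminq import (
    CostesError,
    OpticsConfig,
    coloc_report,
    costes_thresholds,
    dual_profile,
    pearson,
    render_image,
)


class TestPearson:
    def test_identical_channels_give_unity(self):
        rng = np.random.default_rng(0)
        ch = rng.random((16, 16))
        assert pearson(ch, ch) == pytest.approx(1.0)

    def test_inverted_channel_gives_minus_one(self):
        rng = np.random.default_rng(1)
        ch = rng.random((16, 16))
        assert pearson(ch, 2.0 - ch) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "ch2, expected",
        [([2.0, 4.0, 6.0, 8.0], 1.0), ([1.0, 3.0, 2.0, 4.0], 0.8)],
    )
    def test_four_pixel_toy_values(self, ch2, expected):
        ch1 = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(ch1, np.array(ch2)) == pytest.approx(expected)

    def test_constant_channel_raises(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            pearson(np.ones((4, 4)), np.arange(16.0).reshape(4, 4))

    @settings(derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 1000),
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-10.0, 10.0),
    )
    def test_affine_invariance_and_symmetry(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        a, b = rng.random(40), rng.random(40)
        r = pearson(a, b)
        assert -1.0 <= r <= 1.0
        assert pearson(scale * a + shift, b) == pytest.approx(r, abs=1e-9)
        assert pearson(b, a) == pytest.approx(r, abs=1e-12)


class TestCostes:
    def test_exact_linear_relation_recovers_slope_two(self):
        rng = np.random.default_rng(2)
        ch1 = rng.random((32, 32)) * 50.0
        t1, t2, a, b = costes_thresholds(ch1, 2.0 * ch1)
        assert a == pytest.approx(2.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-7)
        assert t2 == pytest.approx(a * t1 + b)

    def test_anti_correlated_channels_raise(self):
        rng = np.random.default_rng(3)
        ch1 = rng.random((16, 16))
        with pytest.raises(CostesError, match="slope"):
            costes_thresholds(ch1, 5.0 - ch1)

    def test_threshold_separates_foreground_from_background(self):
        """Shared 100-count foreground on uncorrelated Gaussian background."""
        rng = np.random.default_rng(4)
        fg = np.zeros((64, 64), dtype=bool)
        fg[20:44, 20:44] = True
        ch1 = rng.normal(10.0, 2.0, fg.shape)
        ch2 = rng.normal(10.0, 2.0, fg.shape)
        ch1[fg] = 100.0 + rng.normal(0, 2.0, fg.sum())
        ch2[fg] = 100.0 + rng.normal(0, 2.0, fg.sum())
        t1, t2, a, b = costes_thresholds(ch1, ch2)
        assert 20.0 < t1 <= 100.0 + 10.0
        assert 20.0 < t2 <= 100.0 + 10.0

    def test_matches_brute_force_threshold_sweep(self):
        """Same (T1, T2) as a literal descending sweep re-testing the criterion."""
        rng = np.random.default_rng(5)
        base = rng.gamma(2.0, 10.0, (24, 24))
        ch1 = base + rng.normal(0, 2.0, base.shape)
        ch2 = 1.5 * base + rng.normal(0, 2.0, base.shape)
        ch1 -= ch1.min()
        ch2 -= ch2.min()
        t1, t2, a, b = costes_thresholds(ch1, ch2)

        # brute force: recompute the below-set Pearson at every candidate
        expected_t1 = None
        for cand in np.unique(ch1)[::-1]:
            cand_t2 = a * cand + b
            mask = (ch1 < cand) & (ch2 < cand_t2)
            if mask.sum() < 2:
                expected_t1 = cand
                break
            x, y = ch1[mask], ch2[mask]
            if x.std() == 0 or y.std() == 0:
                expected_t1 = cand
                break
            if np.corrcoef(x, y)[0, 1] <= 0:
                expected_t1 = cand
                break
        assert expected_t1 is not None
        assert t1 == pytest.approx(expected_t1)

    def test_below_set_contract_on_simulated_image(self, top_scene_factory):
        _, gt = top_scene_factory(rho=0.5, seed=2)
        stack = render_image(gt, OpticsConfig(modality="sted", seed=9))
        ch1, ch2 = stack.plane(0), stack.plane(1)
        t1, t2, a, b = costes_thresholds(ch1, ch2)
        assert t2 == pytest.approx(a * t1 + b, rel=1e-12)
        below = (ch1 < t1) & (ch2 < t2)
        if below.sum() >= 2 and ch1[below].std() > 0 and ch2[below].std() > 0:
            assert np.corrcoef(ch1[below], ch2[below])[0, 1] <= 1e-9


class TestColocReport:
    def test_perfect_overlap_noiseless_is_unity(self, top_scene_factory):
        _, gt = top_scene_factory(rho=1.0, seed=0)
        stack = render_image(gt, OpticsConfig(modality="sted"), noiseless=True)
        rep = coloc_report(stack.plane(0), stack.plane(1))
        assert rep.pearson_coloc == pytest.approx(1.0, abs=1e-6)
        assert rep.pearson_global == pytest.approx(1.0, abs=1e-6)

    def test_strictly_increasing_in_shared_fraction(self, top_scene_factory):
        for seed in range(4):
            vals = []
            for rho in (0.0, 0.5, 1.0):
                _, gt = top_scene_factory(rho=rho, seed=seed)
                stack = render_image(gt, OpticsConfig(modality="sted", seed=100 + seed))
                vals.append(coloc_report(stack.plane(0), stack.plane(1)).pearson_coloc)
            assert vals[0] < vals[1] < vals[2]

    def test_confocal_reports_higher_colocalization_than_sted(self, top_scene_factory):
        for seed in range(4):
            _, gt = top_scene_factory(rho=0.5, seed=seed)
            reps = {}
            for modality in ("confocal", "sted"):
                stack = render_image(gt, OpticsConfig(modality=modality, seed=200 + seed))
                reps[modality] = coloc_report(stack.plane(0), stack.plane(1)).pearson_coloc
            assert reps["confocal"] >= reps["sted"]

    def test_radial_offset_lowers_sted_colocalization(self, top_scene_factory):
        gaps = []
        for seed in range(6):
            vals = {}
            for offset in (0.0, 20.0):
                _, gt = top_scene_factory(rho=0.8, seed=seed, radial_offset=offset)
                stack = render_image(gt, OpticsConfig(modality="sted", seed=300 + seed))
                vals[offset] = coloc_report(stack.plane(0), stack.plane(1)).pearson_coloc
            gaps.append(vals[0.0] - vals[20.0])
        assert np.mean(gaps) > 0  # trend over seeds


class TestDualProfile:
    def test_identical_channels_give_identical_traces(self, top_scene_factory):
        _, gt = top_scene_factory(rho=1.0, seed=1)
        stack = render_image(gt, OpticsConfig(modality="sted"), noiseless=True)
        ny, nx = stack.plane(0).shape
        prof = dual_profile(stack, (ny // 2, 2), (ny // 2, nx - 3))
        np.testing.assert_allclose(prof.intensity_ch1, prof.intensity_ch2)

    def test_traces_normalized_to_unit_maximum(self, top_scene_factory):
        _, gt = top_scene_factory(rho=0.5, seed=1)
        stack = render_image(gt, OpticsConfig(modality="sted", seed=5))
        ny, nx = stack.plane(0).shape
        prof = dual_profile(stack, (ny // 2, 2), (ny // 2, nx - 3))
        assert prof.intensity_ch1.max() == pytest.approx(1.0)
        assert prof.intensity_ch2.max() == pytest.approx(1.0)

    def test_partially_shared_networks_show_segregated_zones(self, top_scene_factory):
        _, gt = top_scene_factory(rho=0.5, seed=3)
        stack = render_image(gt, OpticsConfig(modality="sted"), noiseless=True)
        ny, nx = stack.plane(0).shape
        prof = dual_profile(stack, (ny // 2, 2), (ny // 2, nx - 3))
        one_high = (prof.intensity_ch1 > 0.5) ^ (prof.intensity_ch2 > 0.5)
        assert one_high.sum() > 0

    def test_zero_channel_raises(self, top_scene_factory):
        _, gt = top_scene_factory(rho=1.0, seed=1)
        stack = render_image(gt, OpticsConfig(modality="sted"), noiseless=True)
        stack.pixels[1] = 0.0
        with pytest.raises(ValueError, match="zero maximum"):
            dual_profile(stack, (5, 5), (5, 30))
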