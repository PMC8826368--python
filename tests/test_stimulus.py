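"""Checkerboard synthesis, edge blending and trial scheduling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

from hemovis import (
    CheckerboardSpec,
    StimFrame,
    ViewingGeometry,
    auto_canny_mask,
    blend_frame,
    build_block_schedule,
    make_checkerboard,
    reversal_times,
    scale_contrast,
    to_isoluminant_gray,
)
from hemovis.errors import DegenerateInputError, ParameterError


class TestCheckerboard:
    def test_zero_contrast_is_uniform_mock(self, geom):
        frame = make_checkerboard(geom, CheckerboardSpec(contrast=0.0))
        assert np.allclose(frame.luminance, geom.mean_luminance_norm)

    def test_two_levels_symmetric_about_mean(self, geom):
        frame = make_checkerboard(geom, CheckerboardSpec(contrast=0.9))
        levels = np.unique(frame.luminance)
        assert levels.tolist() == pytest.approx([0.05, 0.95])
        assert levels.mean() == pytest.approx(geom.mean_luminance_norm)

    def test_phase_inversion_sums_to_twice_mean(self, geom):
        f0 = make_checkerboard(geom, CheckerboardSpec(phase=0))
        f1 = make_checkerboard(geom, CheckerboardSpec(phase=1))
        assert np.allclose(f0.luminance + f1.luminance,
                           2 * geom.mean_luminance_norm)

    def test_phase_inversion_is_involution(self, geom):
        f0 = make_checkerboard(geom, CheckerboardSpec(phase=0))
        f1 = make_checkerboard(geom, CheckerboardSpec(phase=1))
        # inverting the inverted frame reproduces the original
        assert np.allclose(2 * f1.mean_level - f1.luminance, f0.luminance,
                           atol=1e-12)

    def test_radial_period_matches_geometry(self):
        # odd resolution puts the pattern center on a pixel center
        geom = ViewingGeometry(screen_width_px=801, screen_height_px=601)
        spec = CheckerboardSpec(spatial_freq_cpd=0.33)
        frame = make_checkerboard(geom, spec)
        row = frame.luminance[300, 400:]
        crossings = np.flatnonzero(np.diff(np.sign(row - frame.mean_level)))
        half_periods = np.diff(crossings)
        expected = geom.pixels_per_degree / spec.spatial_freq_cpd / 2
        assert abs(np.median(half_periods) - expected) <= 1.0

    def test_invalid_spatial_frequency_rejected(self):
        with pytest.raises(ParameterError):
            CheckerboardSpec(spatial_freq_cpd=0.0)


class TestReversalTimes:
    @pytest.mark.parametrize("rate,duration,n", [
        (4.0, 5.0, 20), (4.0, 0.25, 1), (0.0, 5.0, 0), (2.0, 3.0, 6),
    ])
    def test_event_counts(self, rate, duration, n):
        times = reversal_times(CheckerboardSpec(reversal_rate_hz=rate), duration)
        assert len(times) == n
        if n > 1:
            assert np.allclose(np.diff(times), 1.0 / rate)


class TestIsoluminantGray:
    def test_white_frame_maps_to_mean_level(self, geom):
        out = to_isoluminant_gray(np.ones((10, 12, 3)), geom)
        assert np.allclose(out.luminance, geom.mean_luminance_norm)

    def test_mean_normalization_contract(self, geom):
        rng = np.random.default_rng(0)
        out = to_isoluminant_gray(rng.uniform(0.1, 0.9, (20, 30, 3)), geom)
        assert out.luminance.mean() == pytest.approx(
            geom.mean_luminance_norm, abs=1e-9)

    def test_global_gain_invariance(self, geom):
        rng = np.random.default_rng(1)
        rgb = rng.uniform(0.2, 0.9, (15, 15, 3))
        a = to_isoluminant_gray(rgb, geom)
        b = to_isoluminant_gray(0.5 * rgb, geom)
        assert np.allclose(a.luminance, b.luminance)

    def test_all_black_frame_rejected(self, geom):
        with pytest.raises(DegenerateInputError):
            to_isoluminant_gray(np.zeros((5, 5, 3)), geom)


class TestScaleContrast:
    def test_extremes(self):
        frame = StimFrame(np.array([[0.2, 0.8]]), 0.5)
        assert np.allclose(scale_contrast(frame, 0.0).luminance, 0.5)
        assert np.allclose(scale_contrast(frame, 1.0).luminance,
                           frame.luminance)

    @pytest.mark.parametrize("c", [0.2, 0.4, 0.8])
    def test_rms_contrast_scales_linearly(self, c):
        rng = np.random.default_rng(2)
        frame = StimFrame(rng.uniform(0, 1, (30, 30)), 0.5)
        rms_in = np.sqrt(((frame.luminance - 0.5) ** 2).mean())
        out = scale_contrast(frame, c)
        rms_out = np.sqrt(((out.luminance - 0.5) ** 2).mean())
        assert rms_out == pytest.approx(c * rms_in, rel=1e-12)

    @given(a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_multiplicative_composition(self, a, b):
        frame = StimFrame(np.linspace(0, 1, 64).reshape(8, 8), 0.5)
        once = scale_contrast(frame, min(a * b, 1.0))
        twice = scale_contrast(scale_contrast(frame, a), b)
        assert np.allclose(once.luminance, twice.luminance, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            scale_contrast(StimFrame(np.zeros((2, 2)), 0.5), 1.5)


class TestAutoCanny:
    def test_uniform_frame_gives_empty_mask(self):
        assert not auto_canny_mask(StimFrame(np.full((20, 20), 0.5), 0.5)).any()

    def test_step_edge_localized_within_two_px(self):
        lum = np.concatenate([np.zeros((50, 25)), np.ones((50, 25))], axis=1)
        mask = auto_canny_mask(StimFrame(lum, 0.5))
        cols = np.flatnonzero(mask.any(axis=0))
        assert mask.any()
        assert cols.min() >= 23 and cols.max() <= 26

    def test_mask_is_binary(self):
        rng = np.random.default_rng(3)
        mask = auto_canny_mask(StimFrame(rng.uniform(0, 1, (30, 30)), 0.5))
        assert mask.dtype == bool


class TestBlendFrame:
    @pytest.fixture
    def checker(self):
        geom = ViewingGeometry(screen_width_px=60, screen_height_px=60)
        return make_checkerboard(geom, CheckerboardSpec())

    def test_uniform_cartoon_leaves_checkerboard(self, checker):
        cartoon = StimFrame(np.full((60, 60), 0.5), 0.5)
        out = blend_frame(cartoon, checker)
        assert np.array_equal(out.luminance, checker.luminance)

    def test_edge_pixels_are_inverted_check_levels(self, checker):
        lum = np.where(np.arange(60)[None, :] < 30, 0.3, 0.7) * np.ones((60, 1))
        cartoon = StimFrame(lum, 0.5)
        mask = auto_canny_mask(cartoon)
        out = blend_frame(cartoon, checker)
        # inversion contract: full check excursion at every edge pixel
        excursion = 2 * checker.mean_level * 0.9
        assert np.allclose(
            np.abs(out.luminance - checker.luminance)[mask], excursion)
        # pixel-count oracle: non-edge pixels match the raw checkerboard
        frac_equal = (out.luminance == checker.luminance).mean()
        assert frac_equal == pytest.approx(1.0 - mask.mean())
        # output never leaves the two checkerboard levels
        levels = np.unique(checker.luminance)
        dist = np.min(np.abs(out.luminance[..., None] - levels[None, None, :]),
                      axis=-1)
        assert dist.max() < 1e-12

    def test_dimension_mismatch_rejected(self, checker):
        with pytest.raises(ParameterError):
            blend_frame(StimFrame(np.full((10, 10), 0.5), 0.5), checker)


class TestBlockSchedule:
    def test_default_protocol_duration(self):
        sched = build_block_schedule(20, 20, 5.0, 10.0, seed=0)
        assert sched.n_trials == 40
        assert sched.total_duration_s == pytest.approx(600.0)
        assert sched.count("S") == 20 and sched.count("B") == 20

    def test_single_trial(self):
        sched = build_block_schedule(1, 0, 5.0, 10.0, seed=7)
        assert sched.trials == [(0.0, "S")]

    def test_seed_determinism(self):
        a = build_block_schedule(20, 20, 5.0, 10.0, seed=42)
        b = build_block_schedule(20, 20, 5.0, 10.0, seed=42)
        assert a.trials == b.trials

    def test_position_distribution_uniform(self):
        # chi-square goodness of fit of per-position S frequencies to 1/2
        n_draws = 400
        draws = np.array([
            [c == "S" for _, c in build_block_schedule(20, 20, 5, 10, s).trials]
            for s in range(n_draws)
        ])
        counts = draws.sum(axis=0)
        chi2 = ((counts - n_draws / 2) ** 2 / (n_draws / 4)).sum()
        p = 1.0 - chi2_dist.cdf(chi2, df=40)
        assert p > 0.01

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_schedule_invariants(self, seed):
        sched = build_block_schedule(20, 20, 5.0, 10.0, seed=seed)
        sched.validate()  # strictly increasing, exact spacing, labels
        onsets = sched.onsets()
        assert np.allclose(np.diff(onsets), 15.0)
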