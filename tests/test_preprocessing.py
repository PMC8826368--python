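"""Optical density, pruning, motion correction, filtering and MBLL."""

import numpy as np
import pytest
from scipy import signal as sg

from hemovis import (
    PipelineConfig,
    Recording,
    bandpass,
    detect_motion,
    intensity_to_od,
    mbll,
    prune_channels,
    spline_correct,
    wavelet_correct,
)
from hemovis.errors import ParameterError, ValidationError
from hemovis.preprocessing import (
    ArtifactMask,
    OpticalDensity,
    forward_mbll,
    preprocess_recording,
    wavelet_correct_targeted,
)

from conftest import FS, od_from_series


def _time(duration_s: float) -> np.ndarray:
    return np.arange(0, duration_s, 1 / FS)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self, small_montage):
        rec = Recording(np.full((4, 2, 50), 0.1), FS, small_montage)
        assert np.allclose(intensity_to_od(rec).od, 0.0)

    def test_log_inverse_identity(self, small_montage):
        rng = np.random.default_rng(0)
        x = 0.01 * rng.standard_normal((4, 2, 200))
        x -= x.mean(axis=2, keepdims=True)
        ibar = 0.08
        intensity = ibar * np.exp(-x)
        rec = Recording(intensity, FS, small_montage)
        od = intensity_to_od(rec).od
        # od recovers x up to a constant offset (the log of the mean ratio)
        assert np.allclose(od - od.mean(axis=2, keepdims=True),
                           x - x.mean(axis=2, keepdims=True), atol=1e-12)

    def test_gain_invariance(self, small_montage):
        rng = np.random.default_rng(1)
        intensity = rng.uniform(0.05, 0.15, (4, 2, 100))
        rec1 = Recording(intensity, FS, small_montage)
        rec2 = Recording(2.0 * intensity, FS, small_montage)
        assert np.allclose(intensity_to_od(rec1).od, intensity_to_od(rec2).od)


class TestPruneChannels:
    def _rec(self, small_montage, mean, sd):
        rng = np.random.default_rng(2)
        base = np.clip(rng.normal(mean, sd, (1, 2, 500)), 1e-6, None)
        rest = rng.uniform(0.05, 0.1, (3, 2, 500))
        return Recording(np.concatenate([base, rest]), FS, small_montage)

    def test_intensity_above_drange_pruned(self, small_montage, pipeline_cfg):
        keep = prune_channels(self._rec(small_montage, 2.0, 0.001), pipeline_cfg)
        assert not keep[0] and keep[1:].all()

    def test_low_snr_pruned(self, small_montage, pipeline_cfg):
        keep = prune_channels(self._rec(small_montage, 0.1, 0.1), pipeline_cfg)
        assert not keep[0]

    def test_clean_channel_kept(self, small_montage, pipeline_cfg):
        keep = prune_channels(self._rec(small_montage, 0.1, 0.001), pipeline_cfg)
        assert keep.all()

    def test_separation_range_enforced(self, small_montage):
        cfg = PipelineConfig(sd_range_mm=(0.0, 25.0))  # montage is 30/35 mm
        rec = self._rec(small_montage, 0.1, 0.001)
        assert not prune_channels(rec, cfg).any()


class TestDetectMotion:
    def test_subthreshold_sinusoid_unflagged(self, pipeline_cfg):
        x = 0.01 * np.sin(2 * np.pi * 0.1 * _time(300))
        assert not detect_motion(od_from_series(x), pipeline_cfg).mask.any()

    def test_step_flagged_and_dilated(self, pipeline_cfg):
        rng = np.random.default_rng(3)
        t = _time(300)
        x = 0.002 * rng.standard_normal(t.size)
        i_step = np.searchsorted(t, 150.0)
        x[i_step:] += 1.0
        mask = detect_motion(od_from_series(x), pipeline_cfg).mask[0]
        idx = np.flatnonzero(mask)
        pad = int(round(pipeline_cfg.t_mask_s * FS))
        assert mask[i_step]
        assert idx.min() <= i_step - pad and idx.max() >= i_step + pad

    def test_spike_sensitivity_and_false_flags(self, pipeline_cfg):
        rng = np.random.default_rng(4)
        t = _time(600)
        x = 0.005 * rng.standard_normal(t.size)
        spikes = rng.choice(np.arange(100, t.size - 100), 20, replace=False)
        x[spikes] += 0.5
        mask = detect_motion(od_from_series(x), pipeline_cfg).mask[0]
        assert mask[spikes].mean() >= 0.95
        # false flags: flagged samples outside any spike +- t_mask window
        near = np.zeros(t.size, bool)
        pad = int(round(pipeline_cfg.t_mask_s * FS)) + 1
        for s in spikes:
            near[max(0, s - pad):s + pad + 1] = True
        assert mask[~near].mean() <= 0.05


class TestSplineCorrect:
    def test_empty_mask_is_identity(self, pipeline_cfg):
        x = 0.01 * np.sin(2 * np.pi * 0.05 * _time(100))
        od = od_from_series(x)
        mask = ArtifactMask(np.zeros((1, x.size), bool))
        assert np.array_equal(spline_correct(od, mask, pipeline_cfg).od, od.od)

    def test_baseline_shift_removed(self, pipeline_cfg):
        t = _time(300)
        x = 0.001 * np.sin(2 * np.pi * 0.05 * t)
        i = np.searchsorted(t, 150.0)
        x[i:] += 0.5
        m = np.zeros((1, t.size), bool)
        m[0, i - 10:i + 30] = True
        out = spline_correct(od_from_series(x), ArtifactMask(m),
                             pipeline_cfg).od[0, 0]
        # level discontinuity across the shift, relative to the 0.5 OD jump
        jump = abs(out[i:i + 20].mean() - out[i - 20:i].mean())
        assert jump < 0.05 * 0.5

    def test_response_outside_segments_preserved(self, pipeline_cfg):
        from hemovis.simulate import SimConfig, response_kernel

        t = _time(300)
        kernel = response_kernel(SimConfig())
        x = np.zeros(t.size)
        x[500:500 + kernel.size] += 3e-3 * kernel
        i = np.searchsorted(t, 250.0)
        x[i - 10:i + 30] += 0.4
        m = np.zeros((1, t.size), bool)
        m[0, i - 10:i + 30] = True
        out = spline_correct(od_from_series(x), ArtifactMask(m),
                             pipeline_cfg).od[0, 0]
        seg = out[500:500 + kernel.size] - out[480:500].mean()
        assert seg.max() == pytest.approx(3e-3, rel=0.01)

    def test_short_segment_mean_shift_fallback(self, pipeline_cfg):
        x = np.zeros(200)
        x[100:102] += 0.6  # 2-sample artifact: below the spline minimum
        m = np.zeros((1, 200), bool)
        m[0, 100:102] = True
        out = spline_correct(od_from_series(x), ArtifactMask(m),
                             pipeline_cfg).od[0, 0]
        assert abs(out[100:102]).max() < 0.3


class TestWaveletCorrect:
    def test_constant_series_unchanged(self, pipeline_cfg):
        out = wavelet_correct(od_from_series(np.full(1000, 0.3)), pipeline_cfg)
        assert np.allclose(out.od, 0.3)

    def test_spike_attenuated(self, pipeline_cfg):
        x = np.zeros(3000)
        x[1500] = 1.0
        out = wavelet_correct(od_from_series(x), pipeline_cfg).od[0, 0]
        assert np.abs(out).max() <= 0.2

    def test_slow_tone_preserved(self, pipeline_cfg):
        x = np.sin(2 * np.pi * 0.05 * _time(300))
        out = wavelet_correct(od_from_series(x), pipeline_cfg).od[0, 0]
        rms_ratio = np.sqrt((out ** 2).mean() / (x ** 2).mean())
        assert abs(rms_ratio - 1.0) < 0.05

    def test_targeted_variant_touches_only_flagged_segments(self, pipeline_cfg):
        rng = np.random.default_rng(5)
        x = 0.002 * rng.standard_normal(3000)
        x[1500] += 0.8
        od = od_from_series(x)
        m = np.zeros((1, 3000), bool)
        m[0, 1480:1520] = True
        out = wavelet_correct_targeted(od, ArtifactMask(m), pipeline_cfg).od[0, 0]
        assert abs(out[1500]) < 0.4  # spike attenuated
        untouched = np.ones(3000, bool)
        untouched[1480:1520] = False
        assert np.array_equal(out[untouched], x[untouched])


class TestBandpass:
    def test_dc_rejection(self, pipeline_cfg):
        out = bandpass(od_from_series(np.full(5000, 1.0)), pipeline_cfg)
        assert np.abs(out.od).max() < 1e-6

    @pytest.mark.parametrize("freq", [0.01, 0.1, 0.5, 1.0])
    def test_gain_matches_analytic_butterworth(self, freq, pipeline_cfg):
        t = _time(600)
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(od_from_series(x), pipeline_cfg).od[0, 0]
        mid = slice(t.size // 4, 3 * t.size // 4)
        measured = y[mid].std() / x[mid].std()
        sos = sg.butter(3, [0.01, 0.5], btype="bandpass", fs=FS, output="sos")
        _, h = sg.sosfreqz(sos, worN=[freq], fs=FS)
        analytic = np.abs(h[0]) ** 2  # forward-backward: squared magnitude
        assert measured == pytest.approx(analytic, rel=0.05, abs=0.005)

    def test_passband_and_stopband_bounds(self, pipeline_cfg):
        t = _time(600)
        for freq, lo, hi in ((0.1, 0.95, 1.05), (1.0, 0.0, 0.2)):
            x = np.sin(2 * np.pi * freq * t)
            y = bandpass(od_from_series(x), pipeline_cfg).od[0, 0]
            mid = slice(t.size // 4, 3 * t.size // 4)
            gain = y[mid].std() / x[mid].std()
            assert lo <= gain <= hi

    def test_cutoff_above_nyquist_rejected(self):
        cfg = PipelineConfig(lpf_hz=6.0)
        with pytest.raises((ParameterError, ValidationError, Exception)):
            bandpass(od_from_series(np.zeros(100)), cfg)


class TestMBLL:
    def test_zero_od_gives_zero_concentrations(self, small_montage, pipeline_cfg):
        od = OpticalDensity(np.zeros((4, 2, 10)), FS)
        hb = mbll(od, small_montage, pipeline_cfg)
        assert np.allclose(hb.ohb, 0) and np.allclose(hb.dhb, 0)

    def test_forward_inverse_round_trip(self, small_montage, pipeline_cfg):
        ohb = np.full((4, 5), 2e-4)
        dhb = np.full((4, 5), -1e-4)
        od = forward_mbll(ohb, dhb, small_montage, pipeline_cfg)
        hb = mbll(OpticalDensity(od, FS), small_montage, pipeline_cfg)
        assert np.allclose(hb.ohb, ohb, atol=1e-10)
        assert np.allclose(hb.dhb, dhb, atol=1e-10)

    def test_thb_is_sum_at_every_sample(self, small_montage, pipeline_cfg):
        rng = np.random.default_rng(6)
        od = OpticalDensity(0.01 * rng.standard_normal((4, 2, 100)), FS)
        hb = mbll(od, small_montage, pipeline_cfg)
        assert np.allclose(hb.thb, hb.ohb + hb.dhb, atol=1e-12)


class TestPipelineOrchestration:
    def test_stage_order_logged(self, child_montage_small, pipeline_cfg):
        from hemovis.simulate import SimConfig, SubjectTruth, simulate_subject
        from hemovis.stimulus import build_block_schedule

        st = SubjectTruth("t", 30.0, {}, 4e-6, 4e-6 * 2 / 3, 0,
                          [1.0, 0.5, 0.4, 0.3, 0.2])
        sched = build_block_schedule(5, 5, 5, 10, seed=0)
        rec = simulate_subject(st, sched, child_montage_small,
                               SimConfig(noise_on=False, artifacts_on=False),
                               seed=0)
        hb, keep, residual, log = preprocess_recording(rec, pipeline_cfg)
        assert log["steps"] == ["intensity_to_od", "spline_correct",
                                "wavelet_correct_targeted", "bandpass"]
        assert keep.all()
        assert np.allclose(hb.thb, hb.ohb + hb.dhb, atol=1e-12)
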