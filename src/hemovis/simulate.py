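"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes so
every stage is testable without any recorded data:

* stimulus trials evoke a canonical double-gamma hemodynamic response
  (peak 6 s, undershoot ratio 1/6) convolved with the 5-s stimulus
  boxcar; mock trials evoke nothing;
* the planted OHb amplitude ``A_i`` of subject ``i`` follows a negative
  linear link to the AQ score, ``A_i = a - b * AQ_i + eps``; DHb is a
  scaled mirror of OHb (ratio -1/3 by default), so the true THb amplitude
  is ``(1 + ratio) * A_i``;
* the child cohort is scaled above the adult cohort;
* physiological noise (cardiac ~1.1 Hz, respiratory ~0.25 Hz, Mayer waves
  ~0.1 Hz, 1/f-like drift, white measurement noise) and scheduled motion
  artifacts (spikes, baseline shifts) are added in optical density before
  exponentiating to raw intensities at 10.2 Hz.

All randomness flows from a single cohort seed through spawned
sub-streams, so the same seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from hemovis.errors import ParameterError
from hemovis.io import (
    DEFAULT_FS_HZ,
    ProbeGeometry,
    Recording,
    default_montage,
    write_events,
    write_recording,
)
from hemovis.preprocessing import PipelineConfig, forward_mbll
from hemovis.stimulus import TrialSchedule, build_block_schedule

__all__ = [
    "HRFShape", "NoisePreset", "ArtifactPreset", "LinkParams", "SimConfig",
    "SubjectTruth", "GroundTruth", "hrf", "response_kernel",
    "simulate_subject", "simulate_cohort", "CohortSim", "subset_montage",
    "COHORT_DEFAULTS",
]


@dataclass(frozen=True)
class HRFShape:
    """Double-gamma impulse response: peak/undershoot times, ratio, widths.

    ``peak_k`` and ``undershoot_k`` are the gamma shape parameters; larger
    values give narrower lobes (lobe SD = mode / sqrt(k - 1)).
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    peak_k: float = 13.0
    undershoot_k: float = 17.0


@dataclass(frozen=True)
class NoisePreset:
    """Physiological + instrumental noise amplitudes, in OD units.

    Cardiac and respiratory components are sinusoids with 5% frequency
    jitter; the slow vasomotor background (Mayer-wave band) is a
    band-limited Gaussian process over ``lowfreq_band_hz``; drift is a
    1/f-like random walk; ``white_sd`` is broadband measurement noise.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.008
    resp_hz: float = 0.25
    resp_amp: float = 0.002
    lowfreq_band_hz: tuple[float, float] = (0.02, 0.20)
    lowfreq_sd: float = 0.0025
    drift_sd: float = 0.005
    white_sd: float = 0.002


@dataclass(frozen=True)
class ArtifactPreset:
    """Motion-artifact schedule parameters (amplitudes in OD units)."""

    spike_rate_per_min: float = 0.3
    spike_amp_range: tuple[float, float] = (0.2, 0.6)
    spike_width_s: float = 0.10
    shift_rate_per_min: float = 0.1
    shift_amp_range: tuple[float, float] = (0.1, 0.3)


@dataclass(frozen=True)
class LinkParams:
    """Amplitude-trait link: ``A_i = a - b * AQ_i + Normal(0, sd)``."""

    a: float
    b: float
    sd: float


@dataclass(frozen=True)
class AQMarginals:
    mean: float
    sd: float
    lo: int
    hi: int


# Cohort study conditions: adult amplitudes carry no trait link (matching
# the absence of adult correlations); the child link is strong and
# negative (true Pearson ~ -0.77). AQ marginals match the reference
# cohorts' printed statistics; `scale` is the net child/adult mean
# amplitude ratio after the trait link is applied.
COHORT_DEFAULTS = {
    "adult": {
        "scale": 1.0,
        "link": LinkParams(a=3.75e-6, b=0.0, sd=1.0e-6),
        "aq": AQMarginals(mean=15.1, sd=6.5, lo=3, hi=32),
        "version": "adult",
    },
    "child": {
        "scale": 1.6,
        "link": LinkParams(a=1.0e-5, b=1.25e-7, sd=1.1e-6),
        "aq": AQMarginals(mean=32.1, sd=10.7, lo=17, hi=49),
        "version": "child",
    },
}


@dataclass
class SimConfig:
    """Generator-level settings shared by a simulated cohort."""

    fs: float = DEFAULT_FS_HZ
    start_s: float = 5.0        # pre-roll before the first onset
    pad_end_s: float = 25.0     # post-roll after the last trial
    dhb_ratio: float = -1.0 / 3.0
    hrf_shape: HRFShape = field(default_factory=HRFShape)
    noise: NoisePreset = field(default_factory=NoisePreset)
    artifacts: ArtifactPreset = field(default_factory=ArtifactPreset)
    noise_on: bool = True
    artifacts_on: bool = True
    n_stim: int = 20
    n_mock: int = 20
    on_s: float = 5.0
    off_s: float = 10.0
    min_amplitude: float = 5e-7
    sidechannel_gain: tuple[float, float] = (0.2, 0.7)


@dataclass
class SubjectTruth:
    """Planted ground truth for one simulated subject."""

    subject_id: str
    aq_total: float          # NaN when the questionnaire is missing
    aq_subscales: dict[str, float]
    amplitude: float         # planted OHb peak amplitude (molar)
    thb_amplitude: float     # (1 + dhb_ratio) * amplitude
    best_channel: int
    channel_gains: list[float]
    artifacts: list[dict] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Cohort-level ground truth: link parameters and per-subject records."""

    cohort: str
    seed: int
    link: LinkParams
    scale: float
    dhb_ratio: float
    subjects: list[SubjectTruth] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cohort": self.cohort,
            "seed": self.seed,
            "link": asdict(self.link),
            "scale": self.scale,
            "dhb_ratio": self.dhb_ratio,
            "subjects": [asdict(s) for s in self.subjects],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def hrf(t, shape: HRFShape | None = None) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response (peak 1 at t=peak_s).

    ``h(t) = g(t; k1) - ratio * g(t; k2)`` with gamma densities whose modes
    sit at the peak and undershoot times; each gamma bump is normalized to
    unit mode height before mixing, and ``h(0) = 0``.
    """
    shape = shape or HRFShape()
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0

    def bump(tt: np.ndarray, mode: float, k: float = 7.0) -> np.ndarray:
        # gamma-shaped bump with its mode at `mode`, unit peak height
        theta = mode / (k - 1.0)
        v = (tt / theta) ** (k - 1.0) * np.exp(-(tt - mode) / theta)
        return v / ((mode / theta) ** (k - 1.0))

    tt = t[pos]
    out[pos] = bump(tt, shape.peak_s, shape.peak_k) \
        - shape.undershoot_ratio * bump(tt, shape.undershoot_s,
                                        shape.undershoot_k)
    return out


def response_kernel(cfg: SimConfig, duration_s: float = 40.0) -> np.ndarray:
    """HRF convolved with the stimulus-on boxcar, normalized to peak 1."""
    dt = 1.0 / cfg.fs
    t = np.arange(0.0, duration_s, dt)
    h = hrf(t, cfg.hrf_shape)
    box = np.ones(max(1, int(round(cfg.on_s * cfg.fs))))
    r = np.convolve(h, box)[: t.size] * dt
    peak = np.abs(r).max()
    if peak == 0:
        raise ParameterError("degenerate HRF: zero response")
    return r / peak


def subset_montage(geom: ProbeGeometry, n_channels: int) -> ProbeGeometry:
    """First ``n_channels`` channels of a montage (for small simulations)."""
    return ProbeGeometry(geom.source_pos_cm, geom.detector_pos_cm,
                         geom.channels[:n_channels])


def _physio_noise(n: int, n_series: int, cfg: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """(n_series, n) array of physiological + instrumental OD noise."""
    from scipy import signal as sg

    p = cfg.noise
    dt = 1.0 / cfg.fs
    t = np.arange(n) * dt
    sos = sg.butter(2, p.lowfreq_band_hz, btype="bandpass", fs=cfg.fs,
                    output="sos")
    out = np.empty((n_series, n))
    for i in range(n_series):
        x = np.zeros(n)
        for f0, amp in ((p.cardiac_hz, p.cardiac_amp),
                        (p.resp_hz, p.resp_amp)):
            f = f0 * (1.0 + 0.05 * rng.standard_normal())
            x += amp * np.sin(2 * math.pi * f * t + rng.uniform(0, 2 * math.pi))
        bg = sg.sosfilt(sos, rng.standard_normal(n))
        sd = bg.std()
        if sd > 0:
            x += p.lowfreq_sd * bg / sd
        drift = np.cumsum(rng.standard_normal(n))
        sd = drift.std()
        if sd > 0:
            x += p.drift_sd * drift / sd
        x += p.white_sd * rng.standard_normal(n)
        out[i] = x
    return out


def _artifact_schedule(duration_s: float, n_channels: int, cfg: SimConfig,
                       rng: np.random.Generator) -> list[dict]:
    a = cfg.artifacts
    events: list[dict] = []
    minutes = duration_s / 60.0
    for kind, rate, amp_range in (
        ("spike", a.spike_rate_per_min, a.spike_amp_range),
        ("shift", a.shift_rate_per_min, a.shift_amp_range),
    ):
        n_ev = rng.poisson(rate * minutes)
        for _ in range(n_ev):
            events.append({
                "type": kind,
                "time_s": float(rng.uniform(2.0, duration_s - 2.0)),
                "channel": int(rng.integers(n_channels)),
                "amplitude": float(rng.uniform(*amp_range) * rng.choice([-1, 1])),
            })
    return sorted(events, key=lambda e: e["time_s"])


def _apply_artifacts(od: np.ndarray, events: list[dict],
                     cfg: SimConfig) -> None:
    n = od.shape[2]
    t = np.arange(n) / cfg.fs
    for ev in events:
        ch = ev["channel"]
        if ev["type"] == "spike":
            bump = ev["amplitude"] * np.exp(
                -0.5 * ((t - ev["time_s"]) / cfg.artifacts.spike_width_s) ** 2
            )
            od[ch, :, :] += bump[None, :]
        else:  # baseline shift persisting to the end of the recording
            od[ch, :, t >= ev["time_s"]] += ev["amplitude"]


def simulate_subject(
    truth: SubjectTruth,
    schedule: TrialSchedule,
    montage: ProbeGeometry,
    cfg: SimConfig | None = None,
    seed: int | np.random.Generator = 0,
    pipeline_cfg: PipelineConfig | None = None,
) -> Recording:
    """Forward-simulate one raw two-wavelength recording.

    Per channel: OHb(t) = amplitude * gain_ch * (HRF x boxcar) summed over
    stimulus onsets (mock trials contribute nothing), DHb = ratio * OHb;
    concentrations are pushed through the forward Beer-Lambert model to
    OD, noise and scheduled artifacts are added, and intensities are
    recovered as ``I0 * exp(-OD)``. Artifacts actually injected are
    recorded in ``truth.artifacts``.
    """
    cfg = cfg or SimConfig()
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    duration_s = cfg.start_s + schedule.total_duration_s + cfg.pad_end_s
    n = int(round(duration_s * cfg.fs))
    last_window_end = (schedule.onsets().max() + cfg.start_s
                       + pipeline_cfg.trange_s[1]) if schedule.n_trials else 0.0
    if last_window_end > duration_s:
        raise ParameterError("schedule longer than the requested duration")
    n_ch = montage.n_channels

    kernel = response_kernel(cfg)
    drive = np.zeros(n)
    for onset in schedule.onsets("S"):
        i0 = int(round((onset + cfg.start_s) * cfg.fs))
        seg = min(kernel.size, n - i0)
        drive[i0:i0 + seg] += kernel[:seg]

    gains = np.asarray(truth.channel_gains)
    ohb = truth.amplitude * gains[:, None] * drive[None, :]
    dhb = cfg.dhb_ratio * ohb
    od = forward_mbll(ohb, dhb, montage, pipeline_cfg)

    if cfg.noise_on:
        od = od + _physio_noise(n, 2 * n_ch, cfg, rng).reshape(n_ch, 2, n)
    if cfg.artifacts_on:
        events = _artifact_schedule(duration_s, n_ch, cfg, rng)
        _apply_artifacts(od, events, cfg)
        truth.artifacts = events

    i0 = rng.uniform(0.02, 0.5, size=(n_ch, 2))
    intensity = i0[:, :, None] * np.exp(-od)
    return Recording(intensity=intensity, fs=cfg.fs, geometry=montage,
                     subject_id=truth.subject_id, cohort="adult")


def _sample_aq(marg: AQMarginals, rng: np.random.Generator) -> int:
    """Truncated-normal AQ total, rounded to an integer within range."""
    sigma = marg.sd * 1.25  # pre-truncation widening to offset SD shrinkage
    a = (marg.lo - marg.mean) / sigma
    b = (marg.hi - marg.mean) / sigma
    v = sps.truncnorm.rvs(a, b, loc=marg.mean, scale=sigma, random_state=rng)
    return int(np.clip(round(v), marg.lo, marg.hi))


def _split_subscales(total: int, sub_max: int,
                     rng: np.random.Generator) -> dict[str, int]:
    """Dirichlet split of the total into the five subscales."""
    names = ["AQ_S", "AQ_C", "AQ_A", "AQ_D", "AQ_I"]
    w = rng.dirichlet(np.full(5, 2.0))
    vals = np.floor(w * total).astype(int)
    vals = np.minimum(vals, sub_max)
    # distribute the remainder without exceeding the per-subscale maximum
    rem = total - vals.sum()
    order = np.argsort(-w)
    k = 0
    while rem > 0 and k < 1000:
        j = order[k % 5]
        if vals[j] < sub_max:
            vals[j] += 1
            rem -= 1
        k += 1
    return dict(zip(names, vals.tolist()))


@dataclass
class CohortSim:
    """A simulated cohort: recordings, schedules, AQ table and ground truth."""

    recordings: list[Recording]
    schedules: list[TrialSchedule]
    aq_table: pd.DataFrame
    truth: GroundTruth
    sim_config: SimConfig

    def write(self, outdir: str | Path, fmt: str = "text") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".snirf" if fmt == "snirf" else ".tsv"
        for rec, sched in zip(self.recordings, self.schedules):
            write_recording(rec, outdir / f"{rec.subject_id}{ext}")
            write_events(sched, outdir / f"{rec.subject_id}_events.tsv")
        self.aq_table.to_csv(outdir / "aq_table.csv", index=False)
        self.truth.to_json(outdir / "ground_truth.json")


def simulate_cohort(
    n: int,
    cohort: str = "child",
    link: LinkParams | None = None,
    seed: int = 0,
    cfg: SimConfig | None = None,
    montage: ProbeGeometry | None = None,
    pipeline_cfg: PipelineConfig | None = None,
) -> CohortSim:
    """Generate a full cohort with AQ scores linked to planted amplitudes.

    AQ totals are drawn from a truncated normal matching the reference
    cohort's mean/SD/range and split into subscales with a Dirichlet
    weight vector; planted amplitudes follow the (negative) linear link
    with the cohort scaling applied; schedules are independently
    pseudo-randomized per subject. Everything derives from ``seed``.
    """
    if n < 3:
        raise ParameterError("cohort size must be at least 3")
    defaults = COHORT_DEFAULTS[cohort]
    link = link or defaults["link"]
    cfg = cfg or SimConfig()
    montage = montage or default_montage(cohort)
    marg: AQMarginals = defaults["aq"]
    if marg.sd <= 0 or marg.hi <= marg.lo:
        raise ParameterError("infeasible AQ marginals")

    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(n + 1)]
    cohort_rng = streams[0]

    sub_max = 10 if cohort == "adult" else 30
    prefix = "A" if cohort == "adult" else "B"
    truth = GroundTruth(cohort=cohort, seed=seed, link=link,
                        scale=defaults["scale"], dhb_ratio=cfg.dhb_ratio)
    recordings, schedules, rows = [], [], []
    for i in range(n):
        rng = streams[i + 1]
        aq = _sample_aq(marg, rng)
        subs = _split_subscales(aq, sub_max, rng)
        amp = link.a - link.b * aq + link.sd * rng.standard_normal()
        amp = max(cfg.min_amplitude, amp)
        n_ch = montage.n_channels
        best = int(cohort_rng.integers(n_ch))
        gains = rng.uniform(*cfg.sidechannel_gain, size=n_ch)
        gains[best] = 1.0
        st = SubjectTruth(
            subject_id=f"{prefix}{i + 1:02d}",
            aq_total=float(aq),
            aq_subscales=subs,
            amplitude=float(amp),
            thb_amplitude=float(amp * (1.0 + cfg.dhb_ratio)),
            best_channel=best,
            channel_gains=gains.tolist(),
        )
        sched = build_block_schedule(cfg.n_stim, cfg.n_mock, cfg.on_s, cfg.off_s,
                                     seed=int(rng.integers(2 ** 31)))
        rec = simulate_subject(st, sched, montage, cfg, seed=rng,
                               pipeline_cfg=pipeline_cfg)
        rec.cohort = cohort
        truth.subjects.append(st)
        recordings.append(rec)
        # analysis-facing schedule: onsets in recording time (incl. pre-roll)
        schedules.append(TrialSchedule(
            trials=[(o + cfg.start_s, c) for o, c in sched.trials],
            on_duration_s=sched.on_duration_s,
            off_duration_s=sched.off_duration_s,
        ))
        rows.append({"subject_id": st.subject_id, "version": defaults["version"],
                     "AQ": aq, **subs})
    aq_table = pd.DataFrame(rows)
    return CohortSim(recordings=recordings, schedules=schedules,
                     aq_table=aq_table, truth=truth, sim_config=cfg)
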