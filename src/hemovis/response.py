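"""Epoching, block averaging, blank subtraction and peak metrics.

Trials are epoched over a -2..20 s window around each onset,
baseline-subtracted (mean over [-2, 0)), and averaged per condition;
trials whose window intersects a residual motion artifact on a channel are
dropped for that channel. The evoked response is summarized per
chromophore as the peak amplitude (maximum for THb/OHb, minimum for DHb)
and its latency within the post-onset window, after sample-wise
subtraction of the mock-trial (blank) time course. Per subject, only the
channel with the highest blank-subtracted THb amplitude is analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hemovis.errors import (
    EmptyConditionError,
    EmptyMontageError,
    MissingDataError,
    ValidationError,
)
from hemovis.preprocessing import ArtifactMask, HbSeries, PipelineConfig
from hemovis.stimulus import TrialSchedule

__all__ = [
    "BlockAverage", "ResponseMetrics", "block_average", "extract_peak",
    "blank_subtract", "select_best_channel", "extract_subject_metrics",
]

CHROMOPHORES = ("THb", "OHb", "DHb")


@dataclass
class BlockAverage:
    """Condition-wise mean time courses over the epoch window.

    ``traces[condition][chromophore]`` has shape ``(n_channels, n_win)``;
    ``time_s`` is the common epoch time axis (onset at 0);
    ``n_trials_used[condition]`` counts usable trials per channel.
    """

    time_s: np.ndarray
    traces: dict[str, dict[str, np.ndarray]]
    n_trials_used: dict[str, np.ndarray]
    fs: float

    @property
    def conditions(self) -> list[str]:
        return list(self.traces)

    def trace(self, condition: str, chromophore: str, channel: int) -> np.ndarray:
        return self.traces[condition][chromophore][channel]


@dataclass(frozen=True)
class ResponseMetrics:
    """Peak amplitude/latency per chromophore at one channel.

    Amplitudes are signed concentration changes (molar): positive peaks
    for THb/OHb, the (typically negative) trough for DHb — noise may
    invert the DHb sign, which is deliberately not enforced.
    """

    amplitude: dict[str, float]
    latency_s: dict[str, float]
    channel_id: int
    condition: str
    blank_subtracted: bool
    n_trials: int = 0


def block_average(
    hb: HbSeries,
    schedule: TrialSchedule,
    residual_mask: ArtifactMask | None,
    cfg: PipelineConfig | None = None,
) -> BlockAverage:
    """Baseline-subtracted trial average per condition and channel.

    Every trial window must lie inside the recording. A trial is dropped
    for a given channel when its window intersects that channel's residual
    artifact mask. A condition with zero usable trials on every channel
    raises :class:`EmptyConditionError`.
    """
    cfg = cfg or PipelineConfig()
    fs = hb.fs
    t0, t1 = cfg.trange_s
    rel = np.arange(int(round(t0 * fs)), int(round(t1 * fs)) + 1)
    time_s = rel / fs
    baseline = time_s < 0
    n_ch, n_t = hb.ohb.shape
    if residual_mask is not None and residual_mask.mask.shape != (n_ch, n_t):
        raise ValidationError("residual mask shape does not match hb")

    conditions = sorted({c for _, c in schedule.trials})
    traces: dict[str, dict[str, np.ndarray]] = {}
    n_used: dict[str, np.ndarray] = {}
    chrom_data = {"THb": hb.thb, "OHb": hb.ohb, "DHb": hb.dhb}
    for cond in conditions:
        sums = {ch: np.zeros((n_ch, rel.size)) for ch in CHROMOPHORES}
        counts = np.zeros(n_ch, dtype=int)
        for onset in schedule.onsets(cond):
            idx = int(round(onset * fs)) + rel
            if idx[0] < 0 or idx[-1] >= n_t:
                raise ValidationError(
                    f"trial at {onset} s extends outside the recording"
                )
            if residual_mask is not None:
                ok = ~residual_mask.mask[:, idx].any(axis=1)
            else:
                ok = np.ones(n_ch, dtype=bool)
            for name, data in chrom_data.items():
                seg = data[:, idx]
                seg = seg - seg[:, baseline].mean(axis=1, keepdims=True)
                sums[name][ok] += seg[ok]
            counts += ok
        if counts.max() == 0:
            raise EmptyConditionError(f"no usable trials for condition {cond!r}")
        denom = np.where(counts > 0, counts, 1)[:, None]
        traces[cond] = {name: sums[name] / denom for name in CHROMOPHORES}
        n_used[cond] = counts
    return BlockAverage(time_s=time_s, traces=traces, n_trials_used=n_used, fs=fs)


def extract_peak(
    block: BlockAverage,
    chromophore: str,
    condition: str = "S",
    channel: int = 0,
) -> tuple[float, float]:
    """Peak amplitude and latency within the post-onset window (0, 20] s.

    The peak is the maximal value for THb and OHb and the minimal value
    for DHb; latency is the time of that extremum relative to stimulus
    onset. Flat traces resolve to the earliest sample (tie-break).
    """
    trace = block.trace(condition, chromophore, channel)
    post = block.time_s > 0
    seg = trace[post]
    if np.all(np.isnan(seg)):
        raise MissingDataError("trace is entirely missing")
    if chromophore == "DHb":
        i = int(np.nanargmin(seg))
    else:
        i = int(np.nanargmax(seg))
    return float(seg[i]), float(block.time_s[post][i])


def blank_subtract(block: BlockAverage, stim: str = "S",
                   blank: str = "B") -> BlockAverage:
    """Subtract the blank-evoked time course sample-wise from the stimulus.

    Returns a new :class:`BlockAverage` whose single condition ``"S-B"``
    holds the normalized response; peaks extracted from it are the
    blank-subtracted metrics.
    """
    if stim not in block.traces or blank not in block.traces:
        raise ValidationError(f"conditions {stim!r} and {blank!r} are required")
    diff = {
        ch: block.traces[stim][ch] - block.traces[blank][ch]
        for ch in CHROMOPHORES
    }
    n = np.minimum(block.n_trials_used[stim], block.n_trials_used[blank])
    return BlockAverage(time_s=block.time_s, traces={"S-B": diff},
                        n_trials_used={"S-B": n}, fs=block.fs)


def select_best_channel(
    amplitudes: np.ndarray,
    keep: np.ndarray | None = None,
) -> int:
    """Channel with the highest blank-subtracted THb amplitude.

    Ties break toward the lowest channel index; pruned channels
    (``keep == False``) are never selected.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if keep is not None:
        amps = np.where(np.asarray(keep, dtype=bool), amps, -np.inf)
    if amps.size == 0 or not np.isfinite(amps).any():
        raise EmptyMontageError("no channels available for selection")
    return int(np.argmax(amps))


def extract_subject_metrics(
    hb: HbSeries,
    schedule: TrialSchedule,
    residual_mask: ArtifactMask | None,
    keep: np.ndarray | None,
    cfg: PipelineConfig | None = None,
    subject_id: str = "",
    peak_mode: str = "timecourse",
) -> pd.DataFrame:
    """Full per-subject extraction: block average -> best channel -> peaks.

    ``peak_mode`` selects how blank subtraction enters the metrics:
    ``"timecourse"`` subtracts the blank time course sample-wise before
    peak extraction (default); ``"peak"`` extracts peaks per condition and
    subtracts the blank peak from the stimulus peak.

    Returns a tidy frame with one row per (condition, chromophore):
    conditions ``S`` and ``B`` are raw, ``S-B`` is blank-subtracted.
    """
    if peak_mode not in ("timecourse", "peak"):
        raise ValidationError("peak_mode must be 'timecourse' or 'peak'")
    cfg = cfg or PipelineConfig()
    block = block_average(hb, schedule, residual_mask, cfg)
    diff = blank_subtract(block)
    n_ch = hb.ohb.shape[0]
    thb_amps = np.array([
        extract_peak(diff, "THb", "S-B", c)[0] for c in range(n_ch)
    ])
    best = select_best_channel(thb_amps, keep)

    rows = []
    for cond, blk in (("S", block), ("B", block), ("S-B", diff)):
        source = blk if cond != "S-B" else diff
        for chrom in CHROMOPHORES:
            if cond == "S-B" and peak_mode == "peak":
                amp_s, lat_s = extract_peak(block, chrom, "S", best)
                amp_b, _ = extract_peak(block, chrom, "B", best)
                amp, lat = amp_s - amp_b, lat_s
            else:
                amp, lat = extract_peak(source, chrom, cond, best)
            rows.append({
                "subject_id": subject_id,
                "channel": best,
                "chrom": chrom,
                "amplitude": amp,
                "latency_s": lat,
                "condition": cond,
                "n_trials": int(source.n_trials_used[cond][best]),
            })
    return pd.DataFrame(rows)
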