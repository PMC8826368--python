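"""Visual stimulus synthesis and trial scheduling.

Implements the pattern-reversal stimulation protocol: a full-field radial
(wedge/ring) square-wave checkerboard with abrupt phase inversion,
optionally blended with an isoluminant grey-scale cartoon so that cartoon
edges stay visible on top of the checkerboard, plus the pseudo-randomly
interleaved stimulus/mock block schedule.

All frames are normalized luminance in [0, 1]; gamma correction is assumed
to be handled by the display. The default geometry reproduces the
experimental setup: 800x600 px at 60 Hz, 70 cm viewing distance, mean
luminance mapped to 0.5 (45 cd/m^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import feature as _skfeature

from hemovis.errors import DegenerateInputError, ParameterError, ValidationError

__all__ = [
    "ViewingGeometry", "CheckerboardSpec", "StimFrame", "TrialSchedule",
    "make_checkerboard", "reversal_times", "to_isoluminant_gray",
    "scale_contrast", "auto_canny_mask", "blend_frame", "build_block_schedule",
]


@dataclass(frozen=True)
class ViewingGeometry:
    """Monitor and viewing parameters defining the pixel<->degree mapping.

    Defaults follow the recording setup: 800x600 resolution, 60 Hz refresh,
    70 cm viewing distance, 45 cd/m^2 mean luminance (normalized to 0.5).
    The physical panel size defaults to a 32-inch 16:9 screen.
    """

    screen_width_px: int = 800
    screen_height_px: int = 600
    screen_width_cm: float = 69.8
    screen_height_cm: float = 39.3
    viewing_distance_cm: float = 70.0
    refresh_hz: float = 60.0
    mean_luminance_norm: float = 0.5

    def __post_init__(self) -> None:
        for name in ("screen_width_px", "screen_height_px", "screen_width_cm",
                     "screen_height_cm", "viewing_distance_cm", "refresh_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 < self.mean_luminance_norm < 1.0:
            raise ParameterError("mean_luminance_norm must lie in (0, 1)")

    @property
    def screen_width_deg(self) -> float:
        """Full horizontal extent in degrees of visual angle."""
        return 2.0 * math.degrees(
            math.atan(self.screen_width_cm / (2.0 * self.viewing_distance_cm))
        )

    @property
    def pixels_per_degree(self) -> float:
        return self.screen_width_px / self.screen_width_deg


@dataclass(frozen=True)
class CheckerboardSpec:
    """Parameters of the reversing radial checkerboard.

    ``spatial_freq_cpd`` is the radial spatial frequency in cycles per
    degree (default 0.33), ``reversal_rate_hz`` the number of abrupt phase
    inversions per second (default 4, pattern-reversal convention),
    ``contrast`` the Michelson contrast (0.90 for the stimulus, 0.0 for the
    mock trials), ``phase`` the current polarity (0 or 1).
    """

    spatial_freq_cpd: float = 0.33
    reversal_rate_hz: float = 4.0
    contrast: float = 0.90
    phase: int = 0

    def __post_init__(self) -> None:
        if self.spatial_freq_cpd <= 0:
            raise ParameterError("spatial_freq_cpd must be positive")
        if not 0.0 <= self.contrast <= 1.0:
            raise ParameterError("contrast must lie in [0, 1]")
        if self.phase not in (0, 1):
            raise ParameterError("phase must be 0 or 1")
        if self.reversal_rate_hz < 0:
            raise ParameterError("reversal_rate_hz must be >= 0")


@dataclass
class StimFrame:
    """A single stimulus frame: normalized luminance plus its pivot level.

    ``mean_level`` is the luminance the frame is contrast-scaled around, not
    necessarily the empirical pixel mean (e.g. after edge blending).
    """

    luminance: np.ndarray
    mean_level: float

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance, dtype=float)
        if self.luminance.ndim != 2:
            raise ValidationError("frame luminance must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.luminance.shape


@dataclass
class TrialSchedule:
    """Ordered stimulation trials: (onset_s, condition) with S/B conditions.

    Condition ``"S"`` is the reversing checkerboard, ``"B"`` the 0%-contrast
    mock stimulus acting as within-run blank control. Trials are laid out
    back-to-back: each occupies ``on_duration_s + off_duration_s`` seconds.
    """

    trials: list[tuple[float, str]]
    on_duration_s: float
    off_duration_s: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        return self.n_trials * (self.on_duration_s + self.off_duration_s)

    def onsets(self, condition: str | None = None) -> np.ndarray:
        if condition is None:
            return np.array([t for t, _ in self.trials])
        return np.array([t for t, c in self.trials if c == condition])

    def count(self, condition: str) -> int:
        return sum(1 for _, c in self.trials if c == condition)

    def validate(self, strict_spacing: bool = True) -> None:
        """Check ordering, spacing and condition labels; raise on violation."""
        if self.on_duration_s <= 0 or self.off_duration_s < 0:
            raise ValidationError("trial durations must be positive")
        period = self.on_duration_s + self.off_duration_s
        prev = None
        for onset, cond in self.trials:
            if cond not in ("S", "B"):
                raise ValidationError(f"unknown condition {cond!r}")
            if prev is not None:
                if onset <= prev:
                    raise ValidationError("onsets must be strictly increasing")
                if strict_spacing and abs((onset - prev) - period) > 1e-9:
                    raise ValidationError(
                        "consecutive onsets must differ by on + off duration"
                    )
            prev = onset


def make_checkerboard(geom: ViewingGeometry, spec: CheckerboardSpec) -> StimFrame:
    """Render one frame of the radial (wedge/ring) square-wave checkerboard.

    The radial period equals ``1 / spatial_freq_cpd`` degrees of visual
    angle (rings of constant radial width); the number of wedges is chosen
    so the tangential check width at half-maximal eccentricity matches the
    radial width. The two luminance levels are
    ``mean_level * (1 +/- contrast)``; ``phase = 1`` swaps them.
    """
    h, w = geom.screen_height_px, geom.screen_width_px
    ppd = geom.pixels_per_degree
    half_period_deg = 1.0 / (2.0 * spec.spatial_freq_cpd)

    y, x = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r_deg = np.hypot(x - cx, y - cy) / ppd
    theta = np.arctan2(y - cy, x - cx)

    ring = np.floor(r_deg / half_period_deg).astype(int)
    # tangential half-period at half-max eccentricity ~ radial half-period
    e_half = (w / 2.0) / ppd / 2.0
    n_half_wedges = max(2, 2 * round(math.pi * e_half / half_period_deg))
    wedge = np.floor((theta + math.pi) / (2.0 * math.pi / n_half_wedges)).astype(int)
    wedge = np.clip(wedge, 0, n_half_wedges - 1)

    parity = (ring + wedge + spec.phase) % 2
    mean = geom.mean_luminance_norm
    lum = np.where(parity == 0,
                   mean * (1.0 + spec.contrast),
                   mean * (1.0 - spec.contrast))
    return StimFrame(luminance=lum, mean_level=mean)


def reversal_times(spec: CheckerboardSpec, on_duration_s: float) -> np.ndarray:
    """Timestamps of the abrupt phase inversions within one stimulus-on period.

    A reversal rate of ``f`` Hz yields ``floor(f * on_duration_s)`` evenly
    spaced inversion events; a static pattern (0 Hz) yields none.
    """
    if on_duration_s <= 0:
        raise ParameterError("on_duration_s must be positive")
    f = spec.reversal_rate_hz
    if f <= 0:
        return np.array([])
    n = int(math.floor(f * on_duration_s + 1e-12))
    return np.arange(1, n + 1) / f


def to_isoluminant_gray(rgb_frame: np.ndarray, geom: ViewingGeometry) -> StimFrame:
    """Convert an RGB frame to grey-scale and rescale to the mean luminance.

    Uses Rec. 709 luma weights, then multiplies by a global gain so the
    spatial mean equals ``geom.mean_luminance_norm`` — the isoluminant
    baseline shown between checkerboard presentations. The output is
    therefore invariant to any global gain applied to the input.
    """
    rgb = np.asarray(rgb_frame, dtype=float)
    if rgb.ndim == 2:
        gray = rgb.copy()
    elif rgb.ndim == 3 and rgb.shape[2] == 3:
        gray = rgb @ np.array([0.2126, 0.7152, 0.0722])
    else:
        raise ValidationError("expected an HxW or HxWx3 array")
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValidationError("RGB values must lie in [0, 1]")
    m = gray.mean()
    if m <= 0:
        raise DegenerateInputError("all-black frame cannot be rescaled to a positive mean")
    gray = gray * (geom.mean_luminance_norm / m)
    return StimFrame(luminance=gray, mean_level=geom.mean_luminance_norm)


def scale_contrast(frame: StimFrame, c: float) -> StimFrame:
    """Scale frame contrast about ``mean_level``: ``p' = mean + c*(p - mean)``.

    Leaves the pivot (and hence the spatial mean of a symmetric frame)
    unchanged; used for the 20/40/80% baseline-contrast conditions.
    """
    if not 0.0 <= c <= 1.0:
        raise ParameterError("contrast scale must lie in [0, 1]")
    lum = frame.mean_level + c * (frame.luminance - frame.mean_level)
    return StimFrame(luminance=lum, mean_level=frame.mean_level)


def auto_canny_mask(frame: StimFrame, sigma: float = 0.33) -> np.ndarray:
    """Binary edge mask via Canny with median-derived hysteresis thresholds.

    The zero-parameter recipe: with ``m`` the median luminance, the
    low/high hysteresis thresholds are ``max(0, (1 - sigma)*m)`` and
    ``min(1, (1 + sigma)*m)`` with ``sigma = 0.33`` by default.
    """
    img = frame.luminance
    m = float(np.median(img))
    lo = max(0.0, (1.0 - sigma) * m)
    hi = min(1.0, (1.0 + sigma) * m)
    mask = _skfeature.canny(img, low_threshold=lo, high_threshold=hi,
                            use_quantiles=False)
    return mask.astype(bool)


def blend_frame(cartoon: StimFrame, checker: StimFrame) -> StimFrame:
    """Overlay cartoon edges on the checkerboard by local polarity inversion.

    Non-edge pixels show the raw checkerboard. At pixels on a cartoon edge
    (auto-Canny mask of the cartoon) the checkerboard level is swapped for
    the opposite level, so every cartoon contour remains visible regardless
    of the local check polarity. Output luminances therefore never leave
    the two checkerboard levels.
    """
    if cartoon.shape != checker.shape:
        raise ParameterError("cartoon and checkerboard frames must share dimensions")
    levels = np.unique(checker.luminance)
    if levels.size > 2:
        raise ParameterError("checkerboard frame must have at most two levels")
    mask = auto_canny_mask(cartoon)
    out = checker.luminance.copy()
    # reflect about the pivot: swaps mean*(1+c) <-> mean*(1-c)
    out[mask] = 2.0 * checker.mean_level - out[mask]
    return StimFrame(luminance=out, mean_level=checker.mean_level)


def _transition_imbalance(conds: np.ndarray) -> int:
    """Worst imbalance of lag-1 and lag-2 condition-history counts.

    For each condition c and lag k in {1, 2}: how often c is followed at
    lag k by itself vs. by the other condition. Balanced histories keep
    slow response carry-over orthogonal to the condition labels.
    """
    worst = 0
    for lag in (1, 2):
        if conds.size <= lag:
            continue
        prev, nxt = conds[:-lag], conds[lag:]
        for c in ("S", "B"):
            stay = int(((prev == c) & (nxt == c)).sum())
            leave = int(((prev == c) & (nxt != c)).sum())
            worst = max(worst, abs(stay - leave))
    return worst


def build_block_schedule(
    n_stim: int,
    n_mock: int,
    on_s: float,
    off_s: float,
    seed: int,
) -> TrialSchedule:
    """Pseudo-randomly interleave stimulus (S) and mock (B) trials.

    The default protocol is 20 S + 20 B trials of 5 s on / 10 s off,
    i.e. a 10-minute block. Ordering is a seeded permutation constrained
    to first-order counterbalancing: each condition is preceded equally
    often (within one trial) by either condition, so slow response
    carry-over between consecutive trials cannot bias the
    stimulus-minus-blank contrast. The constraint is symmetric under
    swapping the condition labels, which keeps every position's S/B
    probability at exactly one half. The same seed always yields the same
    schedule.
    """
    if n_stim < 0 or n_mock < 0:
        raise ParameterError("trial counts must be non-negative")
    if on_s <= 0 or off_s <= 0:
        raise ParameterError("durations must be positive")
    rng = np.random.default_rng(seed)
    conditions = np.array(["S"] * n_stim + ["B"] * n_mock)
    best, best_score = conditions.copy(), _transition_imbalance(conditions)
    for _ in range(2000):
        rng.shuffle(conditions)
        score = _transition_imbalance(conditions)
        if score < best_score:
            best, best_score = conditions.copy(), score
        if best_score <= 1:
            break
    period = on_s + off_s
    trials = [(i * period, str(c)) for i, c in enumerate(best)]
    sched = TrialSchedule(trials=trials, on_duration_s=on_s, off_duration_s=off_s)
    sched.validate()
    return sched
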