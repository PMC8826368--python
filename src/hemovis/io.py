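"""Recordings, event files, probe montages and AQ questionnaires.

Two on-disk dialects are first-class for recordings: SNIRF (HDF5) and a
plain-text TSV dialect with a small ``#``-prefixed header block, so that
test fixtures need no binary container. Events are TSV
(``onset_s  duration_s  condition``), AQ tables CSV, montages JSON.

AQ scoring follows the two published conventions: the adult self-report is
binary-scored (1 point whenever the response falls on the autistic side of
the 4-point Likert scale, total 0-50), the child parent-report keeps the
full 0-3 Likert range per item after reverse-scoring (total 0-150). Both
group the 50 items into five subscales (social skills AQ_S, attention
switching AQ_A, attention to detail AQ_D, communication AQ_C, imagination
AQ_I). The item-direction and subscale keys ship as package data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from hemovis.errors import FormatError, ValidationError
from hemovis.stimulus import TrialSchedule

__all__ = [
    "Recording", "ProbeGeometry", "AQRecord", "default_montage",
    "read_recording", "write_recording", "read_events", "write_events",
    "score_aq", "risk_flag", "load_adult_table", "load_child_table",
    "load_aq_keys", "read_aq_table", "write_aq_table",
    "read_montage", "write_montage",
]

WAVELENGTHS_NM = (760.0, 850.0)
DEFAULT_FS_HZ = 10.2

_SEPARATION_RANGE_MM = {"adult": (20.0, 44.0), "child": (22.0, 30.0)}


# ---------------------------------------------------------------------------
# probe geometry

@dataclass
class ProbeGeometry:
    """Optode layout: source/detector positions (cm) and channel pairing.

    The default montage covers the occipital region with 8 sources and 7
    detectors on a 3x5 grid (checkerboard type assignment), every
    nearest-neighbour source-detector pair forming one of 22 channels.
    """

    source_pos_cm: np.ndarray      # (n_sources, 3)
    detector_pos_cm: np.ndarray    # (n_detectors, 3)
    channels: list[tuple[int, int]]  # 0-based (source, detector) pairs

    def __post_init__(self) -> None:
        self.source_pos_cm = np.asarray(self.source_pos_cm, dtype=float)
        self.detector_pos_cm = np.asarray(self.detector_pos_cm, dtype=float)
        self.channels = [(int(s), int(d)) for s, d in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def separations_mm(self) -> np.ndarray:
        seps = [
            10.0 * np.linalg.norm(self.source_pos_cm[s] - self.detector_pos_cm[d])
            for s, d in self.channels
        ]
        return np.asarray(seps)

    def validate(self, cohort: str | None = None) -> None:
        if self.n_channels != 22:
            raise ValidationError(
                f"default montage must have 22 channels, got {self.n_channels}"
            )
        if cohort is not None:
            lo, hi = _SEPARATION_RANGE_MM[cohort]
            seps = self.separations_mm
            if seps.min() < lo - 1e-9 or seps.max() > hi + 1e-9:
                raise ValidationError(
                    f"{cohort} separations must lie in [{lo}, {hi}] mm, "
                    f"got [{seps.min():.1f}, {seps.max():.1f}]"
                )


def default_montage(cohort: str = "adult") -> ProbeGeometry:
    """The 22-channel occipital montage for the requested cap size.

    Optodes sit on a 3x5 grid centred on the occiput; alternating grid
    cells carry sources (8) and detectors (7). Grid spacing is chosen per
    cohort so channel separations fall in 20-44 mm (adult caps) or
    22-30 mm (child caps).
    """
    if cohort not in _SEPARATION_RANGE_MM:
        raise ValidationError(f"cohort must be 'adult' or 'child', got {cohort!r}")
    dx, dy = (3.5, 3.0) if cohort == "adult" else (2.6, 2.2)
    sources, detectors = [], []
    kind = {}  # (row, col) -> ("S"|"D", index)
    for r in range(3):
        for c in range(5):
            pos = ((c - 2) * dx, (r - 1) * dy, 0.0)
            if (r + c) % 2 == 0:
                kind[(r, c)] = ("S", len(sources))
                sources.append(pos)
            else:
                kind[(r, c)] = ("D", len(detectors))
                detectors.append(pos)
    channels = []
    for r in range(3):
        for c in range(5):
            for r2, c2 in ((r, c + 1), (r + 1, c)):
                if r2 > 2 or c2 > 4:
                    continue
                (k1, i1), (k2, i2) = kind[(r, c)], kind[(r2, c2)]
                if k1 == "S":
                    channels.append((i1, i2))
                else:
                    channels.append((i2, i1))
    geom = ProbeGeometry(np.array(sources), np.array(detectors), channels)
    geom.validate(cohort)
    return geom


def write_montage(geom: ProbeGeometry, path: str | Path) -> None:
    payload = {
        "source_pos_cm": geom.source_pos_cm.tolist(),
        "detector_pos_cm": geom.detector_pos_cm.tolist(),
        "channels": [list(ch) for ch in geom.channels],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_montage(path: str | Path) -> ProbeGeometry:
    payload = json.loads(Path(path).read_text())
    return ProbeGeometry(
        np.array(payload["source_pos_cm"]),
        np.array(payload["detector_pos_cm"]),
        [tuple(ch) for ch in payload["channels"]],
    )


# ---------------------------------------------------------------------------
# recordings

@dataclass
class Recording:
    """Raw two-wavelength CW-fNIRS intensity recording.

    ``intensity`` has shape ``(n_channels, 2, n_samples)`` in arbitrary
    detector units (strictly positive), sampled at ``fs`` Hz (10.2 by
    default); wavelength axis order follows ``wavelengths`` (760, 850 nm).
    """

    intensity: np.ndarray
    fs: float
    geometry: ProbeGeometry
    wavelengths: tuple[float, float] = WAVELENGTHS_NM
    subject_id: str = ""
    cohort: str = "adult"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.wavelengths) != 2:
            raise ValidationError("exactly two wavelengths are required")
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValidationError(
                "intensity must have shape (n_channels, 2 wavelengths, n_samples)"
            )
        if self.intensity.shape[0] != self.geometry.n_channels:
            raise ValidationError("channel count does not match montage")
        if not np.all(self.intensity > 0):
            raise ValidationError("intensities must be strictly positive")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as SNIRF (``.snirf``) or the plain-text dialect."""
    path = Path(path)
    if path.suffix == ".snirf":
        _write_snirf(rec, path)
    else:
        _write_text(rec, path)


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".snirf":
        return _read_snirf(path)
    return _read_text(path)


def _write_snirf(rec: Recording, path: Path) -> None:
    n_ch, _, n_t = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("cohort", data=rec.cohort)
        meta.create_dataset("LengthUnit", data="cm")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        probe.create_dataset("sourcePos3D", data=rec.geometry.source_pos_cm)
        probe.create_dataset("detectorPos3D", data=rec.geometry.detector_pos_cm)
        data = nirs.create_group("data1")
        # measurement columns: all channels at wl 1, then all at wl 2
        series = np.concatenate(
            [rec.intensity[:, 0, :].T, rec.intensity[:, 1, :].T], axis=1
        )
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_t) / rec.fs)
        for j in range(2 * n_ch):
            ch = j % n_ch
            wl = j // n_ch
            ml = data.create_group(f"measurementList{j + 1}")
            ml.create_dataset("sourceIndex", data=rec.geometry.channels[ch][0] + 1)
            ml.create_dataset("detectorIndex", data=rec.geometry.channels[ch][1] + 1)
            ml.create_dataset("wavelengthIndex", data=wl + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)


def _read_snirf(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        try:
            nirs = f["nirs"] if "nirs" in f else f["nirs1"]
            probe = nirs["probe"]
            wavelengths = np.asarray(probe["wavelengths"])
            src = np.asarray(probe["sourcePos3D"])
            det = np.asarray(probe["detectorPos3D"])
            data = nirs["data1"]
            series = np.asarray(data["dataTimeSeries"])
            time = np.asarray(data["time"])
            mls = sorted(
                (k for k in data.keys() if k.startswith("measurementList")),
                key=lambda k: int(k[len("measurementList"):]),
            )
            meta = nirs["metaDataTags"]
            subject = _h5str(meta["SubjectID"]) if "SubjectID" in meta else ""
            cohort = _h5str(meta["cohort"]) if "cohort" in meta else "adult"
        except KeyError as exc:
            raise FormatError(f"not a readable SNIRF file: missing {exc}") from exc
        if len(wavelengths) != 2:
            raise FormatError("SNIRF file must carry exactly two wavelengths")
        pairs, wl_idx = [], []
        for k in mls:
            ml = data[k]
            pairs.append((int(np.asarray(ml["sourceIndex"])) - 1,
                          int(np.asarray(ml["detectorIndex"])) - 1))
            wl_idx.append(int(np.asarray(ml["wavelengthIndex"])) - 1)
    n_meas = series.shape[1]
    n_ch = n_meas // 2
    channels = pairs[:n_ch]
    intensity = np.empty((n_ch, 2, series.shape[0]))
    for j in range(n_meas):
        ch = channels.index(pairs[j])
        intensity[ch, wl_idx[j], :] = series[:, j]
    fs = 1.0 / np.median(np.diff(time))
    geom = ProbeGeometry(src, det, channels)
    return Recording(intensity=intensity, fs=float(fs), geometry=geom,
                     wavelengths=tuple(wavelengths), subject_id=subject,
                     cohort=cohort)


def _h5str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _write_text(rec: Recording, path: Path) -> None:
    n_ch = rec.n_channels
    montage = {
        "source_pos_cm": rec.geometry.source_pos_cm.tolist(),
        "detector_pos_cm": rec.geometry.detector_pos_cm.tolist(),
        "channels": [list(ch) for ch in rec.geometry.channels],
    }
    cols = [f"ch{c + 1:02d}_{int(w)}" for w in rec.wavelengths for c in range(n_ch)]
    with open(path, "w") as fh:
        fh.write("# hemovis-recording v1\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# cohort: {rec.cohort}\n")
        fh.write(f"# fs: {rec.fs!r}\n")
        fh.write(f"# wavelengths: {rec.wavelengths[0]:g} {rec.wavelengths[1]:g}\n")
        fh.write(f"# montage: {json.dumps(montage)}\n")
        fh.write("\t".join(cols) + "\n")
        block = np.concatenate([rec.intensity[:, 0, :].T, rec.intensity[:, 1, :].T],
                               axis=1)
        np.savetxt(fh, block, delimiter="\t", fmt="%.17g")


def _read_text(path: Path) -> Recording:
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# hemovis-recording"):
            raise FormatError(f"{path} is not a hemovis text recording")
        n_header += 1
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition(":")
            header[key.strip()] = value.strip()
    for req in ("fs", "wavelengths", "montage"):
        if req not in header:
            raise FormatError(f"missing header field {req!r}")
    wavelengths = tuple(float(w) for w in header["wavelengths"].split())
    if len(wavelengths) != 2:
        raise FormatError("recording must carry exactly two wavelengths")
    montage = json.loads(header["montage"])
    geom = ProbeGeometry(
        np.array(montage["source_pos_cm"]),
        np.array(montage["detector_pos_cm"]),
        [tuple(ch) for ch in montage["channels"]],
    )
    block = np.loadtxt(path, delimiter="\t", skiprows=n_header + 1, ndmin=2)
    n_ch = geom.n_channels
    if block.shape[1] != 2 * n_ch:
        raise FormatError("column count does not match montage")
    intensity = np.stack([block[:, :n_ch].T, block[:, n_ch:].T], axis=1)
    return Recording(intensity=intensity, fs=float(header["fs"]), geometry=geom,
                     wavelengths=wavelengths,
                     subject_id=header.get("subject_id", ""),
                     cohort=header.get("cohort", "adult"))


# ---------------------------------------------------------------------------
# events

def write_events(schedule: TrialSchedule, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s\tduration_s\tcondition\n")
        for onset, cond in schedule.trials:
            fh.write(f"{onset:g}\t{schedule.on_duration_s:g}\t{cond}\n")


def read_events(path: str | Path) -> TrialSchedule:
    """Parse a TSV events file into a validated :class:`TrialSchedule`.

    Rows may appear in any order on disk; trials are sorted by onset. The
    off duration is inferred from the spacing between consecutive onsets.
    Overlapping trials raise a validation error.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "condition"}
    if not required.issubset(df.columns):
        raise FormatError(f"events file must have columns {sorted(required)}")
    if len(df) == 0:
        return TrialSchedule(trials=[], on_duration_s=1.0, off_duration_s=0.0)
    df = df.sort_values("onset_s").reset_index(drop=True)
    durations = df["duration_s"].unique()
    on_s = float(durations[0])
    if len(durations) > 1:
        raise ValidationError("trials must share a common duration")
    onsets = df["onset_s"].to_numpy(dtype=float)
    gaps = np.diff(onsets)
    if len(gaps) and gaps.min() < on_s - 1e-9:
        raise ValidationError("overlapping trials in events file")
    off_s = float(gaps[0] - on_s) if len(gaps) else 0.0
    trials = list(zip(onsets.tolist(), df["condition"].astype(str).tolist()))
    sched = TrialSchedule(trials=trials, on_duration_s=on_s, off_duration_s=off_s)
    sched.validate(strict_spacing=False)
    return sched


# ---------------------------------------------------------------------------
# AQ questionnaires

@dataclass(frozen=True)
class AQRecord:
    """Scored Autism-Spectrum Quotient: total plus the five subscales."""

    version: str  # "adult" | "child"
    total: int
    AQ_S: int
    AQ_C: int
    AQ_A: int
    AQ_D: int
    AQ_I: int

    def __post_init__(self) -> None:
        if self.version not in ("adult", "child"):
            raise ValidationError("version must be 'adult' or 'child'")
        sub_max, tot_max = (10, 50) if self.version == "adult" else (30, 150)
        subs = (self.AQ_S, self.AQ_C, self.AQ_A, self.AQ_D, self.AQ_I)
        if not all(0 <= s <= sub_max for s in subs):
            raise ValidationError(f"subscales must lie in [0, {sub_max}]")
        if not 0 <= self.total <= tot_max:
            raise ValidationError(f"total must lie in [0, {tot_max}]")
        if self.total != sum(subs):
            raise ValidationError("total must equal the sum of subscales")

    @property
    def subscales(self) -> dict[str, int]:
        return {"AQ_S": self.AQ_S, "AQ_C": self.AQ_C, "AQ_A": self.AQ_A,
                "AQ_D": self.AQ_D, "AQ_I": self.AQ_I}


def load_aq_keys() -> dict:
    with resources.files("hemovis.data").joinpath("aq_keys.json").open() as fh:
        return json.load(fh)


def score_aq(responses, version: str, keys: dict | None = None) -> AQRecord:
    """Score 50 Likert responses into total + subscale AQ scores.

    ``responses`` are integers 0-3 on the 4-point scale (0 = definitely
    agree, 1 = slightly agree, 2 = slightly disagree, 3 = definitely
    disagree), ordered by item number. Adult scoring assigns 1 point when
    the response is on the autistic side of the scale (slightly or
    strongly); child scoring keeps the 0-3 range per item, reverse-scoring
    disagree-keyed items so higher always means more autistic traits.
    """
    if version not in ("adult", "child"):
        raise ValidationError("version must be 'adult' or 'child'")
    keys = keys or load_aq_keys()
    resp = np.asarray(responses)
    if resp.shape != (keys["n_items"],):
        raise ValidationError(f"expected {keys['n_items']} responses, got {resp.shape}")
    if not np.issubdtype(resp.dtype, np.integer):
        if not np.allclose(resp, np.round(resp)):
            raise ValidationError("responses must be integers on the 0-3 scale")
        resp = resp.astype(int)
    if resp.min() < 0 or resp.max() > 3:
        raise ValidationError("responses must lie in {0, 1, 2, 3}")
    agree_keyed = np.zeros(keys["n_items"], dtype=bool)
    agree_keyed[np.asarray(keys["agree_keyed"]) - 1] = True
    if version == "adult":
        item_scores = np.where(agree_keyed, resp <= 1, resp >= 2).astype(int)
    else:
        item_scores = np.where(agree_keyed, 3 - resp, resp).astype(int)
    subs = {
        name: int(item_scores[np.asarray(items) - 1].sum())
        for name, items in keys["subscales"].items()
    }
    return AQRecord(version=version, total=int(item_scores.sum()), **subs)


def risk_flag(aq: AQRecord) -> bool:
    """Autism-risk screen: strictly above the clinical threshold.

    Thresholds are 32 (adult) and 76 (child); the comparison is strict
    because a score of exactly the adult threshold occurs in the reference
    cohort without being counted as above-threshold.
    """
    threshold = 32 if aq.version == "adult" else 76
    return aq.total > threshold


# ---------------------------------------------------------------------------
# tabular fixtures and AQ tables

def _load_table(name: str) -> pd.DataFrame:
    with resources.files("hemovis.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_adult_table() -> pd.DataFrame:
    """Demographics + AQ scores of the 40-subject adult reference cohort."""
    return _load_table("table1_adults.csv")


def load_child_table() -> pd.DataFrame:
    """Demographics + AQ scores of the 19-subject child reference cohort.

    One child (B10) has no questionnaire; the AQ columns are NaN for that
    row and are excluded listwise from statistics.
    """
    return _load_table("table2_children.csv")


_AQ_COLUMNS = ["subject_id", "version", "AQ", "AQ_S", "AQ_C", "AQ_A", "AQ_D", "AQ_I"]


def write_aq_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=_AQ_COLUMNS)


def read_aq_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_AQ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"AQ table missing columns {sorted(missing)}")
    return df
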