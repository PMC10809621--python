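"""Reading and writing wrist-wearable recordings in the E4-style CSV dialect.

One directory per subject-session holds ``BVP.csv``, ``EDA.csv``,
``TEMP.csv``, ``HR.csv``, ``IBI.csv`` (and optionally ``ACC.csv``).
Channel files carry a two-line header — line 1 the UTC start time in
seconds, line 2 the sampling rate in Hz — followed by one sample per line
(comma-separated triplets for the accelerometer). IBI files have no rate
line; rows after the start time are ``offset_seconds,duration_seconds``
beat events.

Study tables are plain CSVs: ``subjects.csv`` (subject_id, age, sex) and
``assessments.csv`` (subject_id, composite, timepoint, z_score, day).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "ChannelRecording",
    "IBIEvents",
    "SubjectTable",
    "AssessmentPair",
    "FormatError",
    "ValidationError",
    "read_channel",
    "write_channel",
    "read_ibi",
    "write_ibi",
    "read_subjects",
    "write_subjects",
    "read_assessments",
    "write_assessments",
    "CHANNEL_FILES",
    "NOMINAL_RATES",
    "COMPOSITES",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


class Channel(str, enum.Enum):
    BVP = "BVP"
    EDA = "EDA"
    TEMP = "TEMP"
    HR = "HR"
    ACC = "ACC"


#: canonical file name per channel within a session directory
CHANNEL_FILES = {
    Channel.BVP: "BVP.csv",
    Channel.EDA: "EDA.csv",
    Channel.TEMP: "TEMP.csv",
    Channel.HR: "HR.csv",
    Channel.ACC: "ACC.csv",
}

#: device-nominal sampling rates in Hz (HR cadence is firmware-defined;
#: 1 Hz is the conventional export rate and is not enforced on read)
NOMINAL_RATES = {
    Channel.BVP: 64.0,
    Channel.EDA: 4.0,
    Channel.TEMP: 4.0,
    Channel.HR: 1.0,
    Channel.ACC: 32.0,
}

#: the five neuropsychological composites consumed downstream
COMPOSITES = (
    "executive_function",
    "processing_speed",
    "immediate_memory",
    "delayed_memory",
    "global_cognition",
)

#: physiological upper bound on a plausible inter-beat interval (seconds)
MAX_IBI_S = 3.0


@dataclass
class ChannelRecording:
    """One gap-free uniformly sampled sensor channel.

    ``values`` is a 1-D float array (or (n, 3) for the accelerometer);
    sample *i* is timestamped ``start_time + i / sampling_rate``.
    """

    channel: Channel
    start_time: float
    sampling_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError(
                f"sampling_rate must be > 0, got {self.sampling_rate}"
            )
        if self.channel is Channel.ACC:
            if self.values.size and self.values.ndim != 2:
                raise ValidationError("ACC values must be (n, 3) triplets")
        elif self.values.ndim != 1:
            raise ValidationError("values must be one sample per row")

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def timestamps(self) -> np.ndarray:
        """UTC timestamps per sample, affine in the sample index."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class IBIEvents:
    """Irregular beat-event list: (offset from start, interval duration)."""

    start_time: float
    offsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    max_duration_s: float = MAX_IBI_S

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.offsets.shape != self.durations.shape:
            raise ValidationError("offsets and durations must align")
        if self.offsets.size:
            if np.any(np.diff(self.offsets) <= 0):
                raise ValidationError("IBI offsets must be strictly increasing")
            if np.any(self.durations <= 0):
                raise ValidationError("IBI durations must be positive")
            if np.any(self.durations >= self.max_duration_s):
                raise ValidationError(
                    f"IBI durations must be < {self.max_duration_s} s"
                )

    @property
    def n_events(self) -> int:
        return int(self.offsets.size)

    def beat_times(self) -> np.ndarray:
        """Absolute UTC beat times."""
        return self.start_time + self.offsets


@dataclass
class SubjectTable:
    """Demographics for the cohort: one row per subject."""

    frame: pd.DataFrame
    age_range: tuple[float, float] = (50.0, 70.0)

    def __post_init__(self) -> None:
        required = {"subject_id", "age", "sex"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"subjects table missing columns: {missing}")
        if self.frame["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id in subjects table")
        bad_sex = set(self.frame["sex"]) - {"female", "male"}
        if bad_sex:
            raise ValidationError(f"unknown sex values: {bad_sex}")
        lo, hi = self.age_range
        if ((self.frame["age"] < lo) | (self.frame["age"] > hi)).any():
            raise ValidationError(f"ages outside study range [{lo}, {hi}]")


@dataclass
class AssessmentPair:
    """Baseline and post-intervention composite z-scores for one subject."""

    subject_id: str
    baseline: dict[str, float]
    post: dict[str, float]
    baseline_day: int
    post_day: int

    def __post_init__(self) -> None:
        if self.post_day <= self.baseline_day:
            raise ValidationError("post_day must exceed baseline_day")
        for scores, label in ((self.baseline, "baseline"), (self.post, "post")):
            missing = set(COMPOSITES) - set(scores)
            if missing:
                raise ValidationError(
                    f"{label} scores incomplete for {self.subject_id}: {missing}"
                )


# ---------------------------------------------------------------------------
# channel files
# ---------------------------------------------------------------------------

def _read_header_line(lines: Sequence[str], row: int, what: str) -> float:
    if len(lines) <= row:
        raise FormatError(f"missing {what} on row {row + 1}")
    token = lines[row].split(",")[0].strip()
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"malformed {what} on row {row + 1}: {token!r}") from exc


def read_channel(path: str | Path, channel: Channel | str) -> ChannelRecording:
    """Parse a two-line-header channel CSV into a :class:`ChannelRecording`."""
    channel = Channel(channel)
    lines = Path(path).read_text().splitlines()
    start = _read_header_line(lines, 0, "start timestamp")
    rate = _read_header_line(lines, 1, "sampling rate")
    if rate <= 0:
        raise ValidationError(f"non-positive sampling rate in {path}")
    if len(lines) <= 2:
        values = np.empty((0, 3)) if channel is Channel.ACC else np.empty(0)
        return ChannelRecording(channel, start, rate, values)
    try:
        body = pd.read_csv(path, skiprows=2, header=None, dtype=float,
                           float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"malformed sample rows in {path}: {exc}") from exc
    if channel is Channel.ACC:
        if body.shape[1] != 3:
            raise FormatError(f"ACC rows must be x,y,z triplets in {path}")
        values = body.to_numpy()
    else:
        if body.shape[1] != 1:
            raise FormatError(f"expected one sample per row in {path}")
        values = body.to_numpy().ravel()
    return ChannelRecording(channel, start, rate, values)


def write_channel(
    rec: ChannelRecording, path: str | Path, decimals: int | None = None
) -> Path:
    """Serialize a recording so that :func:`read_channel` inverts it.

    With ``decimals=None`` samples are written in shortest round-trip form
    (bit-exact re-read); a fixed decimal count is much faster for long
    synthetic signals where full float precision carries no information.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{float(rec.start_time)!r}\n{float(rec.sampling_rate)!r}\n")
        if rec.channel is Channel.ACC:
            for row in rec.values:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")
        elif rec.values.size:
            if decimals is None:
                fh.write("\n".join(rec.values.astype(str)) + "\n")
            else:
                fmt = f"%.{decimals}f\n" * rec.values.size
                fh.write(fmt % tuple(rec.values))
    return path


def read_ibi(path: str | Path) -> IBIEvents:
    """Parse an IBI event file (start timestamp, then offset,duration rows)."""
    lines = Path(path).read_text().splitlines()
    start = _read_header_line(lines, 0, "start timestamp")
    offsets, durations = [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split(",")
        if len(parts) != 2:
            raise FormatError(f"IBI row must be offset,duration: {ln!r}")
        offsets.append(float(parts[0]))
        durations.append(float(parts[1]))
    return IBIEvents(start, np.array(offsets), np.array(durations))


def write_ibi(ev: IBIEvents, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{float(ev.start_time)!r}\n")
        for off, dur in zip(ev.offsets, ev.durations):
            fh.write(f"{float(off)!r},{float(dur)!r}\n")
    return path


# ---------------------------------------------------------------------------
# study tables
# ---------------------------------------------------------------------------

def read_subjects(path: str | Path, age_range=(50.0, 70.0)) -> SubjectTable:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    return SubjectTable(frame, age_range=age_range)


def write_subjects(table: SubjectTable, path: str | Path) -> Path:
    table.frame.to_csv(path, index=False)
    return Path(path)


def read_assessments(path: str | Path) -> list[AssessmentPair]:
    """Read the long-form assessments table into per-subject score pairs."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "composite", "timepoint", "z_score", "day"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"assessments table missing columns: {missing}")
    pairs = []
    for sid, grp in frame.groupby("subject_id", sort=True):
        by_tp = {
            tp: dict(zip(sub["composite"], sub["z_score"]))
            for tp, sub in grp.groupby("timepoint")
        }
        days = {tp: int(sub["day"].iloc[0]) for tp, sub in grp.groupby("timepoint")}
        if set(by_tp) != {"baseline", "post"}:
            raise ValidationError(f"subject {sid} lacks baseline/post rows")
        pairs.append(
            AssessmentPair(
                subject_id=str(sid),
                baseline=by_tp["baseline"],
                post=by_tp["post"],
                baseline_day=days["baseline"],
                post_day=days["post"],
            )
        )
    return pairs


def write_assessments(pairs: Sequence[AssessmentPair], path: str | Path) -> Path:
    rows = []
    for p in pairs:
        for comp in COMPOSITES:
            rows.append((p.subject_id, comp, "baseline", p.baseline[comp], p.baseline_day))
            rows.append((p.subject_id, comp, "post", p.post[comp], p.post_day))
    pd.DataFrame(
        rows, columns=["subject_id", "composite", "timepoint", "z_score", "day"]
    ).to_csv(path, index=False)
    return Path(path)
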