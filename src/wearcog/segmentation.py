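"""Day-batched segmentation of wearable recordings into 5-minute windows.

Each day-length signal is regularized onto its channel's nominal-rate grid
and cut into fixed 5-min segments anchored at local midnight (00:00:00),
i.e. up to 288 segments per day. Minor interior gaps shorter than 30 s are
linearly interpolated; per-segment coverage (fraction of grid positions
observed *before* interpolation) gates validity at 50% for HR and skin
temperature and 70% for EDA and the PPG/BVP signal. A segment's beat-event
list must additionally agree with the HR channel: the number of detected
beats may not differ from the HR-implied count by more than 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_e4 import Channel, ChannelRecording, IBIEvents, ValidationError

__all__ = [
    "Segment",
    "QCThresholds",
    "SEGMENT_SECONDS",
    "segment_day",
    "fill_small_gaps",
    "coverage_valid",
    "ibi_beats_valid",
    "restrict_ibi",
]

SEGMENT_SECONDS = 300
SEGMENTS_PER_DAY = 86_400 // SEGMENT_SECONDS  # 288


@dataclass
class QCThresholds:
    """Validity thresholds; boundaries are inclusive."""

    min_coverage_hr_temp: float = 0.50
    min_coverage_eda_ppg: float = 0.70
    max_gap_s: float = 30.0
    ibi_tolerance: float = 0.10

    def min_coverage(self, channel: Channel) -> float:
        channel = Channel(channel)
        if channel in (Channel.HR, Channel.TEMP):
            return self.min_coverage_hr_temp
        if channel in (Channel.EDA, Channel.BVP):
            return self.min_coverage_eda_ppg
        raise ValidationError(f"no coverage threshold for channel {channel}")


@dataclass
class Segment:
    """One channel's data within a single 5-min wall-clock window.

    ``values`` lie on the nominal-rate grid with NaN where no sample was
    observed; ``coverage`` is the observed fraction before any gap repair.
    ``start_clock`` is seconds since local midnight, on the 5-min grid.
    """

    subject_id: str
    date: int  # local day index (days since epoch of the local clock)
    start_clock: int
    channel: Channel
    sampling_rate: float
    values: np.ndarray
    coverage: float

    @property
    def n_expected(self) -> int:
        return int(round(SEGMENT_SECONDS * self.sampling_rate))

    @property
    def start_time_local(self) -> float:
        """Local-clock timestamp (s) of the segment start."""
        return self.date * 86_400.0 + self.start_clock


def segment_day(
    rec: ChannelRecording,
    date: int,
    utc_offset: float = 0.0,
    subject_id: str = "",
) -> list[Segment]:
    """Cut one recording into the given local day's 5-min segments.

    Samples are snapped to the channel's nominal-rate grid by nearest
    timestamp; coincident hits on a grid slot are averaged. Every input
    sample falling inside the day is assigned to exactly one segment.
    """
    rate = rec.sampling_rate
    t_local = rec.timestamps() + utc_offset
    day_start = date * 86_400.0
    rel = t_local - day_start
    in_day = (rel >= 0) & (rel < 86_400.0)
    if not np.any(in_day):
        return []
    rel = rel[in_day]
    vals = np.asarray(rec.values, dtype=float)[in_day]

    # nearest grid slot over the whole day, then split per segment
    grid_idx = np.rint(rel * rate).astype(np.int64)
    n_day = int(round(86_400 * rate))
    grid_idx = np.clip(grid_idx, 0, n_day - 1)
    day_grid = np.full(n_day, np.nan)
    counts = np.zeros(n_day)
    np.add.at(counts, grid_idx, 1.0)
    sums = np.zeros(n_day)
    np.add.at(sums, grid_idx, vals)
    hit = counts > 0
    day_grid[hit] = sums[hit] / counts[hit]

    seg_len = int(round(SEGMENT_SECONDS * rate))
    segments = []
    for k in range(SEGMENTS_PER_DAY):
        chunk = day_grid[k * seg_len : (k + 1) * seg_len]
        observed = np.isfinite(chunk)
        if not observed.any():
            continue
        segments.append(
            Segment(
                subject_id=subject_id,
                date=date,
                start_clock=k * SEGMENT_SECONDS,
                channel=rec.channel,
                sampling_rate=rate,
                values=chunk.copy(),
                coverage=float(observed.mean()),
            )
        )
    return segments


def fill_small_gaps(seg: Segment, max_gap_s: float = 30.0) -> Segment:
    """Linearly interpolate interior NaN runs strictly shorter than ``max_gap_s``.

    Runs touching a segment edge have no flanking sample on one side and are
    left missing. Observed samples are never altered and ``coverage`` keeps
    its pre-repair value.
    """
    vals = seg.values.copy()
    isnan = ~np.isfinite(vals)
    if not isnan.any():
        return seg
    n = vals.size
    max_run = max_gap_s * seg.sampling_rate  # fill iff run length < this
    # locate NaN runs
    padded = np.concatenate(([False], isnan, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    for s, e in zip(starts, ends):
        if s == 0 or e == n:
            continue  # edge gap: no flank
        if (e - s) >= max_run:
            continue
        left, right = vals[s - 1], vals[e]
        w = np.arange(1, e - s + 1) / (e - s + 1)
        vals[s:e] = left + w * (right - left)
    return replace(seg, values=vals)


def coverage_valid(seg: Segment, th: QCThresholds | None = None) -> bool:
    """True iff pre-repair coverage meets the channel-specific threshold."""
    th = th or QCThresholds()
    return seg.coverage >= th.min_coverage(seg.channel)


def restrict_ibi(ibi: IBIEvents, seg_start_local: float, utc_offset: float = 0.0) -> IBIEvents:
    """Events whose beat time falls inside the 5-min window starting at
    ``seg_start_local`` (local-clock seconds)."""
    beat_local = ibi.beat_times() + utc_offset
    mask = (beat_local >= seg_start_local) & (beat_local < seg_start_local + SEGMENT_SECONDS)
    return IBIEvents(
        ibi.start_time, ibi.offsets[mask], ibi.durations[mask], ibi.max_duration_s
    )


def ibi_beats_valid(
    ibi_segment: IBIEvents,
    hr_segment: Segment | None,
    tol: float = 0.10,
) -> tuple[bool, str]:
    """Beat-count consistency check against the HR channel.

    Expected beats over the 5-min window = mean(HR in bpm) * 5; the event
    count must lie within ``tol`` (relative) of that, inclusive. Returns the
    flag and a reason code.
    """
    if hr_segment is None:
        return False, "no_hr_segment"
    hr_vals = hr_segment.values[np.isfinite(hr_segment.values)]
    if hr_vals.size == 0:
        return False, "empty_hr_segment"
    if ibi_segment.n_events == 0:
        return False, "no_ibi_events"
    expected = float(np.mean(hr_vals)) * (SEGMENT_SECONDS / 60.0)
    if expected <= 0:
        return False, "nonpositive_expected"
    if abs(ibi_segment.n_events - expected) <= tol * expected:
        return True, "ok"
    return False, "ibi_hr_mismatch"
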