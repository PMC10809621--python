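"""Reduction of 5-min feature rows to per-subject 10-day analysis rows.

Order of operations is fixed: drop windows without valid beat-event (IBI)
data (the most sensitive indicator of device misuse), restrict to the
calmest 5-h night window chosen by lowest pooled population mean HR,
compute daily medians (nights with at least four valid 5-min windows),
average daily medians over consecutive 10-day intervals, and finally prune
redundant features (squared Pearson correlation >= 0.95) from the
interval-level matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_REGISTRY, FeatureVector
from .io_e4 import ValidationError
from .segmentation import SEGMENT_SECONDS

__all__ = [
    "NightWindow",
    "feature_table",
    "require_ibi",
    "select_night_window",
    "daily_aggregate",
    "interval_aggregate",
    "drop_redundant_features",
]

KEY_COLS = ["subject_id", "date", "start_clock"]
DAY_S = 86_400


@dataclass
class NightWindow:
    """Contiguous wall-clock window (seconds since local midnight)."""

    start_clock: int
    duration_s: int = 5 * 3600

    @property
    def end_clock(self) -> int:
        return self.start_clock + self.duration_s

    def contains(self, clock: int | np.ndarray) -> np.ndarray:
        return ((np.asarray(clock) - self.start_clock) % DAY_S) < self.duration_s


def feature_table(fvs: list[FeatureVector]) -> pd.DataFrame:
    """Wide frame of 5-min feature rows with per-group validity columns."""
    registry_names = [n for n, _ in FEATURE_REGISTRY]
    rows = []
    for fv in fvs:
        row: dict = {
            "subject_id": fv.subject_id,
            "date": fv.date,
            "start_clock": fv.start_clock,
        }
        row.update({n: fv.values.get(n, np.nan) for n in registry_names})
        row.update({f"valid_{g}": v for g, v in fv.group_valid.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def require_ibi(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep only 5-min rows whose IBI group passed the HR-consistency check."""
    if "valid_IBI" not in rows.columns:
        raise ValidationError("rows lack the valid_IBI flag column")
    return rows[rows["valid_IBI"].astype(bool)].reset_index(drop=True)


def select_night_window(
    hr_rows: pd.DataFrame,
    candidate_span: tuple[int, int] = (21 * 3600, 9 * 3600),
    duration_s: int = 5 * 3600,
    hr_col: str = "HRMean",
) -> NightWindow:
    """Choose the calmest window by lowest rolling population mean HR.

    ``hr_rows`` needs ``start_clock`` and an HR column; the per-slot
    population mean pools all subjects and days. Candidate windows are the
    5-min-aligned starts whose full span lies inside ``candidate_span``
    (which may wrap midnight, default 21:00–09:00); the window minimizing
    the mean of its covered slot means wins, ties to the earliest start in
    span order. Windows with no data are excluded.
    """
    slot_means = hr_rows.dropna(subset=[hr_col]).groupby("start_clock")[hr_col].mean()
    span_start, span_end = candidate_span
    span_len = (span_end - span_start) % DAY_S or DAY_S
    if duration_s > span_len:
        raise ValidationError("window duration exceeds candidate span")
    n_starts = (span_len - duration_s) // SEGMENT_SECONDS + 1
    best: tuple[float, int] | None = None
    for k in range(int(n_starts)):
        start = (span_start + k * SEGMENT_SECONDS) % DAY_S
        slots = [(start + j * SEGMENT_SECONDS) % DAY_S
                 for j in range(duration_s // SEGMENT_SECONDS)]
        present = [s for s in slots if s in slot_means.index]
        if not present:
            continue
        mean_hr = float(slot_means.loc[present].mean())
        if best is None or mean_hr < best[0]:
            best = (mean_hr, start)
    if best is None:
        raise ValidationError("no candidate window contains HR data")
    return NightWindow(start_clock=best[1], duration_s=duration_s)


def daily_aggregate(
    rows: pd.DataFrame,
    window: NightWindow,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Nightly medians of each feature over valid 5-min windows.

    A night is keyed to the calendar date on which the window starts (a
    window spanning midnight books post-midnight rows to the previous
    date). Nights with fewer than ``min_samples`` rows are dropped.
    """
    feature_cols = [n for n, _ in FEATURE_REGISTRY if n in rows.columns]
    sub = rows[window.contains(rows["start_clock"].to_numpy())].copy()
    if sub.empty:
        return pd.DataFrame(columns=["subject_id", "date", "n_samples"] + feature_cols)
    wrapped = sub["start_clock"].to_numpy() < window.start_clock
    sub["night_date"] = sub["date"].to_numpy() - wrapped.astype(int)
    out = []
    for (sid, night), grp in sub.groupby(["subject_id", "night_date"], sort=True):
        if len(grp) < min_samples:
            continue
        rec = {"subject_id": sid, "date": night, "n_samples": len(grp)}
        rec.update(grp[feature_cols].median(skipna=True).to_dict())
        out.append(rec)
    return pd.DataFrame(out)


def interval_aggregate(
    daily: pd.DataFrame,
    interval_days: int = 10,
    observation_days: int = 70,
    anchor: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Means of daily medians over consecutive 10-day intervals.

    Interval *i* (1-based) covers days [interval_days*(i-1), interval_days*i)
    relative to each subject's anchor day (default: the subject's first
    observed night). A row exists only for intervals with at least one
    valid day; ``days_used`` records provenance.
    """
    feature_cols = [n for n, _ in FEATURE_REGISTRY if n in daily.columns]
    n_intervals = observation_days // interval_days
    out = []
    for sid, grp in daily.groupby("subject_id", sort=True):
        day0 = anchor[sid] if anchor is not None else int(grp["date"].min())
        rel = grp["date"].to_numpy() - day0
        interval = rel // interval_days + 1
        for i in range(1, n_intervals + 1):
            sel = grp[interval == i]
            if sel.empty:
                continue
            rec = {"subject_id": sid, "interval": i, "days_used": len(sel)}
            rec.update(sel[feature_cols].mean(skipna=True).to_dict())
            out.append(rec)
    return pd.DataFrame(out)


def drop_redundant_features(
    matrix: pd.DataFrame,
    r2_threshold: float = 0.95,
    order: list[str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Greedy redundancy pruning in frozen registry order.

    Zero-variance columns are dropped first; then a column is dropped when
    its squared Pearson correlation with any already-kept column meets the
    threshold. Returns (kept, {dropped: reason}).
    """
    if len(matrix) < 3:
        raise ValidationError("need at least 3 rows to assess redundancy")
    if order is None:
        registry = [n for n, _ in FEATURE_REGISTRY]
        order = [n for n in registry if n in matrix.columns] + [
            c for c in matrix.columns if c not in registry
        ]
    kept: list[str] = []
    dropped: dict[str, str] = {}
    corr = matrix[order].corr()  # pairwise-complete Pearson
    for col in order:
        vals = matrix[col].dropna()
        if vals.size < 3 or float(np.std(vals)) == 0.0:
            dropped[col] = "zero_variance"
            continue
        redundant = None
        for k in kept:
            r = corr.loc[col, k]
            if np.isfinite(r) and r * r >= r2_threshold:
                redundant = k
                break
        if redundant is not None:
            dropped[col] = f"r2_with_{redundant}"
        else:
            kept.append(col)
    return kept, dropped
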