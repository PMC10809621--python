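"""Per-segment physiological feature catalogue.

For each valid 5-min segment the catalogue covers:

* heart-rate variability computed twice — from the device's inter-beat
  events (IBI) and from beats detected in the raw PPG/BVP signal with the
  Elgendi two-moving-average peak detector — spanning time-domain
  statistics, FFT band powers of the interpolated tachogram, and nonlinear
  Poincaré / heart-rate-asymmetry / fragmentation indices;
* electrodermal activity decomposed into tonic and phasic components with
  skin-conductance-response detection and a sympathetic-band spectral index;
* heart-rate and skin-temperature summary statistics, plus band powers of
  the continuous HR signal.

Feature names form a frozen registry so that downstream pruning and
selection are deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import interpolate, signal, stats

from .io_e4 import Channel, IBIEvents, ValidationError
from .segmentation import SEGMENT_SECONDS, QCThresholds, Segment, coverage_valid

__all__ = [
    "NNSource",
    "NNSeries",
    "FeatureVector",
    "FEATURE_REGISTRY",
    "FEATURE_GROUPS",
    "HRV_FEATURE_NAMES",
    "elgendi_peaks",
    "clean_nn",
    "hrv_time",
    "hrv_freq",
    "hrv_freq_signal",
    "hrv_nonlinear",
    "hrv_all",
    "eda_process",
    "eda_features",
    "temp_features",
    "hr_features",
    "extract_all",
]

# interval plausibility bounds after cleaning, ms (exclusive)
NN_MIN_MS = 200.0
NN_MAX_MS = 3000.0

# spectral band edges, Hz
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
VHF_BAND = (0.40, 0.50)
TOTAL_BAND = (0.0, 0.50)
EDA_SYMPATHETIC_BAND = (0.045, 0.25)

# Elgendi detector constants: moving-average windows (s) and threshold offset
ELGENDI_PEAK_WINDOW_S = 0.111
ELGENDI_BEAT_WINDOW_S = 0.667
ELGENDI_BETA = 0.02

SCR_MIN_AMPLITUDE_US = 0.01


class NNSource(str, enum.Enum):
    IBI = "IBI"
    PPG = "PPG"


@dataclass
class NNSeries:
    """Cleaned normal-to-normal beat-interval sequence.

    ``times`` holds the time (s, local clock) of the beat *closing* each
    interval, so ``len(times) == len(intervals)``; ``intervals`` are in ms.
    """

    times: np.ndarray
    intervals: np.ndarray
    source: NNSource
    reason: str = "ok"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.source = NNSource(self.source)
        if self.times.shape != self.intervals.shape:
            raise ValidationError("times and intervals must align")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValidationError("NN intervals must be positive")

    @property
    def n(self) -> int:
        return int(self.intervals.size)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n > 1 else 0.0


def nn_from_ibi(ibi: IBIEvents, utc_offset: float = 0.0) -> NNSeries:
    """Beat events to an NN series (durations seconds -> ms)."""
    return NNSeries(
        times=ibi.beat_times() + utc_offset,
        intervals=ibi.durations * 1000.0,
        source=NNSource.IBI,
    )


# ---------------------------------------------------------------------------
# PPG beat detection (two-moving-average block detector)
# ---------------------------------------------------------------------------

def _nan_fill(values: np.ndarray) -> np.ndarray:
    """Linear interpolation over interior NaN, zeros at uncovered edges."""
    vals = np.asarray(values, dtype=float).copy()
    bad = ~np.isfinite(vals)
    if bad.all():
        return np.zeros_like(vals)
    if bad.any():
        idx = np.arange(vals.size)
        vals[bad] = np.interp(idx[bad], idx[~bad], vals[~bad])
    return vals


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = max(int(w), 1)
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def elgendi_peaks(bvp: Segment, beta: float = ELGENDI_BETA) -> NNSeries:
    """Detect systolic peaks in a 5-min BVP segment.

    Band-pass 0.5–8 Hz (order-2 Butterworth, zero-phase), clip negative
    lobes, square; compare a short moving average (peak window ~111 ms)
    against a long one (beat window ~667 ms) plus an offset ``beta`` times
    the mean squared signal. Contiguous blocks wider than the peak window
    each contribute one beat at the filtered signal's maximum.
    """
    fs = bvp.sampling_rate
    w1 = int(round(ELGENDI_PEAK_WINDOW_S * fs))
    w2 = int(round(ELGENDI_BEAT_WINDOW_S * fs))
    if w1 < 2 or fs < 16:
        raise ValidationError("sampling rate too low to resolve the pulse template")
    x = _nan_fill(bvp.values)
    sos = signal.butter(2, [0.5, 8.0], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    clipped = np.clip(filt, 0.0, None)
    squared = clipped**2
    ma_peak = _moving_average(squared, w1)
    ma_beat = _moving_average(squared, w2)
    thr = ma_beat + beta * float(np.mean(squared))
    blocks = ma_peak > thr
    if not blocks.any():
        return NNSeries(np.empty(0), np.empty(0), NNSource.PPG, reason="no_peaks")
    padded = np.concatenate(([False], blocks, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    peaks = [
        s + int(np.argmax(filt[s:e])) for s, e in zip(starts, ends) if (e - s) >= w1
    ]
    if len(peaks) < 2:
        return NNSeries(np.empty(0), np.empty(0), NNSource.PPG, reason="lt_2_peaks")
    t = bvp.start_time_local + np.asarray(peaks) / fs
    return NNSeries(times=t[1:], intervals=np.diff(t) * 1000.0, source=NNSource.PPG)


def clean_nn(nn: NNSeries) -> NNSeries:
    """Drop physiologically implausible intervals (outside 200–3000 ms)."""
    mask = (nn.intervals > NN_MIN_MS) & (nn.intervals < NN_MAX_MS)
    return NNSeries(nn.times[mask], nn.intervals[mask], nn.source, nn.reason)


# ---------------------------------------------------------------------------
# HRV: time domain
# ---------------------------------------------------------------------------

def hrv_time(nn: NNSeries) -> dict[str, float]:
    """Time-domain statistics of the NN intervals (ms).

    SDNN/SDSD use the sample SD (ddof=1); pNN thresholds are strict;
    MADNN is the scaled median absolute deviation (x1.4826).
    """
    x = nn.intervals
    if x.size < 3:
        return {}
    d = np.diff(x)
    mean = float(np.mean(x))
    median = float(np.median(x))
    mad = 1.4826 * float(np.median(np.abs(x - median)))
    q1, q3 = np.percentile(x, [25, 75])
    out = {
        "MeanNN": mean,
        "SDNN": float(np.std(x, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "SDSD": float(np.std(d, ddof=1)),
        "pNN50": 100.0 * float(np.mean(np.abs(d) > 50.0)),
        "pNN20": 100.0 * float(np.mean(np.abs(d) > 20.0)),
        "CVNN": float(np.std(x, ddof=1)) / mean,
        "MedianNN": median,
        "MADNN": mad,
        "MCVNN": mad / median,
        "IQRNN": float(q3 - q1),
        "MinNN": float(np.min(x)),
        "MaxNN": float(np.max(x)),
        "RangeNN": float(np.max(x) - np.min(x)),
        "MeanHR": float(np.mean(60_000.0 / x)),
        "CVSD": float(np.sqrt(np.mean(d**2))) / mean,
        "Prc20NN": float(np.percentile(x, 20)),
        "Prc80NN": float(np.percentile(x, 80)),
    }
    return out


# ---------------------------------------------------------------------------
# HRV: frequency domain
# ---------------------------------------------------------------------------

def _band_powers(freqs: np.ndarray, psd: np.ndarray, prefix: str = "") -> dict[str, float]:
    def integrate(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = integrate(*LF_BAND)
    hf = integrate(*HF_BAND)
    vhf = integrate(*VHF_BAND)
    total = integrate(*TOTAL_BAND)
    out = {
        f"{prefix}LF": lf,
        f"{prefix}HF": hf,
        f"{prefix}VHF": vhf,
        f"{prefix}TotalPower": total,
        f"{prefix}LFHF": lf / hf if hf > 0 else np.nan,
        f"{prefix}LFn": lf / (lf + hf) if (lf + hf) > 0 else np.nan,
        f"{prefix}HFn": hf / (lf + hf) if (lf + hf) > 0 else np.nan,
        f"{prefix}LnHF": float(np.log(hf)) if hf > 0 else np.nan,
    }
    return out


def hrv_freq(nn: NNSeries, resample_hz: float = 4.0) -> dict[str, float]:
    """Band powers of the tachogram.

    The NN series is cubic-interpolated onto a uniform grid (4 Hz),
    linearly detrended, and Welch-transformed (120-s Hann segments, 50%
    overlap); band powers integrate the PSD by the trapezoid rule over
    LF 0.04–0.15, HF 0.15–0.40 and VHF 0.40–0.50 Hz. Units: ms^2.
    """
    if nn.n < 4 or nn.span < 30.0:
        return {}
    t = nn.times
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tachogram = interpolate.interp1d(t, nn.intervals, kind="cubic")(grid)
    tachogram = signal.detrend(tachogram, type="linear")
    nperseg = min(int(120 * resample_hz), tachogram.size)
    freqs, psd = signal.welch(
        tachogram, fs=resample_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return _band_powers(freqs, psd)


def hrv_freq_signal(seg: Segment, prefix: str = "HRSpec") -> dict[str, float]:
    """Same band-power machinery applied to the continuous HR signal (bpm^2)."""
    vals = seg.values[np.isfinite(seg.values)]
    if vals.size < 8:
        return {}
    fs = seg.sampling_rate
    vals = signal.detrend(vals, type="linear")
    nperseg = min(int(120 * fs), vals.size)
    freqs, psd = signal.welch(
        vals, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return _band_powers(freqs, psd, prefix=prefix)


# ---------------------------------------------------------------------------
# HRV: nonlinear (Poincaré, asymmetry, fragmentation)
# ---------------------------------------------------------------------------

def _runs(seq: np.ndarray) -> list[int]:
    """Lengths of maximal runs of equal consecutive values."""
    if seq.size == 0:
        return []
    change = np.flatnonzero(seq[1:] != seq[:-1])
    edges = np.concatenate(([0], change + 1, [seq.size]))
    return list(np.diff(edges))


def hrv_nonlinear(nn: NNSeries) -> dict[str, float]:
    """Poincaré-plot geometry, heart-rate asymmetry and fragmentation.

    SD1^2 = Var(ΔNN)/2 and SD2^2 = 2 Var(NN) − Var(ΔNN)/2 with population
    variances (SD2^2 floored at zero). With axis lengths T = 4 SD1 and
    L = 4 SD2: CSI = L/T, CVI = log10(L·T), modified CSI = L^2/T. Asymmetry
    partitions split the squared distances to / along the identity line by
    decelerations (above the line) vs accelerations. Fragmentation indices
    (PIP, IALS, PSS, PAS) are computed on the sign sequence of ΔNN.
    """
    x = nn.intervals
    if x.size < 4:
        return {}
    d = np.diff(x)
    var_nn = float(np.var(x))
    var_d = float(np.var(d))
    sd1_sq = 0.5 * var_d
    sd2_sq_raw = 2.0 * var_nn - 0.5 * var_d
    sd1 = float(np.sqrt(sd1_sq))
    sd2 = float(np.sqrt(max(sd2_sq_raw, 0.0)))
    out: dict[str, float] = {"SD1": sd1, "SD2": sd2}
    if sd1 > 0 and sd2 > 0:
        t_ax, l_ax = 4.0 * sd1, 4.0 * sd2
        out.update(
            SD1SD2=sd1 / sd2,
            EllipseArea=float(np.pi * sd1 * sd2),
            CSI=l_ax / t_ax,
            CVI=float(np.log10(l_ax * t_ax)),
            CSIModified=l_ax**2 / t_ax,
        )
    else:
        out.update(
            SD1SD2=np.nan, EllipseArea=np.nan, CSI=np.nan, CVI=np.nan, CSIModified=np.nan
        )

    # asymmetry: signed distance to the identity line per Poincaré point
    xi, xj = x[:-1], x[1:]
    dist = (xj - xi) / np.sqrt(2.0)
    above = dist > 0  # decelerations
    below = dist < 0
    off = above | below
    ss_all = float(np.sum(dist**2))
    n_pairs = dist.size
    if ss_all > 0 and off.any():
        out["GuzikIndex"] = 100.0 * float(np.sum(dist[above] ** 2)) / ss_all
        out["PortaIndex"] = 100.0 * float(np.count_nonzero(below)) / float(
            np.count_nonzero(off)
        )
    else:
        out["GuzikIndex"] = np.nan
        out["PortaIndex"] = np.nan
    mean_centered = (xi - np.mean(x)) + (xj - np.mean(x))
    along = mean_centered / np.sqrt(2.0)
    sd1d_sq = float(np.sum(dist[above] ** 2)) / n_pairs
    sd1a_sq = float(np.sum(dist[below] ** 2)) / n_pairs
    sd2d_sq = float(np.sum(along[above] ** 2)) / n_pairs
    sd2a_sq = float(np.sum(along[below] ** 2)) / n_pairs
    out.update(
        SD1d=float(np.sqrt(sd1d_sq)),
        SD1a=float(np.sqrt(sd1a_sq)),
        SD2d=float(np.sqrt(sd2d_sq)),
        SD2a=float(np.sqrt(sd2a_sq)),
        C1d=sd1d_sq / (sd1d_sq + sd1a_sq) if (sd1d_sq + sd1a_sq) > 0 else np.nan,
        C1a=sd1a_sq / (sd1d_sq + sd1a_sq) if (sd1d_sq + sd1a_sq) > 0 else np.nan,
    )

    # fragmentation on the sign sequence of successive differences
    s = np.sign(d)
    n_d = s.size
    inflections = int(np.count_nonzero(s[1:] != s[:-1]))
    out["PIP"] = 100.0 * inflections / n_d
    runs = _runs(s)
    out["IALS"] = 1.0 / float(np.mean(runs)) if runs else np.nan
    short = sum(r for r in runs if r < 3)
    out["PSS"] = 100.0 * short / n_d
    # alternation runs: maximal stretches where the sign flips at every step
    flip = s[1:] == -s[:-1]
    alt_total = 0
    if flip.size:
        padded = np.concatenate(([False], flip, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        for a, b in zip(starts, ends):
            run_len = (b - a) + 1  # number of diffs in the alternation run
            if run_len >= 4:
                alt_total += run_len
    out["PAS"] = 100.0 * alt_total / n_d
    return out


def hrv_all(nn: NNSeries) -> dict[str, float]:
    """Full 45-feature HRV block for one NN series (unprefixed names)."""
    nn = clean_nn(nn)
    out: dict[str, float] = {}
    out.update(hrv_time(nn))
    out.update(hrv_freq(nn))
    out.update(hrv_nonlinear(nn))
    return out


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def eda_process(
    eda: Segment,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, float]]]:
    """Decompose a 4-Hz EDA segment into tonic and phasic components.

    Order-4 Butterworth low-pass at 1 Hz denoises; the tonic level is a
    second-order zero-phase low-pass at 0.05 Hz (a first-order Butterworth
    run forward-backward: real poles, so the tonic estimate cannot overshoot
    and inject spurious phasic rebounds); phasic = denoised − tonic.
    Skin-conductance responses are phasic local maxima at least 0.01 µS
    above zero that rise at least 0.01 µS above the preceding trough;
    returned as (index, amplitude).
    """
    fs = eda.sampling_rate
    x = _nan_fill(eda.values)
    sos_lp = signal.butter(4, 1.0, btype="lowpass", fs=fs, output="sos")
    denoised = signal.sosfiltfilt(sos_lp, x)
    sos_tonic = signal.butter(1, 0.05, btype="lowpass", fs=fs, output="sos")
    tonic = signal.sosfiltfilt(sos_tonic, denoised)
    phasic = denoised - tonic
    peaks, _ = signal.find_peaks(phasic)
    scrs: list[tuple[int, float]] = []
    prev = 0
    for pk in peaks:
        trough = float(np.min(phasic[prev : pk + 1]))
        amp = float(phasic[pk]) - trough
        if amp >= SCR_MIN_AMPLITUDE_US and phasic[pk] >= SCR_MIN_AMPLITUDE_US:
            scrs.append((int(pk), amp))
            prev = pk
    return tonic, phasic, scrs


def eda_features(
    tonic: np.ndarray,
    phasic: np.ndarray,
    scrs: list[tuple[int, float]],
    fs: float = 4.0,
) -> dict[str, float]:
    """Summary statistics plus the sympathetic-band spectral index.

    SympatheticPower integrates the Welch PSD of the phasic-path signal over
    0.045–0.25 Hz; the normalized variant divides by total 0–0.5 Hz power.
    """
    minutes = tonic.size / fs / 60.0
    hours_axis = np.arange(tonic.size) / fs / 3600.0
    slope = float(np.polyfit(hours_axis, tonic, 1)[0]) if tonic.size > 1 else np.nan
    nperseg = min(int(120 * fs), phasic.size)
    freqs, psd = signal.welch(
        phasic, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )

    def integrate(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0

    symp = integrate(*EDA_SYMPATHETIC_BAND)
    total = integrate(0.0, 0.5)
    amps = [a for _, a in scrs]
    return {
        "TonicMean": float(np.mean(tonic)),
        "TonicSD": float(np.std(tonic, ddof=1)),
        "TonicSlope": slope,
        "TonicMin": float(np.min(tonic)),
        "TonicMax": float(np.max(tonic)),
        "PhasicMean": float(np.mean(phasic)),
        "PhasicSD": float(np.std(phasic, ddof=1)),
        "PhasicMax": float(np.max(phasic)),
        "SCRCount": float(len(scrs)),
        "SCRRate": len(scrs) / minutes if minutes > 0 else np.nan,
        "SCRMeanAmplitude": float(np.mean(amps)) if amps else 0.0,
        "SympatheticPower": symp,
        "SympatheticPowerNormalized": symp / total if total > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# temperature and HR statistics
# ---------------------------------------------------------------------------

def _stat_block(seg: Segment, prefix: str) -> dict[str, float]:
    finite = np.isfinite(seg.values)
    vals = seg.values[finite]
    if vals.size < 2:
        return {}
    t_hours = (np.arange(seg.values.size) / seg.sampling_rate / 3600.0)[finite]
    slope = float(np.polyfit(t_hours, vals, 1)[0])
    return {
        f"{prefix}Mean": float(np.mean(vals)),
        f"{prefix}Median": float(np.median(vals)),
        f"{prefix}SD": float(np.std(vals, ddof=1)),
        f"{prefix}Min": float(np.min(vals)),
        f"{prefix}Max": float(np.max(vals)),
        f"{prefix}Slope": slope,
    }


def temp_features(seg: Segment) -> dict[str, float]:
    """Mean/median/SD/min/max and least-squares slope (°C per hour)."""
    return _stat_block(seg, "Temp")


def hr_features(seg: Segment) -> dict[str, float]:
    """HR summary statistics (bpm; slope per hour) plus HR-signal band powers."""
    out = _stat_block(seg, "HR")
    if out:
        out.update(hrv_freq_signal(seg))
    return out


# ---------------------------------------------------------------------------
# registry and whole-window extraction
# ---------------------------------------------------------------------------

_TIME_NAMES = [
    "MeanNN", "SDNN", "RMSSD", "SDSD", "pNN50", "pNN20", "CVNN", "MedianNN",
    "MADNN", "MCVNN", "IQRNN", "MinNN", "MaxNN", "RangeNN", "MeanHR", "CVSD",
    "Prc20NN", "Prc80NN",
]
_FREQ_NAMES = ["LF", "HF", "VHF", "TotalPower", "LFHF", "LFn", "HFn", "LnHF"]
_NONLINEAR_NAMES = [
    "SD1", "SD2", "SD1SD2", "EllipseArea", "CSI", "CVI", "CSIModified",
    "GuzikIndex", "PortaIndex", "SD1d", "SD1a", "SD2d", "SD2a", "C1d", "C1a",
    "PIP", "IALS", "PSS", "PAS",
]
HRV_FEATURE_NAMES = _TIME_NAMES + _FREQ_NAMES + _NONLINEAR_NAMES  # 45

_EDA_NAMES = [
    "TonicMean", "TonicSD", "TonicSlope", "TonicMin", "TonicMax", "PhasicMean",
    "PhasicSD", "PhasicMax", "SCRCount", "SCRRate", "SCRMeanAmplitude",
    "SympatheticPower", "SympatheticPowerNormalized",
]
_HR_NAMES = ["HRMean", "HRMedian", "HRSD", "HRMin", "HRMax", "HRSlope"] + [
    f"HRSpec{n}" for n in _FREQ_NAMES
]
_TEMP_NAMES = ["TempMean", "TempMedian", "TempSD", "TempMin", "TempMax", "TempSlope"]

#: frozen registry: ordered (qualified name, group) pairs
FEATURE_REGISTRY: list[tuple[str, str]] = (
    [(f"PPG_{n}", "PPG") for n in HRV_FEATURE_NAMES]
    + [(f"IBI_{n}", "IBI") for n in HRV_FEATURE_NAMES]
    + [(f"EDA_{n}", "EDA") for n in _EDA_NAMES]
    + [(n, "HR") for n in _HR_NAMES]
    + [(n, "TEMP") for n in _TEMP_NAMES]
)
FEATURE_GROUPS = ("PPG", "IBI", "EDA", "HR", "TEMP")


@dataclass
class FeatureVector:
    """Named feature values for one 5-min window with per-group validity."""

    subject_id: str
    date: int
    start_clock: int
    values: dict[str, float] = field(default_factory=dict)
    group_valid: dict[str, bool] = field(default_factory=dict)


def extract_all(
    segments: Mapping[Channel | str, Segment],
    ibi_segment: IBIEvents | None = None,
    thresholds: QCThresholds | None = None,
    ibi_valid: bool | None = None,
    utc_offset: float = 0.0,
) -> FeatureVector:
    """Compute every catalogue feature whose source segment is valid.

    HRV is computed twice — from the device beat events and from the PPG
    peak detector. ``ibi_valid`` may carry a precomputed HR-consistency
    flag; otherwise it is derived here from the HR segment.
    """
    from .segmentation import ibi_beats_valid  # local to avoid cycle at import

    th = thresholds or QCThresholds()
    segs = {Channel(k): v for k, v in segments.items()}
    ref = next(iter(segs.values()))
    fv = FeatureVector(ref.subject_id, ref.date, ref.start_clock)

    valid = {g: False for g in FEATURE_GROUPS}
    for ch, group in ((Channel.BVP, "PPG"), (Channel.EDA, "EDA"),
                      (Channel.HR, "HR"), (Channel.TEMP, "TEMP")):
        if ch in segs:
            valid[group] = coverage_valid(segs[ch], th)
    if ibi_segment is not None:
        if ibi_valid is None:
            ibi_valid, _ = ibi_beats_valid(
                ibi_segment, segs.get(Channel.HR), th.ibi_tolerance
            )
        valid["IBI"] = bool(ibi_valid)
    fv.group_valid = valid

    if valid["PPG"]:
        nn = elgendi_peaks(segs[Channel.BVP])
        fv.values.update({f"PPG_{k}": v for k, v in hrv_all(nn).items()})
    if valid["IBI"] and ibi_segment is not None:
        nn = nn_from_ibi(ibi_segment, utc_offset)
        fv.values.update({f"IBI_{k}": v for k, v in hrv_all(nn).items()})
    if valid["EDA"]:
        tonic, phasic, scrs = eda_process(segs[Channel.EDA])
        fv.values.update(
            {f"EDA_{k}": v
             for k, v in eda_features(tonic, phasic, scrs,
                                      segs[Channel.EDA].sampling_rate).items()}
        )
    if valid["HR"]:
        fv.values.update(hr_features(segs[Channel.HR]))
    if valid["TEMP"]:
        fv.values.update(temp_features(segs[Channel.TEMP]))
    return fv
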