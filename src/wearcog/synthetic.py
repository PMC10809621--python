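"""Synthetic wearable cohorts with known signal–cognition coupling.

The generator writes complete on-disk datasets in the device CSV dialect —
nightly beat-interval series with controllable LF (0.10 Hz) / HF (0.25 Hz)
modulation rendered to a 64-Hz pulse waveform, electrodermal activity with
tonic drift and Bateman-shaped skin-conductance responses, slowly varying
skin temperature, a 1-Hz HR channel, and device beat events — together with
subject and assessment tables. Each subject carries a latent cognitive
trajectory (a Gompertz sigmoid between the two assessments); chosen
physiological parameters are linear in that latent score with configurable
slope, so every downstream stage has a recoverable ground truth.

Wear is night-dominant: sessions exist only around the night window, and
non-wear appears as whole missing nights, mirroring cohorts where only the
calm night hours are analyzable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_e4 import (
    COMPOSITES,
    AssessmentPair,
    Channel,
    ChannelRecording,
    IBIEvents,
    SubjectTable,
    ValidationError,
    write_assessments,
    write_channel,
    write_ibi,
    write_subjects,
)
from .features import NNSeries, NNSource
from .outcomes import GompertzShape, gompertz_series

__all__ = [
    "SimulationConfig",
    "TrueTrajectory",
    "simulate_rr_series",
    "rr_to_bvp",
    "simulate_eda",
    "simulate_temperature",
    "simulate_cognition",
    "generate_cohort",
]

LF_HZ = 0.10
HF_HZ = 0.25


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a 10-week night-wear protocol in older adults: 17
    analyzable subjects, 70 observation days in seven 10-day intervals,
    resting night heart period ~850 ms with modest LF/HF modulation, sparse
    nocturnal skin-conductance responses over a ~1.5 µS tonic level, and
    wrist temperature near 33.5 °C.
    """

    n_subjects: int = 17
    observation_days: int = 70
    interval_days: int = 10
    wear_nights_per_interval: int = 2
    segments_per_night: int = 4  # 5-min windows of full-sensor data per night
    night_start_clock: int = 1 * 3600  # wear block starts 01:00 local
    # beat-interval structure (ms)
    mean_rr_ms: float = 850.0
    lf_amp_ms: float = 20.0
    hf_amp_ms: float = 25.0
    jitter_sd_ms: float = 10.0
    # EDA
    tonic_level_us: float = 1.5
    tonic_drift_us_per_h: float = 0.1
    scr_rate_per_min: float = 2.0
    scr_amp_us: float = 0.3
    # temperature
    temp_mean_c: float = 33.5
    temp_circadian_amp_c: float = 0.5
    temp_noise_sd_c: float = 0.05
    # outcome model
    coupling: list[tuple[str, float]] = field(
        default_factory=lambda: [("hf_amp_ms", 12.0)]
    )
    coupling_outcome: str = "executive_function"
    outcome_noise_sd: float = 0.05
    gompertz_shape: GompertzShape = field(default_factory=GompertzShape)
    baseline_mean: float = -0.8
    baseline_sd: float = 0.5
    change_mean: float = 0.25
    change_sd: float = 0.35
    utc_offset: float = 0.0
    seed: int = 0

    @property
    def n_intervals(self) -> int:
        return self.observation_days // self.interval_days

    def __post_init__(self) -> None:
        if self.observation_days < 10:
            raise ValidationError("observation_days must be >= 10")
        for name in ("jitter_sd_ms", "scr_rate_per_min", "outcome_noise_sd",
                     "temp_noise_sd_c"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class TrueTrajectory:
    """Ground truth for one subject: latent composite values per interval and
    the physiological parameter values realized each wear night."""

    subject_id: str
    latent: dict[str, np.ndarray]  # composite -> per-interval values
    night_params: pd.DataFrame  # date, interval, and the per-night parameters


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def simulate_rr_series(
    mean_rr: float,
    lf_amp: float,
    hf_amp: float,
    jitter_sd: float,
    duration: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    t0: float = 0.0,
) -> NNSeries:
    """Beat intervals by direct modulation of the instantaneous heart period.

    interval(t) = mean_rr + lf_amp sin(2π 0.10 t) + hf_amp sin(2π 0.25 t)
    + N(0, jitter_sd) [ms]; beats accumulate until ``duration`` seconds are
    covered (last beat truncated).
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if mean_rr - abs(lf_amp) - abs(hf_amp) <= 6.0 * jitter_sd:
        raise ValidationError("modulation amplitudes would produce non-positive intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times, intervals = [], []
    t = 0.0
    n_guess = int(duration / mean_rr * 1000 * 1.5) + 16
    jitter = rng.normal(0.0, jitter_sd, size=n_guess) if jitter_sd > 0 else np.zeros(n_guess)
    k = 0
    while True:
        ivl = (mean_rr
               + lf_amp * np.sin(2 * np.pi * LF_HZ * t)
               + hf_amp * np.sin(2 * np.pi * HF_HZ * t))
        if k < n_guess:
            ivl += jitter[k]
        else:
            ivl += rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
        if ivl <= 0:
            raise ValidationError("generated a non-positive beat interval")
        t_next = t + ivl / 1000.0
        if t_next > duration:
            break
        times.append(t0 + t_next)
        intervals.append(ivl)
        t = t_next
        k += 1
    return NNSeries(np.asarray(times), np.asarray(intervals), NNSource.IBI)


def _pulse_template(fs: float, width_scale: float = 1.0) -> tuple[np.ndarray, int]:
    """Asymmetric pulse with its maximum at the central sample.

    Fast rise (σ 50 ms), slower decay (σ 120 ms) and a small dicrotic bump;
    returns (template, index of the peak sample).
    """
    half = 0.45 * width_scale
    t = np.arange(-half, half + 1e-9, 1.0 / fs)
    rise = np.exp(-(t**2) / (2 * (0.05 * width_scale) ** 2))
    decay = np.exp(-(t**2) / (2 * (0.12 * width_scale) ** 2))
    main = np.where(t < 0, rise, decay)
    dicrotic = 0.25 * np.exp(-((t - 0.25 * width_scale) ** 2) / (2 * (0.05 * width_scale) ** 2))
    template = main + dicrotic
    return template, int(np.argmax(template))


def rr_to_bvp(
    nn: NNSeries,
    fs: float = 64.0,
    amplitude: float = 1.0,
    width_scale: float = 1.0,
    noise_sd: float = 0.05,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    start_time: float | None = None,
) -> ChannelRecording:
    """Render an NN series to a pulse waveform (one template per beat).

    The template maximum lands on the beat time, so detected peak times are
    directly comparable to the generating beat times.
    """
    if nn.n == 0:
        raise ValidationError("empty NN series")
    if fs < 16:
        raise ValidationError("sampling rate too low to resolve the pulse template")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    first_beat = nn.times[0] - nn.intervals[0] / 1000.0
    beats = np.concatenate(([first_beat], nn.times))
    start = first_beat if start_time is None else start_time
    duration = float(nn.times[-1] - start) + 1.0
    n = int(round(duration * fs))
    sig = np.zeros(n)
    template, peak_idx = _pulse_template(fs, width_scale)
    for bt in beats:
        center = int(round((bt - start) * fs))
        lo = center - peak_idx
        hi = lo + template.size
        s0, s1 = max(lo, 0), min(hi, n)
        if s1 <= s0:
            continue
        sig[s0:s1] += amplitude * template[s0 - lo : s1 - lo]
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd * max(amplitude, 1e-12), size=n)
    return ChannelRecording(Channel.BVP, start, fs, sig)


def simulate_eda(
    tonic_level: float,
    drift: float,
    scr_rate: float,
    scr_amp: float,
    duration: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    fs: float = 4.0,
    tau1: float = 4.0,
    tau2: float = 0.75,
    start_time: float = 0.0,
    scr_times: np.ndarray | None = None,
    return_times: bool = False,
):
    """Tonic ramp plus Poisson-timed Bateman-shaped SCRs (µS, 4 Hz).

    Kernel A (e^{-t/τ1} − e^{-t/τ2}) with τ1 > τ2 > 0, normalized so each
    response peaks at ``scr_amp``. ``scr_times`` overrides the Poisson draw
    for construction-vs-detection tests; ``return_times`` additionally
    returns the response onset times actually used.
    """
    if tonic_level <= 0:
        raise ValidationError("tonic_level must be > 0")
    if tau1 <= tau2 or tau2 <= 0:
        raise ValidationError("Bateman kernel requires tau1 > tau2 > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = tonic_level + drift * t / 3600.0
    if scr_times is None:
        n_scr = rng.poisson(scr_rate * duration / 60.0) if scr_rate > 0 else 0
        scr_times = np.sort(rng.uniform(0.0, duration, size=n_scr))
    kern_t = np.arange(0, 8 * tau1, 1.0 / fs)
    kernel = np.exp(-kern_t / tau1) - np.exp(-kern_t / tau2)
    peak = float(kernel.max())
    kernel = kernel / peak * scr_amp
    for st in np.asarray(scr_times, dtype=float):
        i0 = int(round(st * fs))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        sig[i0 : i0 + seg.size] += seg
    rec = ChannelRecording(Channel.EDA, start_time, fs, np.clip(sig, 0.0, None))
    if return_times:
        return rec, np.asarray(scr_times, dtype=float)
    return rec


def simulate_temperature(
    mean: float,
    circadian_amp: float,
    noise_sd: float,
    duration: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    fs: float = 4.0,
    start_time: float = 0.0,
) -> ChannelRecording:
    """Mean plus a slow 24-h sinusoid plus white noise (°C, 4 Hz)."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = start_time + np.arange(n) / fs
    sig = mean + circadian_amp * np.sin(2 * np.pi * t / 86_400.0)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return ChannelRecording(Channel.TEMP, start_time, fs, sig)


def simulate_cognition(
    baseline: float,
    post: float,
    n_intervals: int = 7,
    shape: GompertzShape | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Latent per-interval trajectory: sigmoid between the assessments with
    noise on interior points only (endpoints exact)."""
    if n_intervals < 2:
        raise ValidationError("need at least 2 intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = gompertz_series(baseline, post, n_intervals, shape).values.copy()
    if noise_sd > 0 and n_intervals > 2:
        vals[1:-1] += rng.normal(0.0, noise_sd, size=n_intervals - 2)
    return vals


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _night_hr_profile(nn: NNSeries, wear_start: float, wear_end: float,
                      hr_pad_bpm: float, rng: np.random.Generator,
                      pad_s: float = 1800.0) -> ChannelRecording:
    """1-Hz HR channel spanning the wear block plus padding on both sides.

    Inside the wear block HR follows the instantaneous beat rate (so beat
    counts agree with HR to well within the 10% consistency check); the
    padding carries elevated HR so the calmest-window search lands on the
    wear block.
    """
    start = wear_start - pad_s
    n = int(round(wear_end + pad_s - start))
    t = start + np.arange(n)
    inst_hr = 60_000.0 / nn.intervals
    hr = np.interp(t, nn.times, inst_hr, left=inst_hr[0], right=inst_hr[-1])
    outside = (t < wear_start) | (t >= wear_end)
    hr[outside] += hr_pad_bpm
    hr += rng.normal(0.0, 0.3, size=n)
    return ChannelRecording(Channel.HR, start, 1.0, hr)


def generate_cohort(
    cfg: SimulationConfig,
    out_dir: str | Path,
) -> tuple[Path, list[TrueTrajectory]]:
    """Write a full synthetic cohort to ``out_dir`` and return the truth.

    Tree layout: ``<out>/<subject>/day_<ddd>/{BVP,EDA,TEMP,HR,IBI}.csv`` plus
    ``subjects.csv``, ``assessments.csv`` and ``truth.csv``. Per wear night,
    the coupled physiological parameters equal their base value plus
    coupling-slope × that interval's latent score. Local midnight of day 0
    is local time 0; UTC = local − utc_offset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(cfg.seed)
    subj_seeds = root_ss.spawn(cfg.n_subjects)
    demo_rng = np.random.default_rng(root_ss.spawn(1)[0])

    subj_rows, pairs, truths, truth_rows = [], [], [], []
    wear_duration = cfg.segments_per_night * 300.0

    for s_idx in range(cfg.n_subjects):
        sid = f"S{s_idx + 1:03d}"
        ss = subj_seeds[s_idx]
        outcome_rng = np.random.default_rng(ss.spawn(1)[0])
        night_ss = ss.spawn(cfg.observation_days)

        age = int(demo_rng.integers(50, 71))
        sex = "female" if demo_rng.random() < 0.5 else "male"
        subj_rows.append({"subject_id": sid, "age": age, "sex": sex})

        baseline, post, latent = {}, {}, {}
        for comp in COMPOSITES:
            b = outcome_rng.normal(cfg.baseline_mean, cfg.baseline_sd)
            p = b + outcome_rng.normal(cfg.change_mean, cfg.change_sd)
            baseline[comp], post[comp] = float(b), float(p)
            latent[comp] = simulate_cognition(
                b, p, cfg.n_intervals, cfg.gompertz_shape,
                cfg.outcome_noise_sd, outcome_rng,
            )
        pairs.append(AssessmentPair(sid, baseline, post,
                                    baseline_day=-7, post_day=cfg.observation_days + 5))
        for comp in COMPOSITES:
            for i, v in enumerate(latent[comp], start=1):
                truth_rows.append({"subject_id": sid, "composite": comp,
                                   "interval": i, "latent": float(v)})

        # choose wear nights per interval
        wear_rng = np.random.default_rng(ss.spawn(1)[0])
        night_rows = []
        for i in range(cfg.n_intervals):
            days = np.arange(i * cfg.interval_days, (i + 1) * cfg.interval_days)
            k = min(cfg.wear_nights_per_interval, days.size)
            chosen = np.sort(wear_rng.choice(days, size=k, replace=False))
            score = float(latent[cfg.coupling_outcome][i])
            params = {
                "mean_rr_ms": cfg.mean_rr_ms,
                "lf_amp_ms": cfg.lf_amp_ms,
                "hf_amp_ms": cfg.hf_amp_ms,
                "jitter_sd_ms": cfg.jitter_sd_ms,
                "tonic_level_us": cfg.tonic_level_us,
                "scr_rate_per_min": cfg.scr_rate_per_min,
                "temp_mean_c": cfg.temp_mean_c,
            }
            for pname, slope in cfg.coupling:
                if pname not in params:
                    raise ValidationError(f"unknown coupled parameter {pname!r}")
                params[pname] = params[pname] + slope * score
            # keep parameters physiological after coupling
            params["hf_amp_ms"] = max(params["hf_amp_ms"], 1.0)
            params["lf_amp_ms"] = max(params["lf_amp_ms"], 1.0)
            params["mean_rr_ms"] = max(params["mean_rr_ms"], 500.0)
            params["scr_rate_per_min"] = max(params["scr_rate_per_min"], 0.0)
            params["tonic_level_us"] = max(params["tonic_level_us"], 0.2)

            for day in chosen:
                night_rows.append({"date": int(day), "interval": i + 1, **params})
                rng = np.random.default_rng(night_ss[int(day)])
                wear_start = day * 86_400.0 + cfg.night_start_clock
                nn = simulate_rr_series(
                    params["mean_rr_ms"], params["lf_amp_ms"], params["hf_amp_ms"],
                    params["jitter_sd_ms"], wear_duration, rng, t0=wear_start,
                )
                bvp = rr_to_bvp(nn, 64.0, seed=rng, start_time=wear_start)
                eda = simulate_eda(
                    params["tonic_level_us"], cfg.tonic_drift_us_per_h,
                    params["scr_rate_per_min"], cfg.scr_amp_us,
                    wear_duration, rng, start_time=wear_start,
                )
                temp = simulate_temperature(
                    params["temp_mean_c"], cfg.temp_circadian_amp_c,
                    cfg.temp_noise_sd_c, wear_duration, rng, start_time=wear_start,
                )
                hr = _night_hr_profile(nn, wear_start, wear_start + wear_duration,
                                       hr_pad_bpm=8.0, rng=rng)
                ibi = IBIEvents(wear_start, nn.times - wear_start, nn.intervals / 1000.0)

                day_dir = out / sid / f"day_{int(day):03d}"
                day_dir.mkdir(parents=True, exist_ok=True)
                for rec, fname in ((bvp, "BVP.csv"), (eda, "EDA.csv"),
                                   (temp, "TEMP.csv"), (hr, "HR.csv")):
                    rec_utc = replace(rec, start_time=rec.start_time - cfg.utc_offset)
                    write_channel(rec_utc, day_dir / fname, decimals=6)
                write_ibi(
                    IBIEvents(ibi.start_time - cfg.utc_offset, ibi.offsets, ibi.durations),
                    day_dir / "IBI.csv",
                )
        truths.append(TrueTrajectory(sid, latent, pd.DataFrame(night_rows)))

    write_subjects(SubjectTable(pd.DataFrame(subj_rows)), out / "subjects.csv")
    write_assessments(pairs, out / "assessments.csv")
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return out, truths
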