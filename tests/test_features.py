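"""Feature catalogue: HRV math oracles, detectors, EDA, registry sizing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearcog.features import (
    FEATURE_GROUPS,
    FEATURE_REGISTRY,
    HRV_FEATURE_NAMES,
    NNSeries,
    NNSource,
    clean_nn,
    eda_features,
    eda_process,
    elgendi_peaks,
    extract_all,
    hr_features,
    hrv_all,
    hrv_freq,
    hrv_nonlinear,
    hrv_time,
    temp_features,
)
from wearcog.io_e4 import Channel, IBIEvents
from wearcog.synthetic import rr_to_bvp, simulate_eda, simulate_rr_series
from tests.conftest import make_segment


def nn_from_intervals(intervals_ms, source=NNSource.IBI, t0=0.0):
    times = t0 + np.cumsum(np.asarray(intervals_ms, dtype=float)) / 1000.0
    return NNSeries(times, np.asarray(intervals_ms, dtype=float), source)


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def test_constant_series_zero_variability():
    f = hrv_time(nn_from_intervals([800.0] * 10))
    assert f["MeanNN"] == 800.0
    assert f["SDNN"] == 0.0
    assert f["RMSSD"] == 0.0
    assert f["pNN50"] == 0.0


def test_rmssd_hand_example():
    # diffs 10, -20, 15 -> sqrt((100+400+225)/3)
    f = hrv_time(nn_from_intervals([800.0, 810.0, 790.0, 805.0]))
    np.testing.assert_allclose(f["RMSSD"], np.sqrt((100 + 400 + 225) / 3), rtol=1e-12)
    np.testing.assert_allclose(f["SDNN"], np.std([800, 810, 790, 805], ddof=1), rtol=1e-12)


def test_pnn_strict_thresholds():
    f = hrv_time(nn_from_intervals([800.0, 860.0] * 10))
    assert f["pNN50"] == 100.0
    assert f["pNN20"] == 100.0
    # |diff| exactly 50 ms is NOT counted (strict >)
    f50 = hrv_time(nn_from_intervals([800.0, 850.0] * 10))
    assert f50["pNN50"] == 0.0


def test_time_domain_matches_independent_definitions(rng):
    """Definitional NumPy re-computation, written independently of hrv_time."""
    x = rng.normal(900.0, 50.0, size=300)
    f = hrv_time(nn_from_intervals(x))
    d = x[1:] - x[:-1]
    expected = {
        "MeanNN": x.mean(),
        "SDNN": x.std(ddof=1),
        "RMSSD": np.sqrt((d ** 2).mean()),
        "SDSD": d.std(ddof=1),
        "MedianNN": np.median(x),
        "IQRNN": np.percentile(x, 75) - np.percentile(x, 25),
        "CVNN": x.std(ddof=1) / x.mean(),
        "MADNN": 1.4826 * np.median(np.abs(x - np.median(x))),
    }
    for name, val in expected.items():
        np.testing.assert_allclose(f[name], val, rtol=1e-6, err_msg=name)


def test_too_few_intervals_marks_group_invalid():
    assert hrv_time(nn_from_intervals([800.0, 820.0])) == {}


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def test_constant_nn_total_power_near_zero():
    f = hrv_freq(nn_from_intervals([800.0] * 400))
    assert f["TotalPower"] < 1e-6


def test_hf_modulation_lands_in_hf_band():
    nn = simulate_rr_series(850, 0, 30, 0, 300, seed=1)
    f = hrv_freq(nn)
    assert f["HF"] / (f["LF"] + f["HF"]) > 0.9


def test_lf_modulation_dominates_ratio():
    nn = simulate_rr_series(850, 30, 0, 0, 300, seed=1)
    f = hrv_freq(nn)
    assert f["LFHF"] > 5


def test_total_power_parseval_on_stationary_series():
    """Band-limited modulation: spectral total within 15% of tachogram variance."""
    nn = simulate_rr_series(850, 20, 25, 0, 300, seed=3)
    f = hrv_freq(nn)
    var = np.var(nn.intervals)
    assert abs(f["TotalPower"] - var) / var < 0.15


def test_freq_against_analytic_band_powers():
    """Closed-form oracle: a sinusoid of amplitude a carries a^2/2 power,
    so LF and HF band powers are known exactly for the modulated series."""
    lf_amp, hf_amp = 20.0, 25.0
    nn = simulate_rr_series(850, lf_amp, hf_amp, 0, 300, seed=7)
    f = hrv_freq(nn)
    np.testing.assert_allclose(f["LF"], lf_amp**2 / 2, rtol=0.10)
    np.testing.assert_allclose(f["HF"], hf_amp**2 / 2, rtol=0.10)


def test_short_span_gives_no_freq_features():
    assert hrv_freq(nn_from_intervals([800.0] * 10)) == {}


# ---------------------------------------------------------------------------
# nonlinear
# ---------------------------------------------------------------------------

def test_alternating_series_closed_form():
    """800/850 alternation: Var(d)=2500 so SD1=sqrt(1250); SD2^2 collapses to 0."""
    f = hrv_nonlinear(nn_from_intervals([800.0, 850.0] * 200))
    np.testing.assert_allclose(f["SD1"], np.sqrt(1250), rtol=1e-2)
    assert f["SD2"] < 2.0
    assert np.isnan(f["SD1SD2"]) or f["SD2"] == 0 or f["SD1SD2"] > 10
    assert f["PAS"] == 100.0
    assert f["PIP"] > 99.0


def test_sd1_sd2_algebraic_identity(rng):
    x = rng.normal(900, 60, size=500)
    f = hrv_nonlinear(nn_from_intervals(x))
    lhs = f["SD1"] ** 2 + f["SD2"] ** 2
    rhs = 2 * np.var(x)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9)


@settings(max_examples=20, deadline=None)
@given(st.lists(st.floats(300, 2000), min_size=8, max_size=60))
def test_sd1_sd2_identity_property(intervals):
    x = np.asarray(intervals)
    f = hrv_nonlinear(nn_from_intervals(x))
    if f["SD2"] > 0:  # identity asserted pre-floor
        np.testing.assert_allclose(f["SD1"] ** 2 + f["SD2"] ** 2,
                                   2 * np.var(x), rtol=1e-9, atol=1e-9)


def test_monotone_series_asymmetry_extremes():
    f = hrv_nonlinear(nn_from_intervals(np.linspace(700, 1000, 100)))
    assert f["PortaIndex"] == 0.0
    assert f["PIP"] < 1e-9
    np.testing.assert_allclose(f["GuzikIndex"], 100.0, rtol=1e-12)
    assert f["PSS"] == 0.0 and f["PAS"] == 0.0


def test_guzik_porta_balanced_on_symmetric_noise(rng):
    x = rng.normal(900, 40, size=4000)
    f = hrv_nonlinear(nn_from_intervals(x))
    assert 40 < f["GuzikIndex"] < 60
    assert 40 < f["PortaIndex"] < 60


# ---------------------------------------------------------------------------
# beat detection and NN cleaning
# ---------------------------------------------------------------------------

def test_elgendi_recovers_synthetic_beats():
    nn = simulate_rr_series(850, 20, 25, 10, 300, seed=11)
    bvp = rr_to_bvp(nn, 64.0, seed=12, start_time=0.0)
    vals = bvp.values[:19200]
    seg = make_segment(vals, channel=Channel.BVP, rate=64.0, clock=0, date=0)
    det = elgendi_peaks(seg)
    true_beats = np.concatenate(([nn.times[0] - nn.intervals[0] / 1000], nn.times))
    det_beats = np.concatenate(([det.times[0] - det.intervals[0] / 1000], det.times))
    eligible = true_beats[true_beats < vals.size / 64.0 - 0.5]
    hits = sum(np.min(np.abs(det_beats - tb)) < 0.05 for tb in eligible)
    assert hits / eligible.size >= 0.99


def test_elgendi_flat_signal_no_peaks():
    seg = make_segment(np.zeros(19200), channel=Channel.BVP, rate=64.0)
    det = elgendi_peaks(seg)
    assert det.n == 0


def test_elgendi_periodic_pulses():
    nn = simulate_rr_series(1000, 0, 0, 0, 300, seed=0)
    bvp = rr_to_bvp(nn, 64.0, noise_sd=0.0, seed=0)
    seg = make_segment(bvp.values[:19200], channel=Channel.BVP, rate=64.0)
    det = elgendi_peaks(seg)
    assert abs(det.n - 298) <= 2
    np.testing.assert_allclose(np.median(det.intervals), 1000.0, atol=20)


def test_clean_nn_bounds():
    nn = nn_from_intervals([800.0, 5000.0, 820.0, 150.0, 810.0])
    cleaned = clean_nn(nn)
    assert cleaned.n == 3
    assert np.all((cleaned.intervals > 200) & (cleaned.intervals < 3000))
    # all-valid series unchanged; empty in -> empty out
    ok = nn_from_intervals([800.0, 820.0])
    np.testing.assert_array_equal(clean_nn(ok).intervals, ok.intervals)
    assert clean_nn(NNSeries(np.empty(0), np.empty(0), NNSource.PPG)).n == 0


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def test_constant_eda_decomposition():
    seg = make_segment(np.full(1200, 2.0), channel=Channel.EDA)
    tonic, phasic, scrs = eda_process(seg)
    assert np.max(np.abs(tonic - 2.0)) < 0.01
    assert np.max(np.abs(phasic)) < 0.01
    assert len(scrs) == 0


def test_planted_scrs_detected_exactly():
    eda = simulate_eda(2.0, 0.0, 0.0, 0.5, 300, seed=5,
                       scr_times=np.array([30.0, 80.0, 130.0, 190.0, 250.0]))
    seg = make_segment(eda.values, channel=Channel.EDA)
    _, _, scrs = eda_process(seg)
    assert len(scrs) == 5
    feats = eda_features(*eda_process(seg))
    assert feats["SCRCount"] == 5
    np.testing.assert_allclose(feats["SCRRate"], 1.0, rtol=1e-6)


def test_ramp_has_no_scrs_and_tonic_tracks_slope():
    t = np.arange(1200) / 4.0
    seg = make_segment(1.0 + 0.001 * t, channel=Channel.EDA)
    tonic, _, scrs = eda_process(seg)
    assert len(scrs) == 0
    mid_slope = np.polyfit(t[200:1000] / 3600.0, tonic[200:1000], 1)[0]
    np.testing.assert_allclose(mid_slope, 3.6, rtol=0.05)  # uS per hour


def test_sympathetic_band_placement():
    t = np.arange(1200) / 4.0
    in_band = np.sin(2 * np.pi * 0.10 * t)
    out_band = np.sin(2 * np.pi * 0.45 * t)
    f_in = eda_features(np.zeros(1200), in_band, [])
    f_out = eda_features(np.zeros(1200), out_band, [])
    assert f_in["SympatheticPower"] > f_out["SympatheticPower"]


def test_zero_phasic_normalized_power_zero():
    f = eda_features(np.full(1200, 2.0), np.zeros(1200), [])
    assert f["SympatheticPowerNormalized"] == 0.0


# ---------------------------------------------------------------------------
# temperature / HR statistics
# ---------------------------------------------------------------------------

def test_constant_temp_stats():
    f = temp_features(make_segment(np.full(1200, 33.0), channel=Channel.TEMP))
    assert f["TempMean"] == 33.0
    assert f["TempSD"] == 0.0
    np.testing.assert_allclose(f["TempSlope"], 0.0, atol=1e-9)


def test_linear_temp_slope_per_hour():
    vals = np.linspace(33.0, 33.5, 1200)  # +0.5 C over 5 min
    f = temp_features(make_segment(vals, channel=Channel.TEMP))
    np.testing.assert_allclose(f["TempSlope"], 6.0, rtol=0.01)


def test_hr_mean_is_sample_mean(rng):
    vals = rng.uniform(55, 75, 300)
    f = hr_features(make_segment(vals, channel=Channel.HR, rate=1.0))
    np.testing.assert_allclose(f["HRMean"], vals.mean(), rtol=1e-12)


# ---------------------------------------------------------------------------
# registry and whole-window extraction
# ---------------------------------------------------------------------------

def test_registry_group_sizes_cover_catalogue():
    counts = {}
    for name, group in FEATURE_REGISTRY:
        counts[group] = counts.get(group, 0) + 1
    assert counts["PPG"] >= 45
    assert counts["IBI"] >= 37
    assert counts["EDA"] >= 12
    assert counts["HR"] >= 7
    assert counts["TEMP"] >= 5
    assert len({n for n, _ in FEATURE_REGISTRY}) == len(FEATURE_REGISTRY)
    assert len(HRV_FEATURE_NAMES) == 45


def _window_segments(seed=21):
    nn = simulate_rr_series(850, 20, 25, 10, 300, seed=seed)
    bvp = rr_to_bvp(nn, 64.0, seed=seed + 1)
    segs = {
        Channel.BVP: make_segment(bvp.values[:19200], channel=Channel.BVP, rate=64.0),
        Channel.EDA: make_segment(
            simulate_eda(2.0, 0.1, 2.0, 0.3, 300, seed=seed).values,
            channel=Channel.EDA),
        Channel.TEMP: make_segment(np.full(1200, 33.2), channel=Channel.TEMP),
        Channel.HR: make_segment(np.full(300, 60000.0 / 850), channel=Channel.HR,
                                 rate=1.0),
    }
    for s in segs.values():
        s.date, s.start_clock = 0, 3600
    ibi = IBIEvents(0.0, nn.times + 3600.0, nn.intervals / 1000.0)
    # restrict to the window [3600, 3900)
    mask = (ibi.offsets >= 3600) & (ibi.offsets < 3900)
    ibi = IBIEvents(0.0, ibi.offsets[mask], ibi.durations[mask])
    return segs, ibi


def test_extract_all_groups_present_when_valid():
    segs, ibi = _window_segments()
    fv = extract_all(segs, ibi)
    assert all(fv.group_valid[g] for g in FEATURE_GROUPS)
    for group, prefix in [("PPG", "PPG_"), ("IBI", "IBI_"), ("EDA", "EDA_")]:
        assert any(k.startswith(prefix) for k in fv.values), group
    registry = {n for n, _ in FEATURE_REGISTRY}
    assert set(fv.values) <= registry


def test_extract_all_invalid_ibi_leaves_others():
    segs, _ = _window_segments()
    fv = extract_all(segs, IBIEvents(0.0))  # no events: IBI invalid
    assert not fv.group_valid["IBI"]
    assert not any(k.startswith("IBI_") for k in fv.values)
    assert any(k.startswith("PPG_") for k in fv.values)


def test_identical_streams_give_identical_hrv():
    """Same beats fed as device events and as detected peaks agree exactly."""
    nn_ibi = simulate_rr_series(850, 15, 20, 8, 300, seed=5)
    nn_ppg = NNSeries(nn_ibi.times.copy(), nn_ibi.intervals.copy(), NNSource.PPG)
    a, b = hrv_all(nn_ibi), hrv_all(nn_ppg)
    assert set(a) == set(b)
    for k in a:
        if np.isnan(a[k]):
            assert np.isnan(b[k])
        else:
            np.testing.assert_allclose(a[k], b[k], rtol=1e-9, err_msg=k)


def test_time_shift_invariance():
    nn = simulate_rr_series(850, 15, 20, 8, 300, seed=9)
    shifted = NNSeries(nn.times + 7200.0, nn.intervals.copy(), nn.source)
    a, b = hrv_all(nn), hrv_all(shifted)
    for k in a:
        if not np.isnan(a[k]):
            np.testing.assert_allclose(a[k], b[k], rtol=1e-7, err_msg=k)
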