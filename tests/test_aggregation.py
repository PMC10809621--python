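"""IBI filter, night-window choice, daily/interval aggregation, pruning."""

import numpy as np
import pandas as pd
import pytest

from wearcog.aggregation import (
    NightWindow,
    daily_aggregate,
    drop_redundant_features,
    interval_aggregate,
    require_ibi,
    select_night_window,
)
from wearcog.io_e4 import ValidationError


def _rows(n, ibi_valid=None, **cols):
    base = {
        "subject_id": ["s1"] * n,
        "date": [0] * n,
        "start_clock": [3600 + 300 * i for i in range(n)],
        "valid_IBI": ibi_valid if ibi_valid is not None else [True] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


def test_require_ibi_counts_and_idempotence():
    rows = _rows(10, ibi_valid=[True] * 7 + [False] * 3)
    kept = require_ibi(rows)
    assert len(kept) == 7
    pd.testing.assert_frame_equal(require_ibi(kept), kept)
    empty = require_ibi(_rows(4, ibi_valid=[False] * 4))
    assert len(empty) == 0


def _hr_rows(profile):
    """profile: {clock_seconds: mean_hr}; three pseudo-days of data."""
    recs = []
    for clock, hr in profile.items():
        for day in range(3):
            recs.append({"subject_id": f"s{day}", "date": day,
                         "start_clock": clock, "HRMean": hr})
    return pd.DataFrame(recs)


def test_night_window_finds_planted_minimum():
    profile = {}
    for k in range(288):
        clock = k * 300
        in_candidate = clock >= 21 * 3600 or clock < 9 * 3600
        if not in_candidate:
            continue
        low = 2 * 3600 <= clock < 7 * 3600
        profile[clock] = 55.0 if low else 70.0
    w = select_night_window(_hr_rows(profile))
    assert w.start_clock == 2 * 3600
    assert w.duration_s == 5 * 3600


def test_night_window_tie_earliest_start():
    profile = {k * 300: 60.0 for k in range(288)
               if k * 300 >= 21 * 3600 or k * 300 < 9 * 3600}
    w = select_night_window(_hr_rows(profile))
    assert w.start_clock == 21 * 3600


def test_night_window_reproduces_1_to_6_am():
    profile = {}
    for k in range(288):
        clock = k * 300
        if clock >= 21 * 3600 or clock < 9 * 3600:
            low = 1 * 3600 <= clock < 6 * 3600
            profile[clock] = 52.0 if low else 68.0
    w = select_night_window(_hr_rows(profile))
    assert w.start_clock == 1 * 3600
    assert w.end_clock == 6 * 3600


def test_night_window_no_data_errors():
    with pytest.raises(ValidationError):
        select_night_window(pd.DataFrame({"start_clock": [], "HRMean": []}))


def test_daily_aggregate_min_samples_and_median():
    window = NightWindow(start_clock=3600)
    rows4 = _rows(4, **{"IBI_MeanNN": [800.0, 810.0, 820.0, 900.0]})
    out = daily_aggregate(rows4, window, min_samples=4)
    assert len(out) == 1
    np.testing.assert_allclose(out["IBI_MeanNN"].iloc[0], 815.0)  # even-count median
    rows3 = _rows(3, **{"IBI_MeanNN": [800.0, 810.0, 820.0]})
    assert len(daily_aggregate(rows3, window, min_samples=4)) == 0


def test_daily_aggregate_order_invariant():
    window = NightWindow(start_clock=3600)
    rows = _rows(5, **{"IBI_MeanNN": [5.0, 1.0, 4.0, 2.0, 3.0]})
    shuffled = rows.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = daily_aggregate(rows, window)["IBI_MeanNN"].iloc[0]
    b = daily_aggregate(shuffled, window)["IBI_MeanNN"].iloc[0]
    assert a == b == 3.0


def test_daily_aggregate_wrapped_window_books_to_start_date():
    window = NightWindow(start_clock=23 * 3600)  # 23:00-04:00
    rows = pd.DataFrame({
        "subject_id": ["s1"] * 4,
        "date": [3, 3, 4, 4],
        "start_clock": [23 * 3600, 23 * 3600 + 300, 0, 300],
        "valid_IBI": [True] * 4,
        "IBI_MeanNN": [800.0] * 4,
    })
    out = daily_aggregate(rows, window, min_samples=4)
    assert len(out) == 1
    assert out["date"].iloc[0] == 3


def test_interval_aggregate_seven_intervals():
    daily = pd.DataFrame({
        "subject_id": ["s1"] * 70,
        "date": list(range(70)),
        "IBI_MeanNN": np.arange(70, dtype=float),
    })
    out = interval_aggregate(daily)
    assert list(out["interval"]) == list(range(1, 8))
    np.testing.assert_allclose(out["IBI_MeanNN"],
                               [np.mean(range(10 * i, 10 * i + 10)) for i in range(7)])


def test_interval_single_day_equals_that_day():
    daily = pd.DataFrame({"subject_id": ["s1"], "date": [12],
                          "IBI_MeanNN": [812.0]})
    out = interval_aggregate(daily, anchor={"s1": 0})
    assert len(out) == 1
    assert out["interval"].iloc[0] == 2
    assert out["IBI_MeanNN"].iloc[0] == 812.0


def test_interval_empty_absent():
    daily = pd.DataFrame({"subject_id": ["s1", "s1"], "date": [0, 65],
                          "IBI_MeanNN": [800.0, 900.0]})
    out = interval_aggregate(daily, anchor={"s1": 0})
    assert set(out["interval"]) == {1, 7}


def test_drop_redundant_duplicate_and_threshold(rng):
    x = rng.normal(size=60)
    noise = rng.normal(size=60)
    # pair with r ~ 0.975 (r^2 ~ 0.95)
    y = 0.975 * x + np.sqrt(1 - 0.975**2) * noise
    m = pd.DataFrame({"a": x, "dup": x.copy(), "corr975": y,
                      "indep": rng.normal(size=60)})
    kept, dropped = drop_redundant_features(m, order=["a", "dup", "corr975", "indep"])
    assert "a" in kept and "indep" in kept
    assert dropped["dup"] == "r2_with_a"
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    if r2 >= 0.95:
        assert "corr975" in dropped
    else:
        assert "corr975" in kept


def test_drop_redundant_zero_variance_first():
    m = pd.DataFrame({"flat": np.ones(10), "ok": np.arange(10.0)})
    kept, dropped = drop_redundant_features(m, order=["flat", "ok"])
    assert dropped["flat"] == "zero_variance"
    assert kept == ["ok"]


def test_drop_redundant_needs_three_rows():
    with pytest.raises(ValidationError):
        drop_redundant_features(pd.DataFrame({"a": [1.0, 2.0]}))
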