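"""Neuropsychological outcome series: composites, interval imputation, centering.

Composite z-scores are means of their constituent test z-scores. Because the
battery is administered only at baseline and post-intervention, per-interval
scores are imputed by interpolating between the two assessments — by default
along a Gompertz sigmoid normalized to pass exactly through both endpoints
(cognitive change over a short intervention tends to be monotone and to
plateau), with linear and random imputation available as comparators. Two
centering transforms isolate intra-individual change: features are centered
on each subject's median, outcomes on the half-range (midpoint) of the two
assessments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_e4 import COMPOSITES, ValidationError

__all__ = [
    "COMPOSITE_TESTS",
    "GompertzShape",
    "OutcomeSeries",
    "compute_composites",
    "gompertz_series",
    "linear_series",
    "random_series",
    "impute_series",
    "imputation_concordance",
    "center_features",
    "center_outcomes",
]

#: constituent tests per composite (z-scores; global averages every test)
COMPOSITE_TESTS: dict[str, tuple[str, ...]] = {
    "executive_function": (
        "digit_span",
        "similarities",
        "tmt_b",
        "category_fluency",
        "letter_fluency",
        "category_switching_fluency",
    ),
    "processing_speed": ("tmt_a", "sdmt"),
    "immediate_memory": ("logical_memory_1", "ravlt_1_5", "visual_reproduction_1"),
    "delayed_memory": ("logical_memory_2", "ravlt_7", "visual_reproduction_2"),
}
ALL_TESTS: tuple[str, ...] = tuple(
    t for tests in COMPOSITE_TESTS.values() for t in tests
)


@dataclass
class GompertzShape:
    """Shape of the normalized Gompertz interpolant.

    ``b`` displaces the inflection, ``c`` sets the growth rate; both must be
    strictly positive. The interpolant is renormalized so endpoints are hit
    exactly regardless of shape.
    """

    b: float = 3.0
    c: float = 4.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.c <= 0:
            raise ValidationError("Gompertz shape parameters must be > 0")


@dataclass
class OutcomeSeries:
    subject_id: str
    composite: str
    values: np.ndarray
    method: str  # gompertz | linear | random
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def compute_composites(test_z: dict[str, float]) -> dict[str, float]:
    """Composite z-scores as arithmetic means of constituent test z-scores.

    The global composite averages every listed test (not the composites);
    a composite with a missing constituent is omitted.
    """
    out: dict[str, float] = {}
    for comp, tests in COMPOSITE_TESTS.items():
        if all(t in test_z for t in tests):
            out[comp] = float(np.mean([test_z[t] for t in tests]))
    if all(t in test_z for t in ALL_TESTS):
        out["global_cognition"] = float(np.mean([test_z[t] for t in ALL_TESTS]))
    return out


def gompertz_curve(u: np.ndarray, shape: GompertzShape) -> np.ndarray:
    """Normalized Gompertz g(u) with g(0) = 0 and g(1) = 1 exactly."""
    u = np.asarray(u, dtype=float)
    b, c = shape.b, shape.c
    raw = np.exp(-b * np.exp(-c * u))
    g0 = np.exp(-b)
    g1 = np.exp(-b * np.exp(-c))
    return (raw - g0) / (g1 - g0)


def gompertz_series(
    y0: float,
    y1: float,
    n: int = 7,
    shape: GompertzShape | None = None,
    subject_id: str = "",
    composite: str = "",
) -> OutcomeSeries:
    """Sigmoid interpolation from ``y0`` to ``y1`` over ``n`` intervals."""
    if n < 2:
        raise ValidationError("need at least 2 intervals")
    shape = shape or GompertzShape()
    u = np.arange(n) / (n - 1)
    vals = y0 + (y1 - y0) * gompertz_curve(u, shape)
    vals[0], vals[-1] = y0, y1  # exact endpoints
    return OutcomeSeries(subject_id, composite, vals, "gompertz")


def linear_series(
    y0: float, y1: float, n: int = 7, subject_id: str = "", composite: str = ""
) -> OutcomeSeries:
    if n < 2:
        raise ValidationError("need at least 2 intervals")
    return OutcomeSeries(subject_id, composite, np.linspace(y0, y1, n), "linear")


def random_series(
    y0: float,
    y1: float,
    n: int = 7,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "",
    composite: str = "",
) -> OutcomeSeries:
    """Endpoints exact; interior i.i.d. uniform within the endpoint envelope."""
    if n < 2:
        raise ValidationError("need at least 2 intervals")
    rng = np.random.default_rng(seed)
    lo, hi = min(y0, y1), max(y0, y1)
    vals = np.empty(n)
    vals[0], vals[-1] = y0, y1
    vals[1:-1] = rng.uniform(lo, hi, size=max(n - 2, 0))
    return OutcomeSeries(subject_id, composite, vals, "random")


def impute_series(
    y0: float,
    y1: float,
    n: int = 7,
    method: str = "gompertz",
    shape: GompertzShape | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "",
    composite: str = "",
) -> OutcomeSeries:
    if method == "gompertz":
        return gompertz_series(y0, y1, n, shape, subject_id, composite)
    if method == "linear":
        return linear_series(y0, y1, n, subject_id, composite)
    if method == "random":
        return random_series(y0, y1, n, seed, subject_id, composite)
    raise ValidationError(f"unknown imputation method {method!r}")


def imputation_concordance(
    corrs_a: np.ndarray, corrs_b: np.ndarray
) -> tuple[float, float]:
    """Agreement between two paired sets of feature–outcome correlations.

    Returns the Pearson r between the vectors and the two-sided paired
    t-test p-value on their differences. Zero differences across the board
    yield p = 1 (no evidence of bias).
    """
    a = np.asarray(corrs_a, dtype=float)
    b = np.asarray(corrs_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired correlation vectors must have equal length")
    if np.array_equal(a, b):
        return 1.0, 1.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(stats.pearsonr(a, b)[0])
        t = stats.ttest_rel(a, b)
    return r, float(t.pvalue)


def center_features(frame: pd.DataFrame, feature_cols: list[str],
                    subject_col: str = "subject_id") -> pd.DataFrame:
    """Per-subject median centering of feature columns (deviation from the
    conditional personal baseline)."""
    out = frame.copy()
    med = out.groupby(subject_col)[feature_cols].transform("median")
    out[feature_cols] = out[feature_cols] - med
    return out


def center_outcomes(series: OutcomeSeries, y0: float, y1: float) -> OutcomeSeries:
    """Subtract the individual half-range (midpoint of the two assessments)."""
    return OutcomeSeries(
        series.subject_id,
        series.composite,
        series.values - (y0 + y1) / 2.0,
        series.method,
        centered=True,
    )
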