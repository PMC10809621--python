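"""Feature selection, CV mechanics, leakage guard and the model grid."""

import numpy as np
import pandas as pd
import pytest

from wearcog.io_e4 import ValidationError
from wearcog.prediction import (
    DEFAULT_THRESHOLDS,
    LeakageError,
    ModelConfig,
    evaluate,
    model_grid,
    run_cv,
    select_features,
)

FAST = dict(rf_n_estimators=60, xgb_n_estimators=40)


def planted_dataset(rng, n_subj=10, n_int=7, slope=0.8, noise=0.1,
                    n_null_features=6):
    """Interval-level frame: one coupled feature plus seeded noise features."""
    subj = np.repeat([f"s{i:02d}" for i in range(n_subj)], n_int)
    level = rng.normal(0, 0.8, size=n_subj)
    y = level[np.repeat(np.arange(n_subj), n_int)] + rng.normal(0, 0.15, subj.size)
    df = pd.DataFrame({
        "subject_id": subj,
        "interval": np.tile(np.arange(1, n_int + 1), n_subj),
        "age": np.repeat(rng.integers(50, 71, n_subj), n_int).astype(float),
        "sex": np.repeat(rng.integers(0, 2, n_subj), n_int).astype(float),
        "coupled": slope * y + rng.normal(0, noise, subj.size),
        "y": y,
    })
    for j in range(n_null_features):
        df[f"null{j}"] = rng.normal(size=subj.size)
    return df, ["coupled"] + [f"null{j}" for j in range(n_null_features)]


def test_select_features_both_p_rule(rng):
    # a feature strong on Pearson only (outlier-driven) is rejected
    n = 40
    y = rng.normal(size=n)
    weak = rng.normal(size=n) * 0.0
    weak[0], y[0] = 50.0, 5.0  # single point drives Pearson, not Spearman
    X = pd.DataFrame({"outlier": weak, "good": y + rng.normal(0, 0.3, n)})
    sel = select_features(X, y, p_threshold=0.05)
    assert "good" in sel
    assert "outlier" not in sel


def test_select_features_prunes_duplicates(rng):
    y = rng.normal(size=50)
    x = y + rng.normal(0, 0.2, 50)
    X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
    sel = select_features(X, y, p_threshold=0.05)
    assert sel.count("a") + sel.count("b") == 1


def test_select_features_planted_signal(rng):
    df, feats = planted_dataset(rng)
    hits = 0
    for subj in df["subject_id"].unique():
        train = df[df["subject_id"] != subj]
        sel = select_features(train[feats], train["y"].to_numpy(), 0.05)
        hits += "coupled" in sel
    assert hits / df["subject_id"].nunique() >= 0.9


def test_evaluate_basic_contracts():
    actual = np.array([0.1, 0.5, -0.2, 0.7, 0.3])
    r, rho, mae, flag = evaluate(actual.copy(), actual)
    np.testing.assert_allclose((r, rho, mae), (1.0, 1.0, 0.0), rtol=1e-12, atol=0)
    assert flag == "ok"
    r, _, mae, _ = evaluate(actual + 0.5, actual)
    np.testing.assert_allclose(r, 1.0, rtol=1e-12)
    np.testing.assert_allclose(mae, 0.5, rtol=1e-12)
    r, rho, mae, flag = evaluate(np.full(5, 0.2), actual)
    assert np.isnan(r) and np.isnan(rho) and flag == "constant_predictions"
    np.testing.assert_allclose(mae, np.mean(np.abs(actual - 0.2)), rtol=1e-12)
    with pytest.raises(ValidationError):
        evaluate(np.ones(3), np.ones(4))


def test_loso_partition_property(rng):
    df, feats = planted_dataset(rng, n_subj=6)
    cfg = ModelConfig(algorithm="elasticnet", outcome="y", **FAST)
    res = run_cv(df, feats, cfg, "loso")
    assert len(res.predictions) == len(df)
    assert res.predictions["predicted"].notna().all()
    # each subject predicted exactly once per row
    assert res.predictions.groupby("subject_id").size().eq(7).all()


def test_leakage_guard_detects_injected_overlap(rng):
    df, feats = planted_dataset(rng, n_subj=5)
    cfg = ModelConfig(algorithm="elasticnet", outcome="y", **FAST)

    def corrupt_folds(data, scheme):
        idx = np.arange(len(data))
        folds = []
        for val in sorted(data["subject_id"].unique()):
            test = idx[(data["subject_id"] == val).to_numpy()]
            folds.append((idx, test))  # training includes the held-out rows
        return folds

    with pytest.raises(LeakageError):
        run_cv(df, feats, cfg, "loso", fold_maker=corrupt_folds)


def test_leakage_guard_detects_duplicated_subject_rows(rng):
    """Memorization probe: a fold whose training set contains rows of the
    held-out subject must be rejected even when index sets are disjoint."""
    df, feats = planted_dataset(rng, n_subj=5)
    dup = pd.concat([df, df[df["subject_id"] == "s00"]], ignore_index=True)
    cfg = ModelConfig(algorithm="elasticnet", outcome="y", **FAST)

    def folds_with_copy(data, scheme):
        idx = np.arange(len(data))
        orig = idx[: len(df)]
        extra = idx[len(df):]
        folds = []
        for val in sorted(data["subject_id"].unique()):
            test = orig[(data.iloc[orig]["subject_id"] == val).to_numpy()]
            train = np.setdiff1d(orig, test)
            if val == "s00":
                train = np.concatenate([train, extra])  # sneak copies in
            folds.append((train, test))
        return folds

    with pytest.raises(LeakageError):
        run_cv(dup, feats, cfg, "loso", fold_maker=folds_with_copy)


def test_loio_holds_out_interval(rng):
    df, feats = planted_dataset(rng, n_subj=5)
    cfg = ModelConfig(algorithm="elasticnet", outcome="y", **FAST)
    res = run_cv(df, feats, cfg, "loio")
    assert len(res.predictions) == len(df)


def test_run_cv_needs_three_groups(rng):
    df, feats = planted_dataset(rng, n_subj=2)
    with pytest.raises(ValidationError):
        run_cv(df, feats, ModelConfig(outcome="y", **FAST), "loso")


def test_model_grid_size_and_gains(rng):
    df, feats = planted_dataset(rng, n_subj=8)
    grid = model_grid(df, feats, "y", scheme="loso", seed=1, **FAST)
    combined = [r for r in grid["results"] if r.config.feature_set == "combined"]
    assert len(combined) == 12  # 4 thresholds x 3 algorithms
    best = grid["best"]
    assert best.config.feature_set == "combined"
    assert np.isfinite(best.pearson_r)
    base = grid["baseline"]
    expected_gain = best.pearson_r - (base.pearson_r if np.isfinite(base.pearson_r) else 0.0)
    np.testing.assert_allclose(best.r_gain, expected_gain, rtol=1e-12)


def test_demographics_constant_predictions_give_full_gain(rng):
    """Centered outcomes: age/sex cannot vary within subject-mean-zero data,
    so the baseline predicts a constant and gains equal the model metrics."""
    df, feats = planted_dataset(rng, n_subj=8)
    # center y per subject -> demographics carry no between-subject signal
    df["y"] = df["y"] - df.groupby("subject_id")["y"].transform("mean")
    df["coupled"] = 0.8 * df["y"] + rng.normal(0, 0.05, len(df))
    grid = model_grid(df, feats, "y", scheme="loio", seed=1,
                      algorithms=("elasticnet",), **FAST)
    base = grid["baseline"]
    # demographic features are constant within interval folds' predictions
    best = grid["best"]
    if not np.isfinite(base.pearson_r):
        np.testing.assert_allclose(best.r_gain, best.pearson_r, rtol=1e-12)


def test_grid_deterministic_rerun(rng):
    df, feats = planted_dataset(rng, n_subj=6)
    g1 = model_grid(df, feats, "y", scheme="loso", seed=7,
                    algorithms=("random_forest",), thresholds=(0.05,), **FAST)
    g2 = model_grid(df, feats, "y", scheme="loso", seed=7,
                    algorithms=("random_forest",), thresholds=(0.05,), **FAST)
    np.testing.assert_allclose(g1["best"].pearson_r, g2["best"].pearson_r, rtol=0)
    np.testing.assert_array_equal(g1["best"].predictions["predicted"],
                                  g2["best"].predictions["predicted"])


def test_default_threshold_set():
    assert DEFAULT_THRESHOLDS == (0.05, 0.001, 0.0001, 0.00001)
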