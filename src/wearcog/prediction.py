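"""Supervised prediction of cognitive composites from physiological features.

Per cross-validation fold, candidate features must pass BOTH Pearson and
Spearman p-value thresholds on the training rows, are ranked by |Pearson r|
and greedily pruned for multicollinearity (|r| > 0.9). Three model families
(elastic-net linear regression, random forest, gradient-boosted trees) are
trained on three feature sets (demographics only, combined, physiology
only) under leave-one-subject-out (LOSO) and leave-one-interval-out (LOIO)
cross-validation; metrics are computed on predictions pooled over all folds
and reported together with the gain over the matched demographics-only
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_e4 import ValidationError

__all__ = [
    "LeakageError",
    "ModelConfig",
    "CVResult",
    "DEFAULT_THRESHOLDS",
    "DEMOGRAPHIC_COLS",
    "select_features",
    "evaluate",
    "run_cv",
    "model_grid",
    "report",
]

DEFAULT_THRESHOLDS = (0.05, 0.001, 0.0001, 0.00001)
DEMOGRAPHIC_COLS = ["age", "sex"]  # sex encoded female=1, male=0
ALGORITHMS = ("elasticnet", "random_forest", "xgboost")
FEATURE_SETS = ("demographics", "combined", "physio")


class LeakageError(AssertionError):
    """A cross-validation fold let held-out rows into training."""


@dataclass
class ModelConfig:
    algorithm: str = "elasticnet"
    feature_set: str = "combined"
    selection_p: float = 0.05
    outcome: str = "executive_function"
    variant: str = "uncentered"
    seed: int = 0
    # fixed, documented hyperparameters (no tuning)
    elasticnet_alpha: float = 0.05
    elasticnet_l1_ratio: float = 0.5
    rf_n_estimators: int = 500
    xgb_n_estimators: int = 300
    xgb_max_depth: int = 3
    xgb_learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValidationError(f"unknown feature set {self.feature_set!r}")


@dataclass
class CVResult:
    config: ModelConfig
    scheme: str
    predictions: pd.DataFrame  # subject_id, interval, actual, predicted
    pearson_r: float
    spearman_rho: float
    mae: float
    metric_flag: str
    n_features_per_fold: list[int] = field(default_factory=list)
    n_features_union: int = 0
    r_gain: float = np.nan
    rho_gain: float = np.nan

    @property
    def n_features_median(self) -> float:
        return float(np.median(self.n_features_per_fold)) if self.n_features_per_fold else 0.0


def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    p_threshold: float,
    prune_r: float = 0.9,
) -> list[str]:
    """Both-p statistical filter with multicollinearity pruning.

    Keep features whose Pearson AND Spearman p-values (against the training
    outcome) fall below the threshold; order by descending |Pearson r|;
    greedily drop any feature with |Pearson r| > ``prune_r`` to an
    already-kept one.
    """
    import warnings

    y = np.asarray(y, dtype=float)
    stats_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
                continue
            pr = stats.pearsonr(x[mask], y[mask])
            sr = stats.spearmanr(x[mask], y[mask])
            if pr.pvalue < p_threshold and sr.pvalue < p_threshold:
                stats_rows.append((col, abs(float(pr.statistic))))
    stats_rows.sort(key=lambda t: -t[1])
    kept: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col, _ in stats_rows:
            x = X[col].to_numpy(dtype=float)
            redundant = False
            for k in kept:
                xk = X[k].to_numpy(dtype=float)
                mask = np.isfinite(x) & np.isfinite(xk)
                if mask.sum() >= 3 and np.std(x[mask]) > 0 and np.std(xk[mask]) > 0:
                    r = float(stats.pearsonr(x[mask], xk[mask]).statistic)
                    if abs(r) > prune_r:
                        redundant = True
                        break
            if not redundant:
                kept.append(col)
    return kept


def evaluate(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float, float, str]:
    """Pooled Pearson r, Spearman rho and MAE.

    Constant predictions leave the correlations undefined (NaN with a
    reason flag); the MAE is always computed.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValidationError("prediction/actual length mismatch")
    if predicted.size < 3:
        raise ValidationError("need at least 3 pooled predictions")
    mae = float(np.mean(np.abs(predicted - actual)))
    if np.std(predicted) == 0 or np.std(actual) == 0:
        return np.nan, np.nan, mae, "constant_predictions"
    r = float(stats.pearsonr(predicted, actual).statistic)
    rho = float(stats.spearmanr(predicted, actual).statistic)
    return r, rho, mae, "ok"


def _make_model(cfg: ModelConfig):
    if cfg.algorithm == "elasticnet":
        from sklearn.linear_model import ElasticNet
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(
            StandardScaler(),
            ElasticNet(alpha=cfg.elasticnet_alpha, l1_ratio=cfg.elasticnet_l1_ratio,
                       max_iter=5000, random_state=cfg.seed),
        )
    if cfg.algorithm == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(
            n_estimators=cfg.rf_n_estimators, random_state=cfg.seed, n_jobs=1
        )
    from xgboost import XGBRegressor

    return XGBRegressor(
        n_estimators=cfg.xgb_n_estimators,
        max_depth=cfg.xgb_max_depth,
        learning_rate=cfg.xgb_learning_rate,
        random_state=cfg.seed,
        n_jobs=1,
        verbosity=0,
    )


def _default_folds(data: pd.DataFrame, scheme: str) -> list[tuple[np.ndarray, np.ndarray]]:
    key = "subject_id" if scheme == "loso" else "interval"
    idx = np.arange(len(data))
    folds = []
    for val in sorted(data[key].unique()):
        test = idx[(data[key] == val).to_numpy()]
        train = idx[(data[key] != val).to_numpy()]
        folds.append((train, test))
    return folds


def run_cv(
    data: pd.DataFrame,
    feature_cols: Sequence[str],
    config: ModelConfig,
    scheme: str = "loso",
    fold_maker: Callable[[pd.DataFrame, str], list] | None = None,
    selection_cache: dict | None = None,
) -> CVResult:
    """Cross-validate one model configuration.

    LOSO holds out all rows of one subject per fold; LOIO all rows of one
    interval index. Feature selection, pruning and model fitting run inside
    each training fold only; a guard raises :class:`LeakageError` if a fold
    overlaps, and pooled predictions must cover every row exactly once.
    """
    if scheme not in ("loso", "loio"):
        raise ValidationError(f"unknown CV scheme {scheme!r}")
    key = "subject_id" if scheme == "loso" else "interval"
    if data[key].nunique() < 3:
        raise ValidationError(f"need >= 3 distinct {key} values for {scheme}")
    folds = (fold_maker or _default_folds)(data, scheme)

    y_all = data[config.outcome].to_numpy(dtype=float)
    predicted = np.full(len(data), np.nan)
    covered = np.zeros(len(data), dtype=int)
    n_feats: list[int] = []
    union: set[str] = set()

    for train_idx, test_idx in folds:
        train_idx = np.asarray(train_idx)
        test_idx = np.asarray(test_idx)
        if train_idx.size == 0:
            raise ValidationError("fold with empty training set")
        if np.intersect1d(train_idx, test_idx).size:
            raise LeakageError("fold train/test overlap")
        test_keys = set(data.iloc[test_idx][key])
        if set(data.iloc[train_idx][key]) & test_keys:
            raise LeakageError(f"held-out {key} present in training rows")
        train = data.iloc[train_idx]
        test = data.iloc[test_idx]

        if config.feature_set == "demographics":
            cols, fallback_mean = DEMOGRAPHIC_COLS, False
        else:
            # selection depends only on the fold and the threshold, so the
            # grid can share one cache across algorithms and feature sets
            cache_key = (scheme, tuple(sorted(test_keys)), config.outcome,
                         config.selection_p)
            if selection_cache is not None and cache_key in selection_cache:
                selected = selection_cache[cache_key]
            else:
                selected = select_features(
                    train[list(feature_cols)], train[config.outcome].to_numpy(),
                    config.selection_p,
                )
                if selection_cache is not None:
                    selection_cache[cache_key] = selected
            n_feats.append(len(selected))
            union.update(selected)
            if selected:
                cols = (DEMOGRAPHIC_COLS + selected
                        if config.feature_set == "combined" else selected)
                fallback_mean = False
            elif config.feature_set == "combined":
                cols, fallback_mean = DEMOGRAPHIC_COLS, False
            else:
                cols, fallback_mean = [], True

        if fallback_mean:
            predicted[test_idx] = float(train[config.outcome].mean())
        else:
            Xtr = train[cols].to_numpy(dtype=float)
            Xte = test[cols].to_numpy(dtype=float)
            # tree/linear fits require finite inputs; impute with train medians
            med = np.nanmedian(Xtr, axis=0)
            Xtr = np.where(np.isfinite(Xtr), Xtr, med)
            Xte = np.where(np.isfinite(Xte), Xte, med)
            model = _make_model(config)
            model.fit(Xtr, train[config.outcome].to_numpy(dtype=float))
            predicted[test_idx] = model.predict(Xte)
        covered[test_idx] += 1

    if not np.all(covered == 1):
        raise LeakageError("each row must be predicted exactly once")
    r, rho, mae, flag = evaluate(predicted, y_all)
    preds = data[["subject_id", "interval"]].copy()
    preds["actual"] = y_all
    preds["predicted"] = predicted
    return CVResult(
        config=config, scheme=scheme, predictions=preds,
        pearson_r=r, spearman_rho=rho, mae=mae, metric_flag=flag,
        n_features_per_fold=n_feats, n_features_union=len(union),
    )


def model_grid(
    data: pd.DataFrame,
    feature_cols: Sequence[str],
    outcome: str,
    scheme: str = "loso",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    variant: str = "uncentered",
    seed: int = 0,
    algorithms: Sequence[str] = ALGORITHMS,
    feature_sets: Sequence[str] = ("combined", "physio"),
    **hyper,
) -> dict:
    """Run the full model grid for one outcome and CV scheme.

    Grid = |thresholds| x |algorithms| per non-baseline feature set (12
    combined models by default) plus the demographics-only baseline. Gains
    are relative to the baseline (treated as 0 when its correlations are
    undefined because predictions are constant). Best = highest Pearson r
    among combined models; ties broken by fewer features, then by the
    penalized-linear family.
    """
    cache: dict = {}
    base_cfg = ModelConfig(algorithm="elasticnet", feature_set="demographics",
                           outcome=outcome, variant=variant, seed=seed, **hyper)
    baseline = run_cv(data, feature_cols, base_cfg, scheme)
    base_r = baseline.pearson_r if np.isfinite(baseline.pearson_r) else 0.0
    base_rho = baseline.spearman_rho if np.isfinite(baseline.spearman_rho) else 0.0

    results: list[CVResult] = []
    for fset in feature_sets:
        for algo in algorithms:
            for p in thresholds:
                cfg = ModelConfig(algorithm=algo, feature_set=fset, selection_p=p,
                                  outcome=outcome, variant=variant, seed=seed, **hyper)
                res = run_cv(data, feature_cols, cfg, scheme,
                             selection_cache=cache)
                res.r_gain = (res.pearson_r if np.isfinite(res.pearson_r) else 0.0) - base_r
                res.rho_gain = (res.spearman_rho if np.isfinite(res.spearman_rho) else 0.0) - base_rho
                results.append(res)

    combined = [r for r in results if r.config.feature_set == "combined"]
    algo_rank = {a: i for i, a in enumerate(ALGORITHMS)}

    def sort_key(res: CVResult):
        r = res.pearson_r if np.isfinite(res.pearson_r) else -np.inf
        return (-r, res.n_features_median, algo_rank[res.config.algorithm])

    best = sorted(combined or results, key=sort_key)[0]
    return {"baseline": baseline, "results": results, "best": best}


def report(grids: dict[tuple[str, str], dict]) -> dict[str, pd.DataFrame]:
    """Summary tables over completed grids keyed (scheme, outcome).

    ``best``: per scheme and outcome, the winning model with its feature
    count (per-fold median and union), selection p, pooled metrics and
    gains. ``by_algorithm``: mean Pearson r per algorithm across selection
    thresholds (combined models). ``raw``: every combined-model r (boxplot
    feed).
    """
    best_rows, avg_rows, raw_rows = [], [], []
    for (scheme, outcome), grid in grids.items():
        best = grid["best"]
        best_rows.append({
            "cv_method": scheme, "outcome": outcome,
            "algorithm": best.config.algorithm,
            "n_features": best.n_features_median,
            "n_features_union": best.n_features_union,
            "selection_p": best.config.selection_p,
            "r": best.pearson_r, "r_gain": best.r_gain,
            "rho": best.spearman_rho, "rho_gain": best.rho_gain,
            "mae": best.mae,
        })
        combined = [r for r in grid["results"] if r.config.feature_set == "combined"]
        for algo in ALGORITHMS:
            rs = [r.pearson_r for r in combined if r.config.algorithm == algo
                  and np.isfinite(r.pearson_r)]
            avg_rows.append({"cv_method": scheme, "outcome": outcome,
                             "algorithm": algo,
                             "mean_r": float(np.mean(rs)) if rs else np.nan})
        for res in combined:
            raw_rows.append({"cv_method": scheme, "outcome": outcome,
                             "algorithm": res.config.algorithm,
                             "selection_p": res.config.selection_p,
                             "r": res.pearson_r})
    return {
        "best": pd.DataFrame(best_rows),
        "by_algorithm": pd.DataFrame(avg_rows),
        "raw": pd.DataFrame(raw_rows),
    }
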