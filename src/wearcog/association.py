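"""Outcome–feature association screening.

Pearson and Spearman correlations for every outcome–feature pair, random-
intercept mixed-model fixed-effect slopes for the subject-grouped data, and
Benjamini–Hochberg step-up FDR adjustment applied across all pairs within
one dataset variant, separately per statistic. A pair is called significant
only when BOTH adjusted correlation p-values fall strictly below alpha.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_e4 import ValidationError

__all__ = [
    "correlation_screen",
    "fdr_adjust",
    "significant_pairs",
    "lmer_screen",
    "lmer_screen_all",
]


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, q_i = p_i * m / i, enforce monotonicity from the largest
    downward, cap at 1, restore the original order. NaN entries are passed
    through and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    pv = p[finite]
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    restored = np.empty(m)
    restored[order] = adjusted
    out[finite] = restored
    return out


def correlation_screen(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson/Spearman correlations for every (outcome, feature) pair.

    Missing values are handled pairwise-complete. Zero-variance cells are
    flagged with coefficients left missing. Adjusted p-value columns apply
    BH-FDR across all pairs, separately for each statistic.
    """
    rows = []
    for outcome in Y.columns:
        y_all = Y[outcome].to_numpy(dtype=float)
        for feat in X.columns:
            x_all = X[feat].to_numpy(dtype=float)
            mask = np.isfinite(x_all) & np.isfinite(y_all)
            n = int(mask.sum())
            rec = {"outcome": outcome, "feature": feat, "n": n, "flag": "ok",
                   "pearson_r": np.nan, "pearson_p": np.nan,
                   "spearman_rho": np.nan, "spearman_p": np.nan}
            if n < min_n:
                rec["flag"] = "too_few_pairs"
            elif np.std(x_all[mask]) == 0 or np.std(y_all[mask]) == 0:
                rec["flag"] = "zero_variance"
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pr = stats.pearsonr(x_all[mask], y_all[mask])
                    sr = stats.spearmanr(x_all[mask], y_all[mask])
                rec.update(
                    pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
                    spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
                )
            rows.append(rec)
    table = pd.DataFrame(rows)
    table["pearson_p_adj"] = fdr_adjust(table["pearson_p"].to_numpy())
    table["spearman_p_adj"] = fdr_adjust(table["spearman_p"].to_numpy())
    return table


def significant_pairs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairs where both adjusted p-values are strictly below alpha."""
    mask = (table["pearson_p_adj"] < alpha) & (table["spearman_p_adj"] < alpha)
    return table[mask.fillna(False)].reset_index(drop=True)


def lmer_screen(
    feature: np.ndarray,
    outcome: np.ndarray,
    subjects: np.ndarray,
) -> dict[str, float]:
    """Random-intercept mixed model: outcome ~ feature + (1 | subject).

    REML fit; the fixed slope's p-value uses the normal approximation.
    The fixed-effect R^2 is Var(slope*feature) over the sum of that term,
    the random-intercept variance and the residual variance.
    """
    import statsmodels.api as sm

    feature = np.asarray(feature, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    subjects = np.asarray(subjects)
    mask = np.isfinite(feature) & np.isfinite(outcome)
    feature, outcome, subjects = feature[mask], outcome[mask], subjects[mask]
    if np.unique(subjects).size < 2:
        return {"flag": "too_few_subjects"}
    if np.std(feature) == 0:
        return {"flag": "zero_variance"}
    exog = sm.add_constant(feature)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(outcome, exog, groups=subjects)
            fit = model.fit(reml=True)
        except Exception:
            return {"flag": "non_convergence"}
    if not np.all(np.isfinite(fit.params)):
        return {"flag": "non_convergence"}
    slope = float(fit.params[1])
    slope_p = float(fit.pvalues[1])
    var_fixed = float(np.var(slope * feature))
    cov_re = np.asarray(fit.cov_re)
    var_re = float(cov_re[0, 0]) if cov_re.size else 0.0
    var_resid = float(fit.scale)
    denom = var_fixed + var_re + var_resid
    return {
        "slope": slope,
        "slope_p": slope_p,
        "r2_fixed": var_fixed / denom if denom > 0 else np.nan,
        "flag": "ok",
    }


def lmer_screen_all(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    subjects: np.ndarray,
) -> pd.DataFrame:
    """Mixed-model screen across all pairs with BH-FDR on the slope p-values.

    Non-converged rows are flagged and excluded from the FDR family.
    """
    rows = []
    for outcome in Y.columns:
        for feat in X.columns:
            res = lmer_screen(X[feat].to_numpy(), Y[outcome].to_numpy(), subjects)
            rows.append({"outcome": outcome, "feature": feat,
                         "slope": res.get("slope", np.nan),
                         "slope_p": res.get("slope_p", np.nan),
                         "r2_fixed": res.get("r2_fixed", np.nan),
                         "flag": res["flag"]})
    table = pd.DataFrame(rows)
    ps = table["slope_p"].to_numpy(dtype=float).copy()
    ps[table["flag"] != "ok"] = np.nan
    table["slope_p_adj"] = fdr_adjust(ps)
    return table
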