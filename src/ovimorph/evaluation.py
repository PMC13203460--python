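"""Regression metrics and agreement statistics.

Beyond the standard error metrics (MAE, RMSE, R^2, MAPE) this module
implements the agreement suite used to compare predictions against
gold-standard measurements: Lin's concordance correlation coefficient
(penalizing both dispersion and location shift from the identity line),
Bland-Altman limits of agreement, and paired significance tests on
absolute errors (parametric t plus the distribution-free Wilcoxon
signed-rank test, exact at small n).

R^2 is the coefficient of determination, 1 - SSE/SST about the truth mean,
not squared Pearson correlation: a miscalibrated predictor can correlate
perfectly yet explain nothing on the identity scale.  Lin's CCC uses
population (1/n) moments, the standard definition; Bland-Altman uses the
sample SD of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import (
    mean_absolute_error,
    mean_absolute_percentage_error,
    mean_squared_error,
    r2_score,
)

__all__ = [
    "MetricSet",
    "BAStats",
    "PairedTestResult",
    "regression_metrics",
    "lin_ccc",
    "bland_altman",
    "compare_models_errors",
    "metrics_table",
]


@dataclass(frozen=True)
class MetricSet:
    mae: float
    rmse: float
    r2: float
    mape: float  # percent
    r2_pearson: float  # squared Pearson, reported alongside


@dataclass(frozen=True)
class BAStats:
    bias: float  # mean of prediction - truth, kg
    sd_diff: float  # sample SD of differences
    loa_low: float
    loa_high: float
    proportional_bias_slope: float  # slope of diff vs pair mean


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    n: int
    note: str = ""


def _paired(y, yhat, min_n=2):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length 1-D vectors")
    if len(y) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return y, yhat


def regression_metrics(y, yhat) -> MetricSet:
    """MAE, RMSE, coefficient-of-determination R^2 and MAPE (percent)."""
    y, yhat = _paired(y, yhat)
    if np.any(y == 0):
        raise ValueError("MAPE undefined: truth contains zeros")
    r = np.corrcoef(y, yhat)[0, 1] if (y.std() > 0 and yhat.std() > 0) else np.nan
    return MetricSet(
        mae=float(mean_absolute_error(y, yhat)),
        rmse=float(np.sqrt(mean_squared_error(y, yhat))),
        r2=float(r2_score(y, yhat)),
        mape=float(100.0 * mean_absolute_percentage_error(y, yhat)),
        r2_pearson=float(r**2),
    )


def lin_ccc(y, yhat) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(y, yhat) / (var y + var yhat + (mean y - mean yhat)^2)
    with population (1/n) moments; 1 iff the points lie on y = x.
    """
    y, yhat = _paired(y, yhat)
    vy, vh = y.var(), yhat.var()
    if vy == 0 or vh == 0:
        raise ValueError("CCC undefined for a constant vector")
    cov = ((y - y.mean()) * (yhat - yhat.mean())).mean()
    return float(2.0 * cov / (vy + vh + (y.mean() - yhat.mean()) ** 2))


def bland_altman(y, yhat) -> BAStats:
    """Agreement via paired differences d = yhat - y: mean bias, sample-SD
    95% limits (bias +/- 1.96 SD), and the slope of d on the pair mean as a
    proportional-bias diagnostic."""
    y, yhat = _paired(y, yhat)
    d = yhat - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mean_pair = (y + yhat) / 2.0
    if mean_pair.std() > 0:
        slope = float(np.polyfit(mean_pair, d, 1)[0])
    else:
        slope = 0.0
    return BAStats(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd,
                   loa_high=bias + 1.96 * sd, proportional_bias_slope=slope)


def compare_models_errors(err_a, err_b) -> PairedTestResult:
    """Paired comparison of two models' absolute errors on the same animals.

    Returns the paired t-test and the Wilcoxon signed-rank test (zeros
    dropped, average ranks on ties; exact null for n <= 25 after zero
    removal, else normal approximation with continuity correction), both
    two-sided.
    """
    err_a, err_b = _paired(err_a, err_b, min_n=5)
    d = err_a - err_b
    nz = d[d != 0]
    if len(nz) == 0:
        return PairedTestResult(
            t_statistic=0.0, t_pvalue=1.0, wilcoxon_statistic=np.nan,
            wilcoxon_pvalue=np.nan, n=len(d),
            note="all paired differences are zero: no evidence either way",
        )
    t_stat, t_p = stats.ttest_rel(err_a, err_b)
    method = "exact" if len(nz) <= 25 else "approx"
    w = stats.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return PairedTestResult(
        t_statistic=float(t_stat), t_pvalue=float(t_p),
        wilcoxon_statistic=float(w.statistic), wilcoxon_pvalue=float(w.pvalue),
        n=len(d),
    )


def metrics_table(y: np.ndarray, yhat: np.ndarray, model: str = "model"):
    """Per-target metric report (one row per target), mirroring the layout
    of a model-comparison table: MAE (kg), RMSE (kg), R^2, MAPE (%), CCC."""
    import pandas as pd

    target_names = ("live_weight", "carcass_weight", "fat_mass", "lean_mass")
    rows = []
    for t, name in enumerate(target_names):
        m = regression_metrics(y[:, t], yhat[:, t])
        rows.append({
            "model": model, "target": name, "mae_kg": m.mae, "rmse_kg": m.rmse,
            "r2": m.r2, "mape_pct": m.mape, "ccc": lin_ccc(y[:, t], yhat[:, t]),
        })
    return pd.DataFrame(rows)
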