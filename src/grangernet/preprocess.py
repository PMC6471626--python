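"""Data cleaning ahead of the causality scan.

Three steps, in the order the pipeline runs them:

1. listwise deletion of time points with any missing value (all downstream
   regressions need one aligned lag grid, so deletion is global);
2. an abundance/prevalence filter on OTUs — a taxon is dropped when its mean
   abundance is below ``mean_thresh`` and/or its zero fraction exceeds
   ``zero_frac_thresh`` (zero-inflated series corrupt the linear lag fits);
   environmental variables are exempt;
3. an augmented Dickey-Fuller screen that removes series for which the unit
   root cannot be rejected — the autoregressive causality model is only valid
   on stationary series, and non-stationary variables (seasonal or trending
   factors) are removed, never transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .io_formats import OTU, TimeSeriesTable

RemovalReason = Literal["low_mean", "high_zero_fraction", "missing_policy", "nonstationary"]


@dataclass
class FilterReport:
    """Who survived a cleaning step and why each removal happened."""

    kept_ids: list[str]
    removed: list[tuple[str, str]]  # (var_id, reason)
    thresholds: dict = field(default_factory=dict)
    dropped_time_labels: list[str] = field(default_factory=list)

    @property
    def removed_ids(self) -> list[str]:
        return [v for v, _ in self.removed]


@dataclass
class StationarityResult:
    var_id: str
    adf_statistic: float
    p_value: float
    n_lags: int
    verdict: Literal["stationary", "nonstationary"]


def drop_missing(table: TimeSeriesTable, min_T: int = 10) -> tuple[TimeSeriesTable, FilterReport]:
    """Delete every time point at which any variable is missing.

    Temporal order of the surviving points is preserved. Errors out if fewer
    than ``min_T`` points remain — too short for any lagged model.
    """
    missing_cols = np.isnan(table.values).any(axis=0)
    keep = [j for j in range(table.T) if not missing_cols[j]]
    if len(keep) < min_T:
        raise ValueError(
            f"only {len(keep)} complete time points remain after missing-data "
            f"deletion (minimum {min_T})"
        )
    out = table.subset_times(keep)
    report = FilterReport(
        kept_ids=list(table.var_ids),
        removed=[],
        thresholds={"min_T": min_T},
        dropped_time_labels=[table.time_labels[j] for j in range(table.T) if missing_cols[j]],
    )
    return out, report


def filter_abundance(
    table: TimeSeriesTable,
    mean_thresh: float = 1.0,
    zero_frac_thresh: float = 0.5,
    combine: Literal["and", "or"] = "and",
) -> tuple[TimeSeriesTable, FilterReport]:
    """Remove low-abundance, zero-inflated OTUs.

    An OTU is removed when (mean < mean_thresh) AND/OR (zero fraction >
    zero_frac_thresh), per ``combine``. Environmental variables always pass.
    Requires a complete table (run :func:`drop_missing` first).
    """
    if table.n_vars == 0 or table.T == 0:
        raise ValueError("empty table")
    if table.has_missing:
        raise ValueError("table contains missing values; run drop_missing first")
    if mean_thresh < 0:
        raise ValueError("mean_thresh must be nonnegative")
    if not 0 <= zero_frac_thresh <= 1:
        raise ValueError("zero_frac_thresh must be in [0, 1]")
    if combine not in ("and", "or"):
        raise ValueError(f"combine must be 'and' or 'or', got {combine!r}")

    kept, removed = [], []
    for vid, cls, row in zip(table.var_ids, table.var_class, table.values):
        if cls != OTU:
            kept.append(vid)
            continue
        low_mean = float(np.mean(row)) < mean_thresh
        high_zero = float(np.mean(row == 0.0)) > zero_frac_thresh
        drop = (low_mean and high_zero) if combine == "and" else (low_mean or high_zero)
        if drop:
            # under "and" both conditions hold; report the primary one first
            reason = "low_mean" if low_mean else "high_zero_fraction"
            removed.append((vid, reason))
        else:
            kept.append(vid)
    report = FilterReport(
        kept_ids=kept,
        removed=removed,
        thresholds={
            "mean_thresh": mean_thresh,
            "zero_frac_thresh": zero_frac_thresh,
            "combine": combine,
        },
    )
    return table.subset_vars(kept), report


def adf_test(
    series: np.ndarray,
    regression: Literal["constant", "constant_trend"] = "constant",
    max_lags: int | Literal["auto_aic"] = "auto_aic",
    var_id: str = "x",
    alpha: float = 0.05,
) -> StationarityResult:
    """Augmented Dickey-Fuller unit-root test for one series.

    ``auto_aic`` picks the augmentation lag by AIC up to floor((T-1)^(1/3)).
    A constant (zero-variance) series cannot reject a unit root and is
    reported nonstationary with a warning rather than crashing.
    """
    series = np.asarray(series, dtype=float)
    reg = {"constant": "c", "constant_trend": "ct"}[regression]
    if np.ptp(series) == 0:
        warnings.warn(
            f"variable {var_id!r} is constant; flagged nonstationary", stacklevel=2
        )
        return StationarityResult(var_id, np.nan, 1.0, 0, "nonstationary")
    maxlag = None if max_lags == "auto_aic" else int(max_lags)
    autolag = "AIC" if max_lags == "auto_aic" else None
    if autolag == "AIC":
        maxlag = int(np.floor((len(series) - 1) ** (1.0 / 3.0)))
    stat, pval, usedlag, *_ = adfuller(series, maxlag=maxlag, regression=reg, autolag=autolag)
    verdict = "stationary" if pval < alpha else "nonstationary"
    return StationarityResult(var_id, float(stat), float(pval), int(usedlag), verdict)


def adf_screen(
    table: TimeSeriesTable,
    alpha: float = 0.05,
    regression: Literal["constant", "constant_trend"] = "constant",
    max_lags: int | Literal["auto_aic"] = "auto_aic",
) -> tuple[TimeSeriesTable, list[StationarityResult]]:
    """Screen out variables whose unit root the ADF test cannot reject.

    Returns the reduced table and a result per input variable. Requires a
    complete table with T >= 10.
    """
    if table.has_missing:
        raise ValueError("table contains missing values; run drop_missing first")
    if table.T < 10:
        raise ValueError(f"T={table.T} too short for a stationarity screen (need >= 10)")
    results = [
        adf_test(table.series(vid), regression, max_lags, vid, alpha)
        for vid in table.var_ids
    ]
    keep = [r.var_id for r in results if r.verdict == "stationary"]
    return table.subset_vars(keep), results
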