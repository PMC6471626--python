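"""Bivariate Granger causality: the log variance-ratio statistic and its F-test.

X1 Granger-causes X2 when lags of X1 improve the prediction of X2 beyond
X2's own lags. The statistic is

    GC(x1 -> x2) = ln( var(u2) / var(w2) ) = ln( RSS_restricted / RSS_full )

where u2 are the residuals of the autoregression of X2 on its own lags and
w2 those of the model that adds lags of X1. Variances are taken as RSS/n_eff
on a shared fit window, so the n_eff normalisations cancel and the statistic
reduces to the RSS ratio. Significance comes from

    F = (T - 2p - 1)/p * (RSS_r - RSS_f)/RSS_f  ~  F(p, T - 2p - 1)

under the null of no causality (all cross-lag coefficients zero), giving the
exact identity gc = ln(1 + f * p / (T - 2p - 1)) on every pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import TimeSeriesTable
from .var_core import DegenerateFitError, LagSpec, fit_lagged, select_order

#: below this, a full-model RSS is treated as a perfect fit
RSS_TINY = 1e-12


@dataclass
class GCResult:
    """One ordered pair's Granger-causality test.

    ``status`` is ``"ok"`` for a completed test and ``"degenerate"`` when the
    full model fitted perfectly (statistic undefined); degenerate pairs carry
    no p-value and are excluded from FDR.
    """

    source_id: str
    target_id: str
    p: int
    gc: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    q_value: float | None = None
    status: str = "ok"


def gc_statistic(rss_restricted: float, rss_full: float, n_eff: int) -> float:
    """ln(RSS_restricted / RSS_full); zero iff lags of the source add nothing.

    ``n_eff`` documents the shared window length; the ML variance
    normalisations RSS/n_eff cancel in the ratio.
    """
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    if rss_restricted < 0 or rss_full < 0:
        raise ValueError("residual sums of squares must be nonnegative")
    if rss_full <= RSS_TINY:
        raise DegenerateFitError(
            "full model fits perfectly (RSS ~ 0); GC statistic undefined"
        )
    return float(np.log(rss_restricted / rss_full))


def gc_f_test(
    rss_restricted: float, rss_full: float, T: int, p: int
) -> tuple[float, float]:
    """F statistic and upper-tail p-value for the no-causality null.

    df1 = p, df2 = T - 2p - 1 (the count of cross-lag coefficients under test
    and the residual degrees of freedom of the bivariate model).
    """
    df2 = T - 2 * p - 1
    if df2 <= 0:
        raise ValueError(f"series too short for lag p={p}: df2 = T - 2p - 1 = {df2}")
    if rss_full <= RSS_TINY:
        raise DegenerateFitError("full model fits perfectly; F statistic undefined")
    f_stat = (df2 / p) * (rss_restricted - rss_full) / rss_full
    # nested OLS guarantees f >= 0 up to round-off
    f_stat = float(max(f_stat, 0.0))
    p_value = float(stats.f.sf(f_stat, p, df2))
    return f_stat, p_value


def gc_pair(
    source: np.ndarray,
    target: np.ndarray,
    p: int,
    include_intercept: bool = True,
    source_id: str = "x1",
    target_id: str = "x2",
) -> GCResult:
    """Test source -> target at lag order p on a shared window."""
    restricted = fit_lagged(
        target, [target], p, include_intercept, target_id, [target_id]
    )
    full = fit_lagged(
        target,
        [target, source],
        p,
        include_intercept,
        target_id,
        [target_id, source_id],
    )
    T = len(target)
    df2 = T - 2 * p - 1
    try:
        gc = gc_statistic(restricted.rss, full.rss, full.n_eff)
        f_stat, p_value = gc_f_test(restricted.rss, full.rss, T, p)
    except DegenerateFitError:
        return GCResult(
            source_id, target_id, p, np.nan, np.nan, p, df2, np.nan, None, "degenerate"
        )
    gc = float(max(gc, 0.0))
    return GCResult(source_id, target_id, p, gc, f_stat, p, df2, p_value)


def pairwise_scan(
    table: TimeSeriesTable,
    spec: LagSpec,
    include_intercept: bool = True,
) -> list[GCResult]:
    """Granger-test every ordered pair of variables in the table.

    Returns n*(n-1) results in lexicographic (source, target) order. The lag
    order is either fixed or selected per pair on the joint bivariate model,
    per ``spec``.
    """
    if table.has_missing:
        raise ValueError("table contains missing values; run preprocessing first")
    if table.n_vars < 2:
        raise ValueError("need at least two variables for a pairwise scan")
    ids = sorted(table.var_ids)
    results: list[GCResult] = []
    for src in ids:
        x1 = table.series(src)
        for tgt in ids:
            if tgt == src:
                continue
            x2 = table.series(tgt)
            p = select_order(x2, x1, spec, include_intercept)
            results.append(
                gc_pair(x1, x2, p, include_intercept, source_id=src, target_id=tgt)
            )
    return results
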