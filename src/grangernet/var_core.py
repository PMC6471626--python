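"""Least-squares fitting of lagged (autoregressive) models.

Every Granger-causality statistic in this package is a ratio of residual sums
of squares from two nested ordinary-least-squares fits. The one rule that
makes those ratios valid is the *shared window*: whatever regressor sets a
model includes, it is always fitted on observations t = p+1..T, so restricted
and full models see exactly the same sample and the nesting property
(RSS never increases when regressors are added) holds.

An intercept is included by default. The textbook autoregressive equations
omit it, but abundance and concentration series are not mean-zero; set
``include_intercept=False`` for the literal zero-mean form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np


class DegenerateFitError(ValueError):
    """A fit is numerically degenerate (perfect fit / zero residual variance)."""


class CollinearityError(ValueError):
    """The lagged design matrix is rank-deficient."""


@dataclass
class LagSpec:
    """How the model order p is chosen.

    ``fixed`` uses ``p`` as given; ``bic``/``aic`` minimise the information
    criterion over 1..p_max on the joint bivariate model, ties broken toward
    the smaller order.
    """

    p: int = 1
    selection: Literal["fixed", "bic", "aic"] = "fixed"
    p_max: int = 4

    def __post_init__(self) -> None:
        if self.selection not in ("fixed", "bic", "aic"):
            raise ValueError(f"unknown selection rule {self.selection!r}")
        if self.p < 1 or self.p_max < 1:
            raise ValueError("lag orders must be positive")
        if self.selection == "fixed" and self.p > self.p_max:
            self.p_max = self.p


@dataclass
class ARFit:
    """Result of one lagged OLS fit.

    ``coefficients`` are ordered: intercept first (if included), then the lag
    blocks of each regressor set in the order supplied, lags 1..p within each
    block. ``n_eff`` is the number of fitted observations, T - p.
    """

    target_id: str
    regressor_ids: list[str]
    p: int
    include_intercept: bool
    coefficients: np.ndarray
    residuals: np.ndarray
    rss: float
    n_eff: int

    @property
    def sigma2(self) -> float:
        """Maximum-likelihood residual variance RSS / n_eff."""
        return self.rss / self.n_eff

    @property
    def n_coeffs(self) -> int:
        return len(self.coefficients)


def _lag_block(series: np.ndarray, p: int, start: int) -> np.ndarray:
    """Columns [x(t-1), ..., x(t-p)] for t = start..T-1 (0-based)."""
    T = len(series)
    return np.column_stack([series[start - k : T - k] for k in range(1, p + 1)])


def _design(
    regressor_sets: Sequence[np.ndarray],
    p: int,
    start: int,
    include_intercept: bool,
) -> np.ndarray:
    T = len(regressor_sets[0]) if regressor_sets else 0
    n = T - start
    blocks = []
    if include_intercept:
        blocks.append(np.ones((n, 1)))
    for s in regressor_sets:
        blocks.append(_lag_block(s, p, start))
    return np.hstack(blocks)


def fit_lagged(
    y: np.ndarray,
    regressor_sets: Sequence[np.ndarray],
    p: int,
    include_intercept: bool = True,
    target_id: str = "y",
    regressor_ids: Sequence[str] | None = None,
) -> ARFit:
    """OLS fit of y(t) on lags 1..p of each regressor series.

    The fit window is t = p+1..T regardless of how many regressor sets are
    supplied, so fits with nested regressor sets are directly comparable.

    Raises
    ------
    ValueError
        If series lengths differ, contain non-finite values, or T is too
        short for the requested order.
    CollinearityError
        If the design matrix is rank-deficient (e.g. duplicated series).
    """
    y = np.asarray(y, dtype=float)
    xs = [np.asarray(x, dtype=float) for x in regressor_sets]
    if regressor_ids is None:
        regressor_ids = [f"x{i}" for i in range(len(xs))]
    regressor_ids = list(regressor_ids)
    if len(regressor_ids) != len(xs):
        raise ValueError("one id per regressor set required")
    T = len(y)
    for x in xs:
        if len(x) != T:
            raise ValueError("all series must share the same length")
    if not np.isfinite(y).all() or any(not np.isfinite(x).all() for x in xs):
        raise ValueError("series contain non-finite values; clean the table first")
    if p < 1:
        raise ValueError("lag order must be >= 1")
    k = int(include_intercept) + p * len(xs)
    if T - p <= k:
        raise ValueError(
            f"series too short: T={T} leaves {T - p} observations for {k} coefficients at p={p}"
        )

    X = _design(xs, p, p, include_intercept)
    y_win = y[p:]
    coef, _, rank, _ = np.linalg.lstsq(X, y_win, rcond=None)
    if rank < X.shape[1]:
        culprits = _collinear_sets(xs, regressor_ids)
        raise CollinearityError(
            f"rank-deficient design for target {target_id!r} "
            f"(rank {rank} < {X.shape[1]} columns); "
            + (f"collinear regressors: {culprits}" if culprits else "check for constant or duplicated series")
        )
    resid = y_win - X @ coef
    rss = float(resid @ resid)
    return ARFit(
        target_id=target_id,
        regressor_ids=regressor_ids,
        p=p,
        include_intercept=include_intercept,
        coefficients=coef,
        residuals=resid,
        rss=rss,
        n_eff=T - p,
    )


def _collinear_sets(xs: Sequence[np.ndarray], ids: Sequence[str]) -> list[str]:
    """Name regressor sets that are exact duplicates or constant."""
    bad: list[str] = []
    for i, x in enumerate(xs):
        if np.ptp(x) == 0:
            bad.append(f"{ids[i]} (constant)")
        for j in range(i + 1, len(xs)):
            if np.array_equal(x, xs[j]):
                bad.append(f"{ids[i]}=={ids[j]} (duplicate)")
    return bad


def select_order(
    y: np.ndarray,
    x: np.ndarray | None,
    spec: LagSpec,
    include_intercept: bool = True,
) -> int:
    """Choose the lag order for a univariate (x=None) or bivariate model.

    Information criteria are evaluated on the common window t = p_max+1..T so
    that fits with different p score the same observations. Ties go to the
    smaller order.
    """
    if spec.selection == "fixed":
        return spec.p
    y = np.asarray(y, dtype=float)
    xs = [y] if x is None else [y, np.asarray(x, dtype=float)]
    T = len(y)
    k_max = int(include_intercept) + spec.p_max * len(xs)
    n = T - spec.p_max
    if n <= k_max:
        raise ValueError(
            f"p_max={spec.p_max} infeasible for T={T}: {n} observations for {k_max} coefficients"
        )
    best_p, best_crit = None, np.inf
    y_win = y[spec.p_max :]
    for p in range(1, spec.p_max + 1):
        X = _design(xs, p, spec.p_max, include_intercept)
        coef, _, rank, _ = np.linalg.lstsq(X, y_win, rcond=None)
        resid = y_win - X @ coef
        rss = float(resid @ resid)
        k = X.shape[1]
        if rss <= 0:
            rss = np.finfo(float).tiny
        ll_term = n * np.log(rss / n)
        crit = ll_term + (2 * k if spec.selection == "aic" else k * np.log(n))
        if crit < best_crit - 1e-12:  # strict improvement; ties keep smaller p
            best_p, best_crit = p, crit
    assert best_p is not None
    return best_p
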