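"""Conditional Granger causality: separating direct edges from mediated ones.

A significant bivariate edge Y -> X may be spurious if it is carried by a
mediator Z (the chain Y -> Z -> X). The conditional statistic asks whether Y
still predicts X once Z's lags sit in both models:

    full:     X_t ~ lags(X) + lags(Y) + lags(Z) + eps
    reduced:  X_t ~ lags(X)           + lags(Z) + eps'

    GC(Y -> X | Z) = ln( var(eps') / var(eps) )

With an empty conditioning set this is exactly the bivariate statistic. The
F-test uses df1 = p (the Y-lag coefficients under test) and the exact
residual degrees of freedom of the full model, df2 = (T - p) - k_full.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .var_core import CollinearityError, DegenerateFitError, fit_lagged


@dataclass
class CondGCResult:
    """Conditional test of source -> target given a mediator set."""

    source_id: str
    target_id: str
    mediator_ids: list[str]
    p: int
    cond_gc: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    verdict: Literal["direct", "indirect"]


def conditional_gc(
    x: np.ndarray,
    y: np.ndarray,
    z: Sequence[np.ndarray],
    p: int,
    include_intercept: bool = True,
    alpha: float = 0.05,
    source_id: str = "Y",
    target_id: str = "X",
    mediator_ids: Sequence[str] | None = None,
) -> CondGCResult:
    """Test whether y Granger-causes x conditional on the series in z.

    Both models are fitted on the shared window t = p+1..T. The provisional
    verdict is ``direct`` when the conditional F-test keeps p < alpha;
    :func:`classify_edge` combines several mediator tests into an edge-level
    verdict.
    """
    z = [np.asarray(s, dtype=float) for s in z]
    if mediator_ids is None:
        mediator_ids = [f"z{i}" for i in range(len(z))]
    mediator_ids = list(mediator_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    T = len(x)
    k_full = int(include_intercept) + p * (2 + len(z))
    if T - p <= k_full:
        raise ValueError(
            f"too many mediators for T={T}: full model needs {k_full} coefficients "
            f"on {T - p} observations"
        )
    for mid, s in zip(mediator_ids, z):
        if np.array_equal(s, y):
            raise CollinearityError(f"mediator {mid!r} is collinear with the source series")

    full = fit_lagged(
        x,
        [x, y, *z],
        p,
        include_intercept,
        target_id,
        [target_id, source_id, *mediator_ids],
    )
    reduced = fit_lagged(
        x, [x, *z], p, include_intercept, target_id, [target_id, *mediator_ids]
    )
    if full.rss <= 1e-12:
        raise DegenerateFitError("full conditional model fits perfectly")
    cond_gc = float(np.log(reduced.rss / full.rss))
    df2 = (T - p) - k_full
    f_stat = float(max(((reduced.rss - full.rss) / p) / (full.rss / df2), 0.0))
    p_value = float(stats.f.sf(f_stat, p, df2))
    verdict = "direct" if p_value < alpha else "indirect"
    return CondGCResult(
        source_id=source_id,
        target_id=target_id,
        mediator_ids=mediator_ids,
        p=p,
        cond_gc=float(max(cond_gc, 0.0)),
        f_stat=f_stat,
        df1=p,
        df2=df2,
        p_value=p_value,
        verdict=verdict,
    )


def classify_edge(
    bivariate,
    cond_results: Sequence[CondGCResult],
    rule: Literal["ftest_alpha", "gc_threshold"] = "ftest_alpha",
    alpha: float = 0.05,
    threshold: float | None = None,
) -> tuple[str, list[str]]:
    """Edge-level verdict from one conditional test per candidate mediator.

    The edge is ``direct`` only if every conditional test retains it; a single
    mediator that explains it away makes the edge ``indirect`` ("any spurious
    indirect causality" removes the edge). Returns the verdict and the ids of
    the mediators responsible for an indirect call.

    ``ftest_alpha`` retains when p_value < alpha; ``gc_threshold`` retains
    when the conditional statistic exceeds ``threshold`` (the raw-value rule,
    provided for replication of published conditional values).
    """
    if not cond_results:
        raise ValueError("cond_results must be nonempty")
    blamed: list[str] = []
    for res in cond_results:
        if rule == "ftest_alpha":
            keep = res.p_value < alpha
        elif rule == "gc_threshold":
            if threshold is None:
                raise ValueError("gc_threshold rule requires a threshold")
            keep = res.cond_gc > threshold
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if not keep:
            blamed.extend(res.mediator_ids)
    verdict = "direct" if not blamed else "indirect"
    return verdict, blamed
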