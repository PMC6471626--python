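"""Assembling, FDR-controlling and pruning the Granger causality graph.

The full pairwise scan is one multiple-testing family of n(n-1) tests; the
false discovery rate over that family is controlled with Storey's q-value.
Edges with q below the threshold enter the directed edge set Ed. A single
pruning pass then re-examines every edge with the conditional statistic:
mediators are enumerated from the *unpruned* graph, each edge is conditioned
on its candidate mediators, and edges explained away are moved to an audit
log. Conditional tests act as a confirmatory filter and are not re-entered
into the FDR family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .bivariate_gc import GCResult
from .conditional_gc import CondGCResult, classify_edge, conditional_gc
from .io_formats import OTU, TimeSeriesTable
from .var_core import DegenerateFitError, LagSpec


@dataclass
class QValueSet:
    """p-values with Storey's FDR-adjusted q-values and the pi0 estimate."""

    p_values: np.ndarray
    pi0_estimate: float
    q_values: np.ndarray


@dataclass
class CausalityGraph:
    """G = (V, Ed, Eu) with the statistics behind every edge.

    ``vertices`` maps variable id to class; isolated vertices are retained.
    ``pruned_edges`` holds the bivariate results of edges removed by the
    conditional pass, and ``pruned_log``/``audit`` the conditional tests that
    removed (resp. examined) them.
    """

    vertices: dict[str, str]
    directed_edges: list[GCResult] = field(default_factory=list)
    undirected_edges: list[tuple[str, str]] = field(default_factory=list)
    pruned_edges: list[GCResult] = field(default_factory=list)
    pruned_log: list[CondGCResult] = field(default_factory=list)
    audit: list[CondGCResult] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source_id, e.target_id) for e in self.directed_edges}

    @property
    def isolated_vertices(self) -> list[str]:
        touched = {v for e in self.directed_edges for v in (e.source_id, e.target_id)}
        return sorted(set(self.vertices) - touched)


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def _smoothing_spline_fit(x: np.ndarray, y: np.ndarray, df: float = 3.0) -> np.ndarray:
    """Natural cubic smoothing spline with a given effective df.

    Fitted values are (I + a*K)^{-1} y where K is the usual second-derivative
    penalty (Reinsch form); the penalty weight a is bisected so that the
    smoother matrix has trace == df. With df=3 this is the smoother used for
    pi0(lambda) regularisation.
    """
    n = len(x)
    h = np.diff(x)
    # second-difference matrix (n-2 x n) and its weight matrix (n-2 x n-2)
    delta = np.zeros((n - 2, n))
    for i in range(n - 2):
        delta[i, i] = 1.0 / h[i]
        delta[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        delta[i, i + 2] = 1.0 / h[i + 1]
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    K = delta.T @ np.linalg.solve(W, delta)
    eig = np.linalg.eigvalsh(K)
    eig = np.clip(eig, 0.0, None)

    def trace_S(log_a: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(log_a) * eig)))

    lo, hi = -25.0, 25.0  # trace is decreasing in a
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if trace_S(mid) > df:
            lo = mid
        else:
            hi = mid
    a = np.exp(0.5 * (lo + hi))
    return np.linalg.solve(np.eye(n) + a * K, y)


def storey_qvalues(
    p_values: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
    pi0_method: Literal["smoother", "fixed_lambda", "bh"] = "smoother",
    fixed_lambda: float = 0.5,
) -> QValueSet:
    """Storey q-values for one family of p-values.

    pi0 (the null proportion) is estimated from the flat right tail of the
    p-value histogram: pi0(lambda) = #{p > lambda} / (m (1 - lambda)),
    smoothed over the lambda grid with a df=3 cubic smoothing spline and
    read off at the largest lambda. ``fixed_lambda`` uses a single lambda;
    ``bh`` fixes pi0 = 1, which makes the q-values exactly Benjamini-Hochberg
    adjusted p-values. q_i = min over p_(j) >= p_(i) of pi0 * m * p_(j) / j.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if pi0_method == "bh":
        pi0 = 1.0
    elif pi0_method == "fixed_lambda":
        pi0 = float(np.mean(p > fixed_lambda) / (1.0 - fixed_lambda))
    elif pi0_method == "smoother":
        grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
        if np.any((grid < 0) | (grid >= 1)):
            raise ValueError("lambda grid must lie in [0, 1)")
        grid = np.sort(grid)
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
        if grid.size >= 4:
            fitted = _smoothing_spline_fit(grid, pi0_lam, df=3.0)
            pi0 = float(fitted[-1])
        else:
            pi0 = float(pi0_lam[-1])
    else:
        raise ValueError(f"unknown pi0 method {pi0_method!r}")

    pi0 = min(pi0, 1.0)
    if pi0 <= 0:
        warnings.warn(
            f"pi0 estimate {pi0:.3g} <= 0; clamped to 1/m", stacklevel=2
        )
        pi0 = 1.0 / m

    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * ps / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueSet(p_values=p, pi0_estimate=pi0, q_values=q)


def attach_qvalues(
    results: Sequence[GCResult],
    pi0_method: Literal["smoother", "fixed_lambda", "bh"] = "smoother",
    lambda_grid: Sequence[float] | None = None,
) -> QValueSet:
    """Compute q-values over all non-degenerate scan results, in place."""
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        raise ValueError("no testable pairs in scan results")
    qset = storey_qvalues([r.p_value for r in ok], lambda_grid, pi0_method)
    for r, q in zip(ok, qset.q_values):
        r.q_value = float(q)
    return qset


def build_graph(
    results: Sequence[GCResult],
    q_threshold: float = 0.05,
    var_class: Mapping[str, str] | None = None,
) -> CausalityGraph:
    """Directed graph of all ordered pairs with q below the threshold.

    Every variable appearing in the scan becomes a vertex (isolated ones are
    retained and reported via ``isolated_vertices``). Cycles are allowed; any
    nontrivial strongly connected component triggers a warning listing it.
    """
    missing_q = [r for r in results if r.status == "ok" and r.q_value is None]
    if missing_q:
        raise ValueError(
            "scan results lack q-values; run attach_qvalues over the full family first"
        )
    vertices: dict[str, str] = {}
    for r in results:
        for v in (r.source_id, r.target_id):
            if v not in vertices:
                vertices[v] = var_class.get(v, OTU) if var_class else OTU
    edges = [
        r
        for r in results
        if r.status == "ok" and r.q_value < q_threshold and r.source_id != r.target_id
    ]
    edges.sort(key=lambda r: (r.source_id, r.target_id))
    graph = CausalityGraph(vertices=dict(sorted(vertices.items())), directed_edges=edges)
    _warn_on_cycles(graph)
    return graph


def _warn_on_cycles(graph: CausalityGraph) -> None:
    g = nx.DiGraph(list(graph.edge_set()))
    sccs = [sorted(c) for c in nx.strongly_connected_components(g) if len(c) > 1]
    if sccs:
        warnings.warn(f"causality graph contains cycles: {sccs}", stacklevel=3)


def candidate_mediators(
    graph: CausalityGraph, source: str, target: str, policy: Literal["two_path", "all"]
) -> list[str]:
    """Mediator candidates for edge source -> target.

    ``two_path`` (default): variables z with both source -> z and z -> target
    in the unpruned graph — the configuration in which a chain can explain
    the edge. ``all``: every other variable in the graph.
    """
    if policy == "all":
        return sorted(set(graph.vertices) - {source, target})
    if policy != "two_path":
        raise ValueError(f"unknown mediator policy {policy!r}")
    edges = graph.edge_set()
    out = {t for s, t in edges if s == source}
    into = {s for s, t in edges if t == target}
    return sorted((out & into) - {source, target})


def prune_graph(
    graph: CausalityGraph,
    table: TimeSeriesTable,
    spec: LagSpec | None = None,
    mediator_policy: Literal["two_path", "all"] = "two_path",
    rule: Literal["ftest_alpha", "gc_threshold"] = "ftest_alpha",
    alpha: float = 0.05,
    threshold: float | None = None,
    include_intercept: bool = True,
) -> CausalityGraph:
    """Single conditional-GC pass removing mediated (indirect) edges.

    Mediators are enumerated against the unpruned edge set and tested one at
    a time (the trivariate model); an edge is kept only if it survives every
    mediator test. Decisions never feed back within the pass, so pruning is
    order-independent and idempotent.
    """
    unknown = set(graph.vertices) - set(table.var_ids)
    if unknown:
        raise ValueError(f"graph vertices absent from table: {sorted(unknown)}")
    kept: list[GCResult] = []
    pruned: list[GCResult] = []
    pruned_log: list[CondGCResult] = []
    audit: list[CondGCResult] = []
    for edge in graph.directed_edges:
        meds = candidate_mediators(graph, edge.source_id, edge.target_id, mediator_policy)
        if not meds:
            kept.append(edge)
            continue
        cond_results = []
        for med in meds:
            try:
                res = conditional_gc(
                    x=table.series(edge.target_id),
                    y=table.series(edge.source_id),
                    z=[table.series(med)],
                    p=edge.p,
                    include_intercept=include_intercept,
                    alpha=alpha,
                    source_id=edge.source_id,
                    target_id=edge.target_id,
                    mediator_ids=[med],
                )
            except DegenerateFitError:
                continue
            cond_results.append(res)
        audit.extend(cond_results)
        if not cond_results:
            kept.append(edge)
            continue
        verdict, blamed = classify_edge(edge, cond_results, rule, alpha, threshold)
        if verdict == "direct":
            kept.append(edge)
        else:
            pruned.append(edge)
            pruned_log.extend(
                r for r in cond_results if set(r.mediator_ids) & set(blamed)
            )
    return CausalityGraph(
        vertices=dict(graph.vertices),
        directed_edges=kept,
        undirected_edges=list(graph.undirected_edges),
        pruned_edges=list(graph.pruned_edges) + pruned,
        pruned_log=list(graph.pruned_log) + pruned_log,
        audit=list(graph.audit) + audit,
    )


def write_pruning_log(graph: CausalityGraph, path) -> None:
    """Audit TSV of every conditional test run during pruning."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "mediator", "p", "cond_gc", "f_stat", "p_value", "verdict"])
        for r in sorted(
            graph.audit, key=lambda r: (r.source_id, r.target_id, r.mediator_ids)
        ):
            w.writerow(
                [
                    r.source_id,
                    r.target_id,
                    ";".join(r.mediator_ids),
                    r.p,
                    repr(r.cond_gc),
                    repr(r.f_stat),
                    repr(r.p_value),
                    r.verdict,
                ]
            )
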