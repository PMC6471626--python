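"""End-to-end run: clean -> scan -> FDR -> build -> prune, with a config and log.

Every threshold the pipeline uses lives in :class:`RunConfig`, loadable from
YAML, and every removal/decision is appended to a JSON-lines run log so a
finished network can be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from .bivariate_gc import GCResult, pairwise_scan
from .io_formats import TimeSeriesTable
from .network_builder import (
    CausalityGraph,
    QValueSet,
    attach_qvalues,
    build_graph,
    prune_graph,
)
from .preprocess import FilterReport, StationarityResult, adf_screen, drop_missing, filter_abundance
from .var_core import LagSpec


@dataclass
class RunConfig:
    """All pipeline thresholds in one place (YAML-serialisable)."""

    # abundance/prevalence filter
    mean_thresh: float = 1.0
    zero_frac_thresh: float = 0.5
    filter_combine: Literal["and", "or"] = "and"
    # missing-data policy
    min_T: int = 10
    # stationarity screen
    adf_alpha: float = 0.05
    adf_regression: Literal["constant", "constant_trend"] = "constant"
    adf_max_lags: int | str = "auto_aic"
    # lag order
    lag_selection: Literal["fixed", "bic", "aic"] = "bic"
    p: int = 1
    p_max: int = 4
    intercept: bool = True
    # significance
    q_threshold: float = 0.05
    pi0_method: Literal["smoother", "fixed_lambda", "bh"] = "smoother"
    # pruning
    mediator_policy: Literal["two_path", "all"] = "two_path"
    prune_rule: Literal["ftest_alpha", "gc_threshold"] = "ftest_alpha"
    prune_alpha: float = 0.05
    prune_threshold: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def lag_spec(self, T: int) -> LagSpec:
        p_max = min(self.p_max, max(T // 10, 1))
        if self.lag_selection == "fixed":
            return LagSpec(p=self.p, selection="fixed", p_max=max(p_max, self.p))
        return LagSpec(p=self.p, selection=self.lag_selection, p_max=p_max)


class RunLog:
    """Append-only JSON-lines log of pipeline decisions."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, step: str, **payload) -> None:
        self.records.append({"step": step, **payload})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


@dataclass
class PipelineResult:
    table: TimeSeriesTable               # cleaned, screened table the scan used
    missing_report: FilterReport
    abundance_report: FilterReport
    stationarity: list[StationarityResult]
    scan: list[GCResult]
    qset: QValueSet
    graph: CausalityGraph                # before pruning
    pruned_graph: CausalityGraph         # final network
    log: RunLog


def run_pipeline(table: TimeSeriesTable, config: RunConfig | None = None) -> PipelineResult:
    """Run the whole inference on one table with the given configuration."""
    cfg = config or RunConfig()
    log = RunLog()
    log.add("config", **asdict(cfg))

    table1, miss_rep = drop_missing(table, min_T=cfg.min_T)
    log.add("drop_missing", dropped_time_labels=miss_rep.dropped_time_labels, T=table1.T)

    table2, ab_rep = filter_abundance(
        table1, cfg.mean_thresh, cfg.zero_frac_thresh, cfg.filter_combine
    )
    log.add("filter_abundance", removed=ab_rep.removed, n_kept=table2.n_vars)

    table3, stat_results = adf_screen(
        table2, cfg.adf_alpha, cfg.adf_regression, cfg.adf_max_lags
    )
    log.add(
        "adf_screen",
        removed=[r.var_id for r in stat_results if r.verdict == "nonstationary"],
        n_kept=table3.n_vars,
    )

    spec = cfg.lag_spec(table3.T)
    scan = pairwise_scan(table3, spec, include_intercept=cfg.intercept)
    log.add("pairwise_scan", n_tests=len(scan), lag_spec=asdict(spec))

    qset = attach_qvalues(scan, pi0_method=cfg.pi0_method)
    log.add("qvalues", pi0=qset.pi0_estimate, method=cfg.pi0_method)

    graph = build_graph(scan, cfg.q_threshold, var_class=table3.class_map())
    log.add("build_graph", n_edges=len(graph.directed_edges))

    pruned = prune_graph(
        graph,
        table3,
        spec,
        mediator_policy=cfg.mediator_policy,
        rule=cfg.prune_rule,
        alpha=cfg.prune_alpha,
        threshold=cfg.prune_threshold,
        include_intercept=cfg.intercept,
    )
    log.add(
        "prune_graph",
        n_pruned=len(pruned.pruned_edges),
        pruned=[(e.source_id, e.target_id) for e in pruned.pruned_edges],
    )

    return PipelineResult(
        table=table3,
        missing_report=miss_rep,
        abundance_report=ab_rep,
        stationarity=stat_results,
        scan=scan,
        qset=qset,
        graph=graph,
        pruned_graph=pruned,
        log=log,
    )


def write_scan_table(scan: list[GCResult], path: str | Path) -> None:
    """Intermediate p/q-value table TSV (source, target, p, gc, f_stat, p_value, q_value)."""
    import csv

    rows = sorted(scan, key=lambda r: (r.source_id, r.target_id))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "p", "gc", "f_stat", "p_value", "q_value", "status"])
        for r in rows:
            w.writerow(
                [
                    r.source_id,
                    r.target_id,
                    r.p,
                    repr(float(r.gc)),
                    repr(float(r.f_stat)),
                    repr(float(r.p_value)),
                    "" if r.q_value is None else repr(float(r.q_value)),
                    r.status,
                ]
            )
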