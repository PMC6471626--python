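"""Reading time-series tables and writing causality networks.

The central in-memory container is :class:`TimeSeriesTable`, a labelled
variables-by-time matrix. Missing observations are carried as NaN — an empty
cell or ``NA`` token means "not measured", which is distinct from an observed
zero abundance; the two are never conflated.

Network output targets Cytoscape: a flat edge table (TSV), the simple
interaction format (SIF), and GraphML with typed node/edge attributes. All
writers emit edges in lexicographic (source, target) order so outputs are
byte-stable and diffable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

OTU = "OTU"
ENVIRONMENTAL = "environmental"
VALID_CLASSES = (OTU, ENVIRONMENTAL)

#: tokens interpreted as a missing observation on read
NA_TOKENS = ("", "NA", "NaN", "nan", "na", "N/A")

Orientation = Literal["vars_in_rows", "vars_in_cols"]


@dataclass
class VariableMeta:
    """Per-variable metadata: display name and class (taxon vs measured factor)."""

    var_id: str
    display_name: str
    var_class: str = OTU

    def __post_init__(self) -> None:
        if self.var_class not in VALID_CLASSES:
            raise ValueError(
                f"variable {self.var_id!r}: class must be one of {VALID_CLASSES}, "
                f"got {self.var_class!r}"
            )


@dataclass
class TimeSeriesTable:
    """Variables x time matrix with labels and per-variable class.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_vars, T)``; NaN marks a missing observation.
    var_ids
        Unique variable identifiers, one per row.
    var_class
        Per-variable label, ``"OTU"`` or ``"environmental"``.
    time_labels
        One label per column (sampling dates or plain indices).
    """

    values: np.ndarray
    var_ids: list[str]
    var_class: list[str]
    time_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.var_ids = [str(v) for v in self.var_ids]
        self.time_labels = [str(t) for t in self.time_labels]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (n_vars x T)")
        n, t = self.values.shape
        if len(self.var_ids) != n:
            raise ValueError(f"{len(self.var_ids)} var_ids for {n} rows")
        if len(self.var_class) != n:
            raise ValueError(f"{len(self.var_class)} class labels for {n} rows")
        if len(self.time_labels) != t:
            raise ValueError(f"{len(self.time_labels)} time labels for {t} columns")
        if len(set(self.var_ids)) != n:
            dupes = sorted({v for v in self.var_ids if self.var_ids.count(v) > 1})
            raise ValueError(f"duplicate variable ids: {dupes}")
        if len(set(self.time_labels)) != t:
            raise ValueError("duplicate time labels")
        bad = [c for c in self.var_class if c not in VALID_CLASSES]
        if bad:
            raise ValueError(f"invalid variable classes: {sorted(set(bad))}")

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def index_of(self, var_id: str) -> int:
        try:
            return self.var_ids.index(var_id)
        except ValueError:
            raise KeyError(f"unknown variable id {var_id!r}") from None

    def series(self, var_id: str) -> np.ndarray:
        """Return one variable's time series as a 1-D array (a view)."""
        return self.values[self.index_of(var_id)]

    def class_of(self, var_id: str) -> str:
        return self.var_class[self.index_of(var_id)]

    def class_map(self) -> dict[str, str]:
        return dict(zip(self.var_ids, self.var_class))

    def subset_vars(self, keep_ids: Sequence[str]) -> "TimeSeriesTable":
        idx = [self.index_of(v) for v in keep_ids]
        return TimeSeriesTable(
            values=self.values[idx].copy(),
            var_ids=[self.var_ids[i] for i in idx],
            var_class=[self.var_class[i] for i in idx],
            time_labels=list(self.time_labels),
        )

    def subset_times(self, keep_cols: Sequence[int]) -> "TimeSeriesTable":
        cols = list(keep_cols)
        return TimeSeriesTable(
            values=self.values[:, cols].copy(),
            var_ids=list(self.var_ids),
            var_class=list(self.var_class),
            time_labels=[self.time_labels[c] for c in cols],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.var_ids, columns=self.time_labels)


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(
    path: str | Path,
    orientation: Orientation = "vars_in_rows",
    meta: Mapping[str, VariableMeta] | None = None,
    default_class: str = OTU,
    delimiter: str | None = None,
) -> TimeSeriesTable:
    """Read a delimited abundance/environment table into a TimeSeriesTable.

    The first row and first column are labels. ``orientation`` states whether
    variables run down the rows or across the columns; the returned table is
    always variables x time. Empty cells and ``NA`` tokens become NaN
    (missing); zeros are data. A cell that is neither numeric nor a missing
    token raises with the offending row and column named.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delim, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "vars_in_cols":
        raw = raw.T
    elif orientation != "vars_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    var_ids = [str(v) for v in raw.index]
    if len(set(var_ids)) != len(var_ids):
        dupes = sorted({v for v in var_ids if var_ids.count(v) > 1})
        raise ValueError(f"duplicate variable ids in {path.name}: {dupes}")

    values = np.empty(raw.shape, dtype=float)
    for i, (vid, row) in enumerate(raw.iterrows()):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell in NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at variable {vid!r}, "
                    f"time point {raw.columns[j]!r} in {path.name}"
                ) from None

    classes = []
    for vid in var_ids:
        if meta is not None and vid in meta:
            classes.append(meta[vid].var_class)
        else:
            classes.append(default_class)
    return TimeSeriesTable(
        values=values,
        var_ids=var_ids,
        var_class=classes,
        time_labels=[str(c) for c in raw.columns],
    )


def read_metadata(path: str | Path, delimiter: str | None = None) -> dict[str, VariableMeta]:
    """Read a variable-metadata table (var_id, display_name, class)."""
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str)
    required = {"var_id", "display_name", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata table needs columns {sorted(required)}")
    out: dict[str, VariableMeta] = {}
    for _, row in df.iterrows():
        m = VariableMeta(row["var_id"], row["display_name"], row["class"])
        if m.var_id in out:
            raise ValueError(f"duplicate metadata entry for {m.var_id!r}")
        out[m.var_id] = m
    return out


# ---------------------------------------------------------------------------
# network writers
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["source", "target", "gc", "f_stat", "p_value", "q_value", "status"]


def _edge_records(graph) -> list[dict]:
    """Flatten retained and pruned edges, sorted lexicographically."""
    rows = []
    for res in graph.directed_edges:
        rows.append(
            dict(
                source=res.source_id,
                target=res.target_id,
                gc=res.gc,
                f_stat=res.f_stat,
                p_value=res.p_value,
                q_value=res.q_value,
                status="direct",
            )
        )
    for res in graph.pruned_edges:
        rows.append(
            dict(
                source=res.source_id,
                target=res.target_id,
                gc=res.gc,
                f_stat=res.f_stat,
                p_value=res.p_value,
                q_value=res.q_value,
                status="pruned",
            )
        )
    rows.sort(key=lambda r: (r["source"], r["target"]))
    return rows


def write_network(
    graph,
    path: str | Path,
    format: Literal["edge_tsv", "sif", "graphml"] = "edge_tsv",
) -> Path:
    """Write a finalized causality graph for Cytoscape import.

    ``edge_tsv`` lists every tested-and-retained edge plus pruned ones with a
    status column; ``sif`` lists only retained edges with interaction type
    ``gc``; ``graphml`` round-trips node classes and edge statistics.
    """
    path = Path(path)
    rows = _edge_records(graph)
    if format == "edge_tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(EDGE_COLUMNS)
            for r in rows:
                w.writerow(
                    [
                        r["source"],
                        r["target"],
                        repr(float(r["gc"])),
                        repr(float(r["f_stat"])),
                        repr(float(r["p_value"])),
                        "" if r["q_value"] is None else repr(float(r["q_value"])),
                        r["status"],
                    ]
                )
    elif format == "sif":
        with open(path, "w") as fh:
            for r in rows:
                if r["status"] == "direct":
                    fh.write(f"{r['source']}\tgc\t{r['target']}\n")
    elif format == "graphml":
        g = to_networkx(graph)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def to_networkx(graph) -> nx.DiGraph:
    """Directed-graph view with node class and edge statistics as attributes."""
    g = nx.DiGraph()
    for vid, cls in sorted(graph.vertices.items()):
        g.add_node(vid, var_class=cls)
    for r in _edge_records(graph):
        if r["status"] != "direct":
            continue
        g.add_edge(
            r["source"],
            r["target"],
            gc=float(r["gc"]),
            f_stat=float(r["f_stat"]),
            p_value=float(r["p_value"]),
            q_value=float("nan") if r["q_value"] is None else float(r["q_value"]),
        )
    return g


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read back an ``edge_tsv`` file written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge table lacks columns {sorted(missing)}")
    return df
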