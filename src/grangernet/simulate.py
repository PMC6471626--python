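"""Synthetic VAR time series with known causal structure.

The generator draws from a stable vector autoregression

    x(t) = c + sum_k B_k x(t-k) + e(t),   e(t) ~ N(0, diag(sd^2))

so the true directed graph (nonzero cross-coefficient => edge) is known by
construction and every pipeline stage can be benchmarked without external
data. Optional post-transforms mimic microbial-count quirks (nonnegative
shift, Poisson rounding) and missing values can be injected to exercise the
cleaning steps. Stationarity is enforced up front via the spectral radius of
the companion matrix; a burn-in discards initialisation transients.

Motif helpers build the canonical small structures used to study mediation:
an isolated pair, the chain Y -> Z -> X (whose spurious bivariate Y -> X
edge the conditional test should remove), the fork and the collider.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .bivariate_gc import GCResult
from .io_formats import OTU, TimeSeriesTable
from .network_builder import CausalityGraph

PostTransform = Literal["none", "shift_to_nonnegative", "poisson_round"]


@dataclass
class SimSpec:
    """Complete description of one simulated dataset.

    ``coeffs`` has shape (p_true, n_vars, n_vars); entry ``[k, i, j]`` is the
    effect of variable j's lag k+1 on variable i. Noise is Gaussian with
    per-variable standard deviation. The seed is mandatory: no global random
    state is ever touched.
    """

    n_vars: int
    T: int
    p_true: int
    coeffs: np.ndarray
    noise_sd: np.ndarray | float = 1.0
    intercepts: np.ndarray | float = 0.0
    seed: int = 0
    post_transform: PostTransform = "none"
    missing_rate: float = 0.0
    burn_in: int = 200
    var_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.p_true, self.n_vars, self.n_vars):
            raise ValueError(
                f"coeffs must have shape (p_true, n_vars, n_vars) = "
                f"({self.p_true}, {self.n_vars}, {self.n_vars}), got {self.coeffs.shape}"
            )
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_vars,)
        ).copy()
        self.intercepts = np.broadcast_to(
            np.asarray(self.intercepts, dtype=float), (self.n_vars,)
        ).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.var_ids is None:
            self.var_ids = [f"V{i}" for i in range(self.n_vars)]
        if len(self.var_ids) != self.n_vars:
            raise ValueError("one var_id per variable required")

    def spectral_radius(self) -> float:
        """Spectral radius of the VAR(p) companion matrix."""
        n, p = self.n_vars, self.p_true
        comp = np.zeros((n * p, n * p))
        for k in range(p):
            comp[:n, k * n : (k + 1) * n] = self.coeffs[k]
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def true_edges(self) -> list[tuple[str, str]]:
        """Directed edges implied by nonzero cross-coefficients (j -> i)."""
        edges = set()
        for k in range(self.p_true):
            for i in range(self.n_vars):
                for j in range(self.n_vars):
                    if i != j and self.coeffs[k, i, j] != 0.0:
                        edges.add((self.var_ids[j], self.var_ids[i]))
        return sorted(edges)


def _true_graph(spec: SimSpec) -> CausalityGraph:
    edges = [
        GCResult(s, t, spec.p_true, np.nan, np.nan, spec.p_true, 0, np.nan, None, "ok")
        for s, t in spec.true_edges()
    ]
    return CausalityGraph(
        vertices={v: OTU for v in spec.var_ids}, directed_edges=edges
    )


def simulate_var(spec: SimSpec) -> tuple[TimeSeriesTable, CausalityGraph]:
    """Draw one dataset from the spec; returns the table and the true graph.

    Raises on a non-stationary specification, naming the spectral radius.
    Identical specs (same seed) produce bitwise-identical tables.
    """
    rho = spec.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"non-stationary specification: companion spectral radius {rho:.4f} >= 1"
        )
    rng = np.random.default_rng(spec.seed)
    n, p, total = spec.n_vars, spec.p_true, spec.burn_in + spec.T
    x = np.zeros((total + p, n))
    x[:p] = rng.normal(0.0, spec.noise_sd, size=(p, n))  # init from noise dist
    noise = rng.normal(0.0, spec.noise_sd, size=(total, n))
    for t in range(p, total + p):
        acc = spec.intercepts + noise[t - p]
        for k in range(p):
            acc = acc + spec.coeffs[k] @ x[t - 1 - k]
        x[t] = acc
    values = x[p + spec.burn_in :].T.copy()  # (n_vars, T)

    if spec.post_transform == "shift_to_nonnegative":
        values = values - np.minimum(values.min(axis=1, keepdims=True), 0.0)
    elif spec.post_transform == "poisson_round":
        shifted = values - np.minimum(values.min(axis=1, keepdims=True), 0.0)
        values = rng.poisson(shifted).astype(float)
    elif spec.post_transform != "none":
        raise ValueError(f"unknown post_transform {spec.post_transform!r}")

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = np.nan

    table = TimeSeriesTable(
        values=values,
        var_ids=list(spec.var_ids),
        var_class=[OTU] * n,
        time_labels=[str(t) for t in range(spec.T)],
    )
    return table, _true_graph(spec)


MOTIFS = ("null", "pair", "chain", "fork", "collider")

#: self-dependence of every simulated series; keeps each series an AR(1)
#: with mild memory while leaving ample headroom for cross-effects
DEFAULT_DIAG = 0.3


def make_motif(
    name: Literal["null", "pair", "chain", "fork", "collider"],
    strength: float = 0.6,
    n_extra_noise_vars: int = 0,
    T: int = 300,
    seed: int = 0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    diag: float = DEFAULT_DIAG,
) -> SimSpec:
    """SimSpec for a canonical causal motif plus optional independent noise vars.

    ``chain`` is Y -> Z -> X with no direct Y -> X entry — the scenario in
    which the bivariate scan flags a spurious Y -> X edge that conditioning
    on Z should remove. ``fork`` is Z -> X, Z -> Y (common driver);
    ``collider`` is X -> Z <- Y.
    """
    if name not in MOTIFS:
        raise ValueError(f"unknown motif {name!r}; choose from {MOTIFS}")
    core: dict[str, list[str]] = {
        "null": ["V0", "V1", "V2"],
        "pair": ["X1", "X2"],
        "chain": ["Y", "Z", "X"],
        "fork": ["Z", "X", "Y"],
        "collider": ["X", "Y", "Z"],
    }
    ids = list(core[name])
    cross: list[tuple[str, str]] = {
        "null": [],
        "pair": [("X1", "X2")],
        "chain": [("Y", "Z"), ("Z", "X")],
        "fork": [("Z", "X"), ("Z", "Y")],
        "collider": [("X", "Z"), ("Y", "Z")],
    }[name]
    ids += [f"N{i}" for i in range(n_extra_noise_vars)]
    n = len(ids)
    B = np.zeros((1, n, n))
    np.fill_diagonal(B[0], diag)
    for src, tgt in cross:
        B[0, ids.index(tgt), ids.index(src)] = strength
    spec = SimSpec(
        n_vars=n,
        T=T,
        p_true=1,
        coeffs=B,
        noise_sd=noise_sd,
        seed=seed,
        missing_rate=missing_rate,
        var_ids=ids,
    )
    if spec.spectral_radius() >= 1.0:
        raise ValueError(
            f"strength {strength} makes the motif non-stationary "
            f"(spectral radius {spec.spectral_radius():.3f})"
        )
    return spec
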