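"""Binary graph metrics and small-world characterisation of FC matrices.

A weighted FC matrix is binarised with an absolute threshold (entries
``>= t`` become edges) and described by the standard measures of
brain-network analysis: degree, characteristic path length, clustering
coefficient and global efficiency, plus the small-world index

    sigma = (CC_real / CC_random) / (L_real / L_random)

against an ensemble of uniform random graphs with the same node and
edge counts.

Conventions for disconnected graphs: the characteristic path length L
averages hop counts over *reachable* ordered pairs and reports the
number of unreachable ordered pairs alongside; global efficiency
assigns unreachable pairs zero inverse distance; nodes of degree < 2
have clustering coefficient 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import numpy.typing as npt
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectivity import FCMatrix, inclusive_grid

__all__ = [
    "AdjacencyMatrix",
    "GraphMetricsResult",
    "SmallWorldResult",
    "PathLengthResult",
    "UndefinedMetricError",
    "threshold_adjacency",
    "threshold_grid",
    "node_strength",
    "degrees",
    "characteristic_path_length",
    "clustering",
    "global_efficiency",
    "count_connected_nodes",
    "compute_metrics",
    "random_reference",
    "small_world_index",
    "metrics_table",
]


class UndefinedMetricError(ValueError):
    """The requested metric is undefined on this graph (e.g. no edges)."""


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary undirected graph: symmetric 0/1 matrix with zero diagonal."""

    a: npt.NDArray[np.int_]
    threshold: float | None = None
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "a", a)
        n = a.shape[0]
        labels = tuple(self.labels) if self.labels else tuple(
            f"R{i + 1:03d}" for i in range(n)
        )
        if len(labels) != n:
            raise ValueError("label count does not match size")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.where(np.triu(self.a, k=1))
        return list(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class PathLengthResult:
    """Characteristic path length plus the unreachable-pair count."""

    L: float
    unreachable_pairs: int  # ordered pairs with no connecting path


@dataclass(frozen=True)
class GraphMetricsResult:
    """All scalar and per-node measures of one thresholded network."""

    threshold: float | None
    degree: npt.NDArray[np.float64]
    strength: npt.NDArray[np.float64]
    clustering: npt.NDArray[np.float64]
    average_degree: float
    path_length: float
    unreachable_pairs: int
    global_clustering: float
    efficiency: float
    n_connected_nodes: int


@dataclass(frozen=True)
class SmallWorldResult:
    """Small-world index sigma = gamma / lambda and its ingredients."""

    gamma: float
    lam: float
    sigma: float
    cc_real: float
    l_real: float
    cc_random: float
    l_random: float
    n_realizations: int
    seed: int


def _weights_array(weights: FCMatrix | npt.NDArray[np.float64]) -> tuple[np.ndarray, tuple]:
    if isinstance(weights, FCMatrix):
        return weights.rho, weights.labels
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got {w.shape}")
    return w, ()


def threshold_adjacency(
    weights: FCMatrix | npt.NDArray[np.float64], t: float
) -> AdjacencyMatrix:
    """Binarise: an edge exists where the off-diagonal weight is >= t."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    w, labels = _weights_array(weights)
    a = (w >= t).astype(np.int8)
    a = a & a.T  # preserve symmetry even for near-ties in an asymmetric input
    np.fill_diagonal(a, 0)
    return AdjacencyMatrix(a=a, threshold=float(t), labels=labels)


def threshold_grid(
    t_min: float = 0.0, t_max: float = 0.5, step: float = 0.01
) -> np.ndarray:
    """Inclusive threshold grid; the defaults give 51 values 0, 0.01, ... 0.5."""
    return inclusive_grid(t_min, t_max, step)


def node_strength(weights: FCMatrix | npt.NDArray[np.float64]) -> np.ndarray:
    """Weighted node strength S_i: sum of off-diagonal weights in row i."""
    w, _ = _weights_array(weights)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=1)


def degrees(adj: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Per-node degrees D_i and their mean D."""
    d = adj.a.sum(axis=1).astype(float)
    return d, float(d.mean())


def _distances(adj: AdjacencyMatrix) -> np.ndarray:
    """Hop-count distance matrix (inf where unreachable)."""
    return shortest_path(adj.a, method="D", unweighted=True, directed=False)


def characteristic_path_length(adj: AdjacencyMatrix) -> PathLengthResult:
    """Mean shortest-path hop count over reachable ordered pairs."""
    if adj.n_edges == 0:
        raise UndefinedMetricError("path length undefined on an edgeless graph")
    d = _distances(adj)
    off = ~np.eye(adj.n_nodes, dtype=bool)
    vals = d[off]
    reachable = np.isfinite(vals)
    return PathLengthResult(
        L=float(vals[reachable].mean()),
        unreachable_pairs=int((~reachable).sum()),
    )


def clustering(adj: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients CC_i = 2 e_i / (k_i (k_i - 1))
    (0 where the degree is < 2) and their mean CC over all nodes."""
    a = adj.a.astype(np.int64)
    k = a.sum(axis=1)
    # e_i = number of edges among neighbours of i = (A^3)_ii / 2
    e2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 e_i per node
    cc = np.zeros(adj.n_nodes, dtype=float)
    mask = k >= 2
    cc[mask] = e2[mask] / (k[mask] * (k[mask] - 1))
    return cc, float(cc.mean())


def global_efficiency(adj: AdjacencyMatrix) -> float:
    """Mean inverse hop distance over ordered pairs (0 when unreachable)."""
    d = _distances(adj)
    off = ~np.eye(adj.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def count_connected_nodes(adj: AdjacencyMatrix) -> int:
    """Number of non-isolated nodes (degree >= 1)."""
    return int((adj.a.sum(axis=1) >= 1).sum())


def compute_metrics(
    weights: FCMatrix | npt.NDArray[np.float64], t: float
) -> GraphMetricsResult:
    """Threshold a weighted FC matrix and compute the full metric set.

    Node strength is computed on the weighted matrix; all other
    measures on the binarised graph.
    """
    adj = threshold_adjacency(weights, t)
    deg, avg_deg = degrees(adj)
    cc_i, cc = clustering(adj)
    if adj.n_edges > 0:
        pl = characteristic_path_length(adj)
        length, unreachable = pl.L, pl.unreachable_pairs
    else:
        length, unreachable = np.nan, adj.n_nodes * (adj.n_nodes - 1)
    return GraphMetricsResult(
        threshold=float(t),
        degree=deg,
        strength=node_strength(weights),
        clustering=cc_i,
        average_degree=avg_deg,
        path_length=length,
        unreachable_pairs=unreachable,
        global_clustering=cc,
        efficiency=global_efficiency(adj),
        n_connected_nodes=count_connected_nodes(adj),
    )


def _random_gnm(n: int, m: int, rng: np.random.Generator) -> AdjacencyMatrix:
    """Uniform random simple graph with exactly n nodes and m edges."""
    pairs = comb(n, 2)
    chosen = rng.choice(pairs, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[chosen], ju[chosen]] = 1
    return AdjacencyMatrix(a=a | a.T)


def random_reference(
    adj: AdjacencyMatrix, n_realizations: int = 20, seed: int = 0
) -> tuple[float, float]:
    """Ensemble means (CC_random, L_random) over uniform random graphs
    with the same node and edge counts as ``adj``.

    Realizations that come out disconnected are kept, with L computed
    under the same reachable-ordered-pair convention as the real graph.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if adj.n_edges == 0:
        raise UndefinedMetricError("random reference undefined without edges")
    rng = np.random.default_rng(seed)
    ccs, lens = [], []
    for _ in range(n_realizations):
        g = _random_gnm(adj.n_nodes, adj.n_edges, rng)
        ccs.append(clustering(g)[1])
        lens.append(characteristic_path_length(g).L)
    return float(np.mean(ccs)), float(np.mean(lens))


def small_world_index(
    adj: AdjacencyMatrix, n_realizations: int = 20, seed: int = 0
) -> SmallWorldResult:
    """Small-world index sigma of a binary graph.

    sigma > 1 indicates small-world organisation (clustering well above
    a matched random graph at a comparable path length).
    """
    cc_real = clustering(adj)[1]
    l_real = characteristic_path_length(adj).L
    cc_rand, l_rand = random_reference(adj, n_realizations, seed)
    if cc_rand == 0:
        raise UndefinedMetricError("sigma undefined: random-ensemble clustering is 0")
    gamma = cc_real / cc_rand
    lam = l_real / l_rand
    return SmallWorldResult(
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        cc_real=cc_real,
        l_real=l_real,
        cc_random=cc_rand,
        l_random=l_rand,
        n_realizations=n_realizations,
        seed=seed,
    )


def metrics_table(
    weights: FCMatrix | npt.NDArray[np.float64],
    thresholds: npt.ArrayLike | None = None,
    n_realizations: int = 20,
    seed: int = 0,
    small_world: bool = True,
) -> pd.DataFrame:
    """Threshold sweep: one row of metrics per threshold.

    Columns: threshold, n_connected, D, L, unreachable_pairs, CC, E,
    gamma, lambda, sigma.  Small-world columns are NaN where undefined
    (edgeless graph or zero random clustering).
    """
    if thresholds is None:
        thresholds = threshold_grid()
    rows = []
    for t in np.asarray(thresholds, dtype=float):
        m = compute_metrics(weights, t)
        row = {
            "threshold": t,
            "n_connected": m.n_connected_nodes,
            "D": m.average_degree,
            "L": m.path_length,
            "unreachable_pairs": m.unreachable_pairs,
            "CC": m.global_clustering,
            "E": m.efficiency,
            "gamma": np.nan,
            "lambda": np.nan,
            "sigma": np.nan,
        }
        if small_world:
            adj = threshold_adjacency(weights, t)
            if adj.n_edges > 0:
                try:
                    sw = small_world_index(adj, n_realizations, seed)
                    row.update(gamma=sw.gamma, **{"lambda": sw.lam}, sigma=sw.sigma)
                except UndefinedMetricError:
                    pass
        rows.append(row)
    return pd.DataFrame(rows)
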