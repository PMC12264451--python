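"""Graph-theoretical features of binarized individual metabolic networks.

The weighted network is thresholded on |W| at each point of a sparsity grid
(default 0.20..0.65 step 0.05), binarized, and summarized by small-world
indices (gamma, lambda, sigma against degree-preserving random references),
global/local efficiency, and nodal degree centrality (Dc) and clustering
coefficient (Ncf) at the anterior/posterior insula. Per-feature scalars are
the normalized trapezoid area under the metric-vs-sparsity curve.

Metrics are computed on dense adjacency matrices (56 nodes) with
scipy.sparse.csgraph shortest paths; this keeps Monte-Carlo loops fast.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np

from .metabolic import IndividualNetwork

__all__ = [
    "BinaryGraph",
    "GraphFeatureSet",
    "DEFAULT_SPARSITY_GRID",
    "GRAPH_FEATURE_NAMES",
    "threshold_by_sparsity",
    "nodal_metrics",
    "global_metrics",
    "random_reference_graph",
    "small_world_indices",
    "graph_feature_profile",
]

DEFAULT_SPARSITY_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.20, 0.651, 0.05), 2)
)

GRAPH_FEATURE_NAMES = [
    "sigma", "gamma", "lambda", "e_global", "e_local",
    "dc_ains", "dc_pins", "ncf_ains", "ncf_pins",
]


@dataclass
class BinaryGraph:
    adjacency: np.ndarray  # 0/1, symmetric, zero diagonal
    sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GraphFeatureSet:
    sigma: float
    gamma: float
    lambda_: float
    e_global: float
    e_local: float
    dc_ains: float
    dc_pins: float
    ncf_ains: float
    ncf_pins: float

    def to_array(self) -> np.ndarray:
        return np.array([
            self.sigma, self.gamma, self.lambda_, self.e_global, self.e_local,
            self.dc_ains, self.dc_pins, self.ncf_ains, self.ncf_pins,
        ])


def threshold_by_sparsity(net: IndividualNetwork, sparsity: float) -> BinaryGraph:
    """Keep the round(sparsity * n_pairs) largest-|W| edges, binarized.

    Ties are broken by lexicographic (i, j) order of the upper triangle,
    which np.argsort's stable sort on the flattened triangle provides.
    """
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie strictly between 0 and 1")
    W = net.W
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = np.abs(W[iu, ju])
    n_edges = int(round(sparsity * iu.size))
    order = np.argsort(-weights, kind="stable")[:n_edges]
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[order], ju[order]] = 1
    A |= A.T
    return BinaryGraph(adjacency=A, sparsity=sparsity)


def _triangles(A: np.ndarray) -> np.ndarray:
    Af = A.astype(float)
    return np.einsum("ij,jk,ki->i", Af, Af, Af) / 2.0


def _clustering(A: np.ndarray) -> np.ndarray:
    k = A.sum(axis=1).astype(float)
    t = _triangles(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * t / (k * (k - 1.0)), 0.0)
    return c


def nodal_metrics(g: BinaryGraph, nodes: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Degree centrality and nodal clustering coefficient at ``nodes``."""
    nodes = np.asarray(nodes, dtype=int)
    k = g.adjacency.sum(axis=1)
    c = _clustering(g.adjacency)
    return k[nodes].astype(float), c[nodes]


def _distances(A: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest paths by dense BFS wavefronts."""
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    Au = A.astype(np.uint8)
    reach = np.eye(n, dtype=bool)
    cur = reach.copy()
    d = 0
    while True:
        d += 1
        nxt = ((cur.astype(np.uint8) @ Au) > 0) & ~reach
        if not nxt.any():
            return D
        D[nxt] = d
        reach |= nxt
        cur = nxt


def _efficiency_from_dist(D: np.ndarray) -> float:
    n = D.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def global_metrics(g: BinaryGraph) -> tuple[float, float, float, float]:
    """(C_mean, L_char, e_global, e_local).

    L_char averages shortest paths over connected off-diagonal pairs only;
    unreachable pairs contribute 0 to efficiency (1/inf convention). E_local
    is the mean over nodes of the global efficiency of each node's
    neighbor-induced subgraph (0 for nodes with < 2 neighbors).
    """
    A = g.adjacency
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    c_mean = float(_clustering(A).mean())
    D = _distances(A)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    l_char = float(D[finite].mean()) if finite.any() else np.inf
    e_glob = _efficiency_from_dist(D)
    e_loc_terms = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size >= 2:
            sub = A[np.ix_(nbrs, nbrs)]
            e_loc_terms[i] = _efficiency_from_dist(_distances(sub))
    return c_mean, l_char, e_glob, float(e_loc_terms.mean())


def _c_mean_l_char(A: np.ndarray) -> tuple[float, float]:
    D = _distances(A)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    l_char = float(D[finite].mean()) if finite.any() else np.inf
    return float(_clustering(A).mean()), l_char


def random_reference_graph(
    g: BinaryGraph, n_rewires: int | None = None, seed: int | np.random.Generator = 0
) -> BinaryGraph:
    """Degree-preserving randomization by Maslov-Sneppen double-edge swaps.

    ``n_rewires`` double-edge swap trials (default 10*|E|) are attempted via
    igraph's C implementation; swaps that would create self-loops or
    multi-edges are rejected, so the degree sequence is preserved exactly.
    A graph with fewer than two edges cannot be rewired and is returned
    unchanged with a warning.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = g.n_edges
    if m < 2:
        warnings.warn("graph too small to rewire; returning input")
        return BinaryGraph(g.adjacency.copy(), g.sparsity)
    n_rewires = 10 * m if n_rewires is None else n_rewires
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    h = igraph.Graph(n=g.n_nodes, edges=list(zip(iu.tolist(), ju.tolist())))
    igraph.set_random_number_generator(random.Random(int(rng.integers(2**31))))
    h.rewire(n=n_rewires)
    A = np.zeros_like(g.adjacency)
    e = np.asarray(h.get_edgelist(), dtype=int)
    A[e[:, 0], e[:, 1]] = 1
    A |= A.T
    return BinaryGraph(A, g.sparsity)


def small_world_indices(
    g: BinaryGraph, n_rand: int = 100, seed: int | np.random.Generator = 0
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against degree-preserving random references."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    D = _distances(g.adjacency)
    comp_sizes = np.isfinite(D).sum(axis=1)
    if comp_sizes.max() < 0.9 * g.n_nodes:
        warnings.warn("giant component covers < 90% of nodes; indices unstable")
    c_obs, l_obs = _c_mean_l_char(g.adjacency)
    c_rand, l_rand = [], []
    for _ in range(n_rand):
        r = random_reference_graph(g, seed=rng)
        c, l = _c_mean_l_char(r.adjacency)
        c_rand.append(c)
        l_rand.append(l)
    c_bar = float(np.mean(c_rand))
    l_bar = float(np.mean(l_rand))
    if c_bar == 0:
        warnings.warn("random ensemble has zero clustering; gamma undefined")
        gamma = np.nan
    else:
        gamma = c_obs / c_bar
    lam = l_obs / l_bar if l_bar > 0 else np.nan
    sigma = gamma / lam if lam and np.isfinite(gamma) else np.nan
    return gamma, lam, sigma


def graph_feature_profile(
    net: IndividualNetwork,
    grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID,
    insula_nodes: tuple[int, int] | None = None,
    n_rand: int = 100,
    seed: int = 0,
    return_curves: bool = False,
) -> GraphFeatureSet | tuple[GraphFeatureSet, dict[str, np.ndarray]]:
    """9-feature profile across the sparsity grid, trapezoid-aggregated.

    ``insula_nodes`` defaults to the atlas anterior/posterior insula, resolved
    by label; both must resolve to exactly one node each.
    """
    if len(grid) == 0:
        raise ValueError("sparsity grid must be nonempty")
    if insula_nodes is None:
        matches_a = [i for i, r in enumerate(net.region_labels) if r == "anterior insula"]
        matches_p = [i for i, r in enumerate(net.region_labels) if r == "posterior insula"]
        if len(matches_a) != 1 or len(matches_p) != 1:
            raise ValueError("anterior/posterior insula labels must each match one region")
        insula_nodes = (matches_a[0], matches_p[0])
    rng = np.random.default_rng(seed)
    curves: dict[str, list[float]] = {n: [] for n in GRAPH_FEATURE_NAMES}
    for s in grid:
        g = threshold_by_sparsity(net, s)
        gamma, lam, sig = small_world_indices(g, n_rand=n_rand, seed=rng)
        _, _, e_glob, e_loc = global_metrics(g)
        dc, ncf = nodal_metrics(g, list(insula_nodes))
        for name, val in zip(
            GRAPH_FEATURE_NAMES,
            [sig, gamma, lam, e_glob, e_loc, dc[0], dc[1], ncf[0], ncf[1]],
        ):
            curves[name].append(float(val))
    agg = {n: _trapezoid_mean(np.asarray(grid, float), np.asarray(v)) for n, v in curves.items()}
    fs = GraphFeatureSet(
        sigma=agg["sigma"], gamma=agg["gamma"], lambda_=agg["lambda"],
        e_global=agg["e_global"], e_local=agg["e_local"],
        dc_ains=agg["dc_ains"], dc_pins=agg["dc_pins"],
        ncf_ains=agg["ncf_ains"], ncf_pins=agg["ncf_pins"],
    )
    if return_curves:
        return fs, {n: np.asarray(v) for n, v in curves.items()}
    return fs


def insula_nodal_profile(
    net: IndividualNetwork,
    grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID,
    insula_nodes: tuple[int, int] | None = None,
) -> dict[str, float]:
    """Fast path: only the four insular nodal features (no random ensemble)."""
    if insula_nodes is None:
        insula_nodes = (
            net.region_labels.index("anterior insula"),
            net.region_labels.index("posterior insula"),
        )
    x = np.asarray(grid, float)
    dc_a, dc_p, nc_a, nc_p = [], [], [], []
    for s in grid:
        g = threshold_by_sparsity(net, s)
        dc, ncf = nodal_metrics(g, list(insula_nodes))
        dc_a.append(dc[0]); dc_p.append(dc[1]); nc_a.append(ncf[0]); nc_p.append(ncf[1])
    return {
        "dc_ains": _trapezoid_mean(x, np.asarray(dc_a)),
        "dc_pins": _trapezoid_mean(x, np.asarray(dc_p)),
        "ncf_ains": _trapezoid_mean(x, np.asarray(nc_a)),
        "ncf_pins": _trapezoid_mean(x, np.asarray(nc_p)),
    }


def _trapezoid_mean(x: np.ndarray, y: np.ndarray) -> float:
    if x.size == 1:
        return float(y[0])
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))
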