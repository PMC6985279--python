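"""Moment-by-moment association graphs and degree-preserving null surrogates.

The association between two moments (timepoints) is the partial correlation
of their whole-brain activation patterns, controlling for the mean activation
pattern: each timepoint's feature vector is residualized (ordinary least
squares with intercept) against the across-time mean image, and the Pearson
correlation of the residuals across features is taken. The T x T matrix is
binarized by keeping the top fraction of upper-triangle values as undirected
edges; null graphs preserve every node's degree via Maslov-Sneppen
double-edge swaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seeds import child_seed
from .data_io import ImageSeries

logger = logging.getLogger("temposeq")

__all__ = [
    "AssociationMatrix",
    "AdjacencyGraph",
    "compute_association_matrix",
    "threshold_top_fraction",
    "rewire_preserving_degree",
    "make_surrogate_ensemble",
]


@dataclass
class AssociationMatrix:
    """Symmetric T x T matrix of moment-to-moment partial correlations.

    The diagonal is excluded by convention (self-similarity of a moment is
    uninformative) and stored as 0.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"association matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Simple undirected binary graph over timepoints 0..n_nodes-1.

    ``edges`` is a sorted tuple of (i, j) pairs with i < j.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"invalid edge ({i}, {j}) for {self.n_nodes} nodes")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)


def compute_association_matrix(
    series: ImageSeries, allow_degenerate: bool = False
) -> AssociationMatrix:
    """Partial correlation between all pairs of timepoints, controlling for
    the mean activation image.

    Each row (length-V pattern) is regressed on the across-time mean image m
    (m[v] = mean over t of data[t, v]) with an intercept; entry (i, j) is the
    Pearson correlation of the residual patterns of rows i and j across
    features. Plain correlation across features already removes each image's
    scalar mean, so the partialled covariate is the spatial mean *pattern*,
    not a per-volume scalar.
    """
    data = series.data
    T, V = data.shape
    if V < 3:
        raise ValueError("partial correlation needs at least 3 features")
    m = data.mean(axis=0)
    design = np.column_stack([np.ones(V), m])  # V x 2
    # OLS residuals of every row against [1, m], all rows at once
    coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)  # 2 x T
    resid = data.T - design @ coef  # V x T
    sd = resid.std(axis=0)
    degenerate = np.flatnonzero(sd < 1e-12 * max(1.0, float(np.abs(data).max())))
    if degenerate.size and not allow_degenerate:
        raise ValueError(
            f"timepoints {(degenerate + 1).tolist()} (1-based) are affine functions "
            "of the mean image (zero residual variance); pass allow_degenerate=True "
            "to zero their associations"
        )
    good = np.setdiff1d(np.arange(T), degenerate)
    values = np.zeros((T, T))
    if good.size >= 2:
        sub = np.corrcoef(resid[:, good].T)
        values[np.ix_(good, good)] = sub
    np.fill_diagonal(values, 0.0)
    if degenerate.size:
        logger.warning(
            "zeroed associations for %d degenerate timepoint(s)", degenerate.size
        )
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(values=values)


def threshold_top_fraction(assoc: AssociationMatrix, fraction: float) -> AdjacencyGraph:
    """Binarize by keeping the largest ``fraction`` of upper-triangle values.

    With M = T(T-1)/2 candidate pairs, exactly k = floor(fraction * M) edges
    are kept. Values are ranked signed (most positive first); ties at the
    cutoff are broken toward the pair with smaller i, then smaller j, so the
    result is deterministic. Use ``np.abs`` on the matrix first for
    magnitude-based thresholding.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    T = assoc.n_nodes
    iu, ju = np.triu_indices(T, k=1)
    vals = assoc.values[iu, ju]
    M = vals.size
    k = int(np.floor(fraction * M))
    if k == 0:
        raise ValueError(
            f"fraction {fraction} keeps 0 of {M} pairs; increase the fraction or T"
        )
    # primary key: value descending; ties: smaller i, then smaller j
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    edges = tuple(sorted((int(iu[e]), int(ju[e])) for e in keep))
    return AdjacencyGraph(n_nodes=T, edges=edges)


def rewire_preserving_degree(
    adj: AdjacencyGraph, seed: int, swaps_per_edge: int = 10
) -> AdjacencyGraph:
    """Randomize edge pairings while preserving every node's degree.

    Maslov-Sneppen double-edge swaps: repeatedly pick two edges (u,v), (x,y)
    and replace them with (u,x), (v,y) when the result stays simple.
    ``swaps_per_edge * n_edges`` swap attempts are made. Graphs admitting no
    valid swap (e.g. a triangle) come back unchanged. Output is a
    deterministic function of (adj, seed, swaps_per_edge).
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    m = adj.n_edges
    if m < 2:
        return AdjacencyGraph(n_nodes=adj.n_nodes, edges=adj.edges)
    rng = np.random.default_rng(seed)
    edges = [list(e) for e in adj.edges]
    edge_set = adj.edge_set()
    attempts = swaps_per_edge * m
    picks = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for (a, b), flip in zip(picks, flips):
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if flip:
            x, y = y, x
        if u == x or v == y or u == y or v == x:
            continue  # would create a self-loop or touch a shared node
        new1 = (u, x) if u < x else (x, u)
        new2 = (v, y) if v < y else (y, v)
        if new1 in edge_set or new2 in edge_set:
            continue
        old1 = tuple(sorted(edges[a]))
        old2 = tuple(sorted(edges[b]))
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(new1)
        edge_set.add(new2)
        edges[a] = list(new1)
        edges[b] = list(new2)
    return AdjacencyGraph(n_nodes=adj.n_nodes, edges=tuple(sorted(map(tuple, edges))))


def make_surrogate_ensemble(
    adj: AdjacencyGraph, n: int, seed: int, swaps_per_edge: int = 10
) -> list[AdjacencyGraph]:
    """n independent degree-preserving rewirings with child seeds derived
    from ``seed``; surrogate k is identical no matter how large n is."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        rewire_preserving_degree(adj, seed=child_seed(seed, k), swaps_per_edge=swaps_per_edge)
        for k in range(n)
    ]
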