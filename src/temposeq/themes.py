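"""Temporal community detection: themes, modularity, surrogate contrasts.

A theme is the temporal analog of a network module: a set of timepoints
(possibly non-contiguous) whose global activation patterns cluster together
under modularity maximization on the moment-adjacency graph. The sequence of
theme labels over time is the thematic profile that all downstream
repetition/rhythm/harmony statistics operate on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seeds import child_seed
from .temporal_graph import AdjacencyGraph

__all__ = [
    "ThematicProfile",
    "ThemeSummary",
    "modularity_statistic",
    "detect_themes",
    "theme_summary",
]


@dataclass
class ThematicProfile:
    """Length-T integer theme labels plus the modularity statistic q.

    Labels are >= 1; ``n_themes`` is always the number of distinct labels.
    """

    labels: np.ndarray
    q: float
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D integer vector")
        if (self.labels < 1).any():
            raise ValueError("theme labels must be integers >= 1")

    @property
    def n_timepoints(self) -> int:
        return self.labels.size

    @property
    def n_themes(self) -> int:
        return int(np.unique(self.labels).size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ThematicProfile):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and self.q == other.q
            and self.tr_seconds == other.tr_seconds
        )


def modularity_statistic(adj: AdjacencyGraph, labels) -> float:
    """Newman-Girvan modularity Q = sum_c (e_cc - a_c^2).

    e_cc is the fraction of edges inside community c and a_c the fraction of
    edge endpoints attached to c. Q quantifies how far within-community
    connectivity exceeds the expectation of a degree-matched random graph;
    range is a subset of [-1, 1).
    """
    labels = np.asarray(labels)
    if labels.size != adj.n_nodes:
        raise ValueError(
            f"labels cover {labels.size} nodes but graph has {adj.n_nodes}"
        )
    m = adj.n_edges
    if m == 0:
        raise ValueError("modularity is undefined for an empty edge set")
    communities = np.unique(labels)
    intra = {c: 0 for c in communities}
    endpoint = {c: 0 for c in communities}
    for i, j in adj.edges:
        ci, cj = labels[i], labels[j]
        if ci == cj:
            intra[ci] += 1
        endpoint[ci] += 1
        endpoint[cj] += 1
    q = 0.0
    for c in communities:
        e_cc = intra[c] / m
        a_c = endpoint[c] / (2 * m)
        q += e_cc - a_c**2
    return float(q)


def _labels_from_communities(communities, n_nodes: int) -> np.ndarray:
    raw = np.empty(n_nodes, dtype=int)
    raw.fill(-1)
    for k, nodes in enumerate(communities):
        for node in nodes:
            raw[node] = k
    if (raw < 0).any():
        raise ValueError("community cover misses nodes")
    return _canonicalize_labels(raw)


def _canonicalize_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by order of first appearance in time."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for t, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[t] = mapping[lab]
    return out


def detect_themes(
    adj: AdjacencyGraph,
    gamma: float = 1.0,
    restarts: int = 100,
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> ThematicProfile:
    """Partition moments into themes by Louvain modularity maximization.

    Louvain is stochastic, so it is restarted ``restarts`` times with child
    seeds derived from ``seed`` and the partition with the highest
    Newman-Girvan q is kept (first-found wins ties). Labels are renumbered
    1..K by first appearance in time so output is canonical and diffable.
    """
    import networkx as nx

    if adj.n_edges == 0:
        raise ValueError("cannot detect themes on an empty graph")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    g = adj.to_networkx()
    best_q = -np.inf
    best_labels: np.ndarray | None = None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            g, resolution=gamma, seed=child_seed(seed, r)
        )
        labels = _labels_from_communities(comms, adj.n_nodes)
        q = modularity_statistic(adj, labels)
        if q > best_q:
            best_q = q
            best_labels = labels
    assert best_labels is not None
    return ThematicProfile(labels=best_labels, q=best_q, tr_seconds=tr_seconds)


@dataclass
class ThemeSummary:
    """Observed-vs-surrogate contrast for the modularity stage."""

    q: float
    surrogate_q_mean: float
    surrogate_q_sd: float
    p: float
    significant: bool
    n_themes: int
    surrogate_modal_n_themes: int
    n_surrogates: int

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "surrogate_q_mean": self.surrogate_q_mean,
            "surrogate_q_sd": self.surrogate_q_sd,
            "p": self.p,
            "significant": self.significant,
            "n_themes": self.n_themes,
            "surrogate_modal_n_themes": self.surrogate_modal_n_themes,
            "n_surrogates": self.n_surrogates,
        }


def theme_summary(
    profile: ThematicProfile,
    surrogate_profiles: list[ThematicProfile],
    alpha: float = 0.05,
) -> ThemeSummary:
    """Compare observed modularity and theme count to the surrogate ensemble.

    ``surrogate_profiles`` must come from :func:`detect_themes` run on each
    degree-preserving surrogate graph with identical settings. The test is a
    one-tailed surrogate t-test on q (observed greater).
    """
    from .group_stats import one_tailed_surrogate_test

    if len(surrogate_profiles) < 2:
        raise ValueError("need at least 2 surrogate profiles")
    surr_q = np.array([p.q for p in surrogate_profiles])
    test = one_tailed_surrogate_test(profile.q, surr_q)
    counts = Counter(p.n_themes for p in surrogate_profiles)
    # modal count; ties broken toward the smaller count for determinism
    modal = min(c for c, k in counts.items() if k == max(counts.values()))
    return ThemeSummary(
        q=profile.q,
        surrogate_q_mean=float(surr_q.mean()),
        surrogate_q_sd=float(surr_q.std(ddof=1)),
        p=test.p,
        significant=test.p < alpha,
        n_themes=profile.n_themes,
        surrogate_modal_n_themes=int(modal),
        n_surrogates=len(surrogate_profiles),
    )
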