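"""Shared fixtures.

The expensive end-to-end chain (T=300 periodic series, 100 degree-preserving
surrogates pushed through the full downstream pipeline) is computed once per
session and shared by the pipeline and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import temposeq as tq
from temposeq.temporal_graph import AdjacencyGraph


def make_planted_block_graph(
    n_per_block: int = 30,
    n_blocks: int = 3,
    p_in: float = 0.9,
    p_out: float = 0.02,
    seed: int = 42,
) -> tuple[AdjacencyGraph, np.ndarray]:
    """Stochastic block graph with groups interleaved in time.

    Node t belongs to block (t mod n_blocks) + 1, so planted themes are
    distributed across the whole epoch rather than contiguous.
    """
    n = n_per_block * n_blocks
    labels = np.arange(n) % n_blocks + 1
    rng = np.random.default_rng(seed)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                edges.append((i, j))
    return AdjacencyGraph(n_nodes=n, edges=tuple(edges)), labels


@pytest.fixture(scope="session")
def planted_block_graph():
    return make_planted_block_graph()


def two_cliques_graph(k: int = 5) -> AdjacencyGraph:
    """Two disconnected k-cliques on nodes 0..k-1 and k..2k-1."""
    edges = []
    for base in (0, k):
        edges += [(base + i, base + j) for i in range(k) for j in range(i + 1, k)]
    return AdjacencyGraph(n_nodes=2 * k, edges=tuple(sorted(edges)))


@pytest.fixture(scope="session")
def chain_result():
    """Full observed + surrogate chain on a planted periodic series.

    T=300 timepoints from K=5 orthogonal patterns on a period-30 schedule
    (every length-n window recurs every 30 timepoints), sigma=0.5, top-5%
    threshold, 100 surrogates, motif lengths 4..11.
    """
    series, truth = tq.generate_image_series(
        T=300, V=500, K=5, noise_sigma=0.5, transition_spec=("periodic", 30), seed=7
    )
    cfg = tq.RunConfig(rng_seed=7, louvain_restarts=5, n_surrogates=100)
    result = tq.analyze_series(series, cfg)
    return {"series": series, "truth": truth, "config": cfg, "result": result}
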