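"""Deterministic synthetic graph generators.

These provide the structured inputs the summarizer is exercised on:
planted partitions (community structure with redundant neighborhoods),
twin pairs (nodes with identical neighbor sets, the guaranteed-positive-
saving case), Erdos-Renyi noise graphs, and the small weighted worked
example used throughout the personalized mode.  All generators are
deterministic under their seed.
"""

from __future__ import annotations

import numpy as np

from .graph_io import Graph, NodeIdMap

__all__ = ["planted_partition", "erdos_renyi", "twins", "fig_weighted_example"]


def _pairs_from_mask(n: int, prob: np.ndarray, rng: np.random.Generator) -> frozenset:
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < prob
    return frozenset(zip(iu[keep].tolist(), ju[keep].tolist()))


def planted_partition(n: int, k: int, p_in: float, p_out: float, seed: int) -> Graph:
    """k blocks of ~n/k nodes; edge prob p_in inside a block, p_out across.

    The last block absorbs the remainder when k does not divide n.
    """
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    rng = np.random.default_rng(seed)
    block_size = n // k
    block = np.minimum(np.arange(n) // max(block_size, 1), k - 1)
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(block[iu] == block[ju], p_in, p_out)
    return Graph(n_nodes=n, edges=_pairs_from_mask(n, prob, rng))


def erdos_renyi(n: int, p: float, seed: int) -> Graph:
    """G(n, p), seeded."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return Graph(n_nodes=n, edges=_pairs_from_mask(n, np.full(n * (n - 1) // 2, p), rng))


def twins(n_pairs: int, shared_degree: int, seed: int = 0) -> Graph:
    """Disjoint twin pairs: nodes 2i, 2i+1 share an identical neighbor set.

    Twins have weighted Jaccard 1 and a merge saving of about 1/2, so they
    are the canonical guaranteed-merge fixture.  The seed only shuffles the
    pair-to-neighbor assignment order and is kept for API symmetry.
    """
    if n_pairs < 1 or shared_degree < 1:
        raise ValueError("n_pairs and shared_degree must be >= 1")
    edges = set()
    base = 2 * n_pairs
    for i in range(n_pairs):
        a, b = 2 * i, 2 * i + 1
        for j in range(shared_degree):
            v = base + i * shared_degree + j
            edges.add((a, v))
            edges.add((b, v))
    return Graph(n_nodes=base + n_pairs * shared_degree, edges=frozenset(edges))


def fig_weighted_example() -> tuple[Graph, NodeIdMap, set[int]]:
    """The 5-node weighted influence example with target A.

    Edges A-E:5, A-G:4, G-B:5, B-F:3.  Flow rates from A are 5 to E, 4 to
    G, 9 to B through G, and 12 to F through G and B.
    """
    idmap = NodeIdMap()
    for label in ("A", "E", "G", "B", "F"):
        idmap.add(label)
    w = {
        ("A", "E"): 5,
        ("A", "G"): 4,
        ("G", "B"): 5,
        ("B", "F"): 3,
    }
    weights = {}
    for (lu, lv), wt in w.items():
        u, v = idmap.id(lu), idmap.id(lv)
        weights[(min(u, v), max(u, v))] = wt
    g = Graph(n_nodes=5, edges=frozenset(weights), weights=weights)
    return g, idmap, {idmap.id("A")}
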