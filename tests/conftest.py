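"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's incremental state: costs are
re-derived by enumerating member pairs straight from the edge set, and flow
rates by enumerating minimum-hop paths with networkx.  They exist to check
the implementation, so they must stay dumb and direct.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from ipgs.graph_io import Graph, canon
from ipgs.summary_core import SummaryState


def oracle_pair_cost(g: Graph, members_a: set[int], members_b: set[int]) -> int:
    """Half-rule cost of one super pair by direct pair enumeration."""
    if members_a is members_b or members_a == members_b:
        pairs = list(itertools.combinations(sorted(members_a), 2))
    else:
        pairs = [canon(u, v) for u in members_a for v in members_b]
    e = sum(1 for p in pairs if p in g.edges)
    f = len(pairs)
    if e == 0:
        return 0
    return e if 2 * e <= f else 1 + f - e


def oracle_node_cost(g: Graph, partition: list[set[int]], idx: int) -> int:
    """Cost(A, S): full cost of every pair incident to A, self included."""
    total = oracle_pair_cost(g, partition[idx], partition[idx])
    for j, other in enumerate(partition):
        if j != idx:
            total += oracle_pair_cost(g, partition[idx], other)
    return total


def oracle_total_size(g: Graph, partition: list[set[int]]) -> int:
    """|E/| + |C+| + |C-|: every unordered pair class counted once."""
    total = sum(oracle_pair_cost(g, p, p) for p in partition)
    for a, b in itertools.combinations(partition, 2):
        total += oracle_pair_cost(g, a, b)
    return total


def oracle_merge_saving(g: Graph, partition: list[set[int]], i: int, j: int) -> float:
    """Merge saving recomputed from scratch on the hypothetical merge."""
    ca = oracle_node_cost(g, partition, i)
    cb = oracle_node_cost(g, partition, j)
    merged = partition[i] | partition[j]
    rest = [p for k, p in enumerate(partition) if k not in (i, j)]
    cm = oracle_node_cost(g, rest + [merged], len(rest))
    return 1.0 - cm / (ca + cb)


def oracle_greedy_size(g: Graph) -> int:
    """Exhaustive best-pair greedy: merge the global best pair while the
    saving is strictly positive; returns the final summary size."""
    st = SummaryState(g)
    while True:
        best, pair = 0.0, None
        ids = sorted(st.s.super_to_members)
        costs = {a: st.node_cost(a) for a in ids}
        for a, b in itertools.combinations(ids, 2):
            denom = costs[a] + costs[b]
            if denom == 0:
                continue
            sav = 1.0 - st.merged_cost(a, b) / denom
            if sav > best:
                best, pair = sav, (a, b)
        if pair is None:
            return st.total_size()
        st.apply_merge(*pair)


def oracle_flow_rates(g: Graph, targets: set[int]) -> dict[int, float]:
    """Max cumulative weight over minimum-hop paths, by path enumeration."""
    nxg = g.to_networkx()
    src = "__virtual__"
    nxg.add_node(src)
    for t in targets:
        nxg.add_edge(src, t, weight=0)
    r: dict[int, float] = {}
    for v in range(g.n_nodes):
        if v == src or not nx.has_path(nxg, src, v):
            continue
        best = None
        for path in nx.all_shortest_paths(nxg, src, v):  # min hop count
            w = sum(nxg[a][b]["weight"] for a, b in zip(path, path[1:]))
            best = w if best is None else max(best, w)
        r[v] = float(best)
    return r


@pytest.fixture
def path3() -> Graph:
    """0-1-2 path."""
    return Graph(n_nodes=3, edges=frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def twin_fixture() -> Graph:
    """Nodes 0,1 each adjacent to exactly {2,3,4}: the saving-1/2 case."""
    return Graph(
        n_nodes=5,
        edges=frozenset({(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)}),
    )
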