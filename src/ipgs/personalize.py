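"""Flow rates from target nodes and the personalized flow view.

The influence of a target set on the rest of the graph is modelled as a
cumulative flow rate: nodes are layered by hop count from the targets
(multi-source BFS) and a node's rate is the best it can inherit from the
previous layer,

    r(v) = max over neighbors u one hop closer of  r(u) + w(u, v),

with r(target) = 0.  Edge weights act as per-hop flow increments, so the
rate accumulates along minimum-hop paths and the ``parent`` pointer records
the best such path.  On the worked weighted example (target A; edges A-E:5,
A-G:4, G-B:5, B-F:3) this yields r(E)=5, r(G)=4, r(B)=9 through G, and
r(F)=12 through G and B.

Rates feed the summarizer two ways: targets are pinned as singleton super
nodes, and edge importances 1 + alpha * max(rho(u), rho(v)) (rho = r
normalized to [0, 1], targets at 1) make corrections near influential nodes
more expensive, keeping the summary fine-grained there.  ``flow_view``
extracts the l strongest flows into a small lossy summary for display,
maximizing the sum of selected terminal rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import inf

from .exceptions import IpgsError
from .graph_io import Edge, Graph, canon
from .summary_core import SummaryGraph, SuperNodeMap

logger = logging.getLogger(__name__)

__all__ = [
    "FlowRates",
    "PersonalizationConfig",
    "flow_rates",
    "edge_importance",
    "flow_view",
]


@dataclass
class FlowRates:
    targets: set[int]
    r: dict[int, float]  # defined exactly on nodes reachable from targets
    parent: dict[int, int | None]  # flow-path predecessor; None for targets


@dataclass(frozen=True)
class PersonalizationConfig:
    targets: tuple[str, ...] = ()
    alpha: float = 1.0  # importance strength; 0 disables personalization
    k: int = 4  # clusters kept in the flow view
    l: int = 4  # flows kept in the flow view

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.k < 1 or self.l < 1:
            raise ValueError("k and l must be >= 1")


def flow_rates(g: Graph, targets: set[int]) -> FlowRates:
    """Layered max-sum flow rates from the target set (multi-source BFS)."""
    if not targets:
        raise IpgsError("target set is empty")
    for t in targets:
        if not 0 <= t < g.n_nodes:
            raise IpgsError(f"unknown target node id {t}")
    adj = g.adjacency()
    dist = {t: 0 for t in targets}
    r: dict[int, float] = {t: 0.0 for t in targets}
    parent: dict[int, int | None] = {t: None for t in targets}
    frontier = sorted(targets)
    d = 0
    while frontier:
        nxt: set[int] = set()
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    nxt.add(v)
        d += 1
        for v in sorted(nxt):
            best, best_u = -inf, None
            for u in sorted(adj[v]):
                if dist.get(u) == d - 1:
                    cand = r[u] + adj[v][u]
                    if cand > best:  # ties keep the smallest u (sorted scan)
                        best, best_u = cand, u
            dist[v] = d
            r[v] = best
            parent[v] = best_u
        frontier = sorted(nxt)
    return FlowRates(targets=set(targets), r=r, parent=parent)


def edge_importance(g: Graph, fr: FlowRates, alpha: float) -> dict[Edge, float]:
    """Per-edge importance 1 + alpha * max(rho(u), rho(v)), always >= 1.

    rho is r normalized by the maximum rate (targets count as 1, unreachable
    nodes as 0), so the importance field is invariant to rescaling all edge
    weights by a constant.
    """
    max_r = max((v for k, v in fr.r.items() if k not in fr.targets), default=0.0)

    def rho(v: int) -> float:
        if v in fr.targets:
            return 1.0
        if v not in fr.r or max_r == 0:
            return 0.0
        return fr.r[v] / max_r

    return {e: 1.0 + alpha * max(rho(e[0]), rho(e[1])) for e in g.edges}


def flow_view(g: Graph, fr: FlowRates, k: int, l: int) -> tuple[SummaryGraph, float]:
    """Extract the l strongest flows into at most k clusters plus targets.

    Flows are parent chains ending at the l reachable non-target nodes with
    the largest rates; the objective is the sum of those terminal rates.
    Retained non-target nodes are grouped by the strongest flow that uses
    them; overflow beyond k clusters folds into the last cluster.  The view
    is lossy by design (visualization aid) — nodes off the selected flows
    are dropped.
    """
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    reachable = sorted(
        (v for v in fr.r if v not in fr.targets), key=lambda v: (-fr.r[v], v)
    )
    if l > len(reachable):
        logger.warning("l=%d exceeds %d reachable nodes; truncating", l, len(reachable))
        l = len(reachable)
    terminals = reachable[:l]
    objective = float(sum(fr.r[t] for t in terminals))

    clusters: list[set[int]] = []
    assigned: set[int] = set()
    for t in terminals:
        chain = []
        v: int | None = t
        while v is not None and v not in fr.targets:
            if v not in assigned:
                chain.append(v)
                assigned.add(v)
            v = fr.parent[v]
        if chain:
            if len(clusters) < k:
                clusters.append(set(chain))
            else:
                clusters[-1] |= set(chain)

    node_to_super: dict[int, int] = {}
    super_to_members: dict[int, set[int]] = {}
    for t in sorted(fr.targets):
        node_to_super[t] = t
        super_to_members[t] = {t}
    for members in clusters:
        sid = min(members)
        super_to_members[sid] = set(members)
        for m in members:
            node_to_super[m] = sid
    retained = set(node_to_super)
    superedges: set[tuple[int, int]] = set()
    for u, v in g.edges:
        if u in retained and v in retained:
            a, b = node_to_super[u], node_to_super[v]
            if a != b or len(super_to_members[a]) > 1:
                superedges.add((min(a, b), max(a, b)))
    view = SummaryGraph(SuperNodeMap(node_to_super, super_to_members), superedges)
    return view, objective
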