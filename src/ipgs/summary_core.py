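"""Correction-set representation of a lossless graph summary.

A summary is a partition of the original vertices into super nodes plus a
set of super edges and two correction lists.  A super edge between super
nodes A and B asserts *all* member pairs; C+ re-adds original edges that no
super edge implies, C- deletes implied pairs that are absent from the
original graph.  Decoding (expand super edges, subtract C-, add C+) always
reproduces the input exactly.

Whether a super pair is encoded as a super edge is decided by the half
rule: with ``E_AB`` actual member edges out of ``F_AB`` possible member
pairs, the pair is stored as corrections only when ``E_AB <= F_AB / 2``
(cost ``E_AB`` entries in C+) and as a super edge otherwise (cost
``1 + F_AB - E_AB``: the edge plus its C- entries).  The per-super-node
cost is the sum of the encoding costs of every incident pair, self pair
included; the saving of a candidate merge of super nodes 1 and 2 is

    saving = 1 - Cost(1 u 2) / (Cost(1) + Cost(2))

where the merged cost is evaluated hypothetically, with the pair (1,2)
folded into the merged node's self pair.  Merging is virtual during the
iteration loop — correction lists are materialized once at the end by
:func:`encode_all`.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import CorruptSummaryError, InvalidMergeError, UndefinedSavingError
from .graph_io import Edge, Graph, NodeIdMap, canon

__all__ = [
    "EncodeMode",
    "SuperNodeMap",
    "PairEncoding",
    "CorrectionSets",
    "SummaryGraph",
    "CostTable",
    "SummaryState",
    "pair_stats",
    "encode_pair",
    "node_cost",
    "merge_saving",
    "apply_merge",
    "encode_all",
    "decode",
    "write_summary",
    "read_summary",
]


class EncodeMode(enum.Enum):
    CORRECTIONS_ONLY = "corrections_only"
    SUPEREDGE = "superedge"


@dataclass
class SuperNodeMap:
    """A partition of the original nodes into super nodes.

    Super-node ids are original node ids; the surviving id after a merge is
    the smaller one, so ids are stable and deterministic.
    """

    node_to_super: dict[int, int]
    super_to_members: dict[int, set[int]]

    @classmethod
    def identity(cls, n_nodes: int) -> "SuperNodeMap":
        return cls(
            node_to_super={v: v for v in range(n_nodes)},
            super_to_members={v: {v} for v in range(n_nodes)},
        )

    def size(self, a: int) -> int:
        return len(self.super_to_members[a])

    def check_partition(self, n_nodes: int) -> None:
        seen: set[int] = set()
        for sid, members in self.super_to_members.items():
            if not members:
                raise ValueError(f"empty super node {sid}")
            if seen & members:
                raise ValueError("super-node members are not disjoint")
            seen |= members
            for m in members:
                if self.node_to_super.get(m) != sid:
                    raise ValueError(f"node_to_super inconsistent at node {m}")
        if seen != set(range(n_nodes)):
            raise ValueError("super-node members do not cover V")

    def copy(self) -> "SuperNodeMap":
        return SuperNodeMap(
            dict(self.node_to_super),
            {k: set(v) for k, v in self.super_to_members.items()},
        )


@dataclass(frozen=True)
class PairEncoding:
    """Edge statistics of one super pair (self pairs allowed, a <= b)."""

    super_a: int
    super_b: int
    e_count: int
    f_possible: int
    mode: EncodeMode

    @property
    def cost(self) -> int:
        """Entries this pair contributes to |E/| + |C+| + |C-|."""
        return _pair_cost(self.e_count, self.f_possible)


def _pair_cost(e: int, f: int) -> int:
    # half rule: corrections cost e; super edge costs 1 + (f - e)
    if e == 0:
        return 0
    return e if 2 * e <= f else 1 + f - e


def _pair_mode(e: int, f: int) -> EncodeMode:
    return EncodeMode.SUPEREDGE if 2 * e > f else EncodeMode.CORRECTIONS_ONLY


@dataclass
class CorrectionSets:
    c_plus: list[Edge] = field(default_factory=list)
    c_minus: list[Edge] = field(default_factory=list)


@dataclass
class SummaryGraph:
    supernodes: SuperNodeMap
    superedges: set[tuple[int, int]]  # (a, b) with a <= b; a == b allowed


class SummaryState:
    """Mutable merge state: partition plus super-level edge counts.

    ``adj[a][b]`` counts original edges between distinct super nodes a, b;
    ``internal[a]`` counts edges inside a.  With ``edge_importance`` given
    (personalized mode), importance sums are tracked in parallel and every
    pair's encoding cost is scaled by the mean importance of its present
    member edges; the unweighted counts still define ``total_size``.
    """

    def __init__(
        self,
        g: Graph,
        s: SuperNodeMap | None = None,
        edge_importance: dict[Edge, float] | None = None,
    ) -> None:
        self.g = g
        self.s = s.copy() if s is not None else SuperNodeMap.identity(g.n_nodes)
        self.imp = edge_importance
        self.adj: dict[int, dict[int, int]] = {a: {} for a in self.s.super_to_members}
        self.internal: dict[int, int] = {a: 0 for a in self.s.super_to_members}
        self.adj_imp: dict[int, dict[int, float]] | None = None
        self.internal_imp: dict[int, float] | None = None
        if self.imp is not None:
            self.adj_imp = {a: {} for a in self.s.super_to_members}
            self.internal_imp = {a: 0.0 for a in self.s.super_to_members}
        n2s = self.s.node_to_super
        for u, v in g.edges:
            a, b = n2s[u], n2s[v]
            w = 1.0 if self.imp is None else float(self.imp[(u, v)])
            if a == b:
                self.internal[a] += 1
                if self.internal_imp is not None:
                    self.internal_imp[a] += w
            else:
                self.adj[a][b] = self.adj[a].get(b, 0) + 1
                self.adj[b][a] = self.adj[b].get(a, 0) + 1
                if self.adj_imp is not None:
                    self.adj_imp[a][b] = self.adj_imp[a].get(b, 0.0) + w
                    self.adj_imp[b][a] = self.adj_imp[b].get(a, 0.0) + w

    # -- pair statistics ---------------------------------------------------

    def _check(self, a: int) -> None:
        if a not in self.s.super_to_members:
            raise InvalidMergeError(f"unknown super node {a}")

    def _f_possible(self, a: int, b: int) -> int:
        if a == b:
            na = self.s.size(a)
            return na * (na - 1) // 2
        return self.s.size(a) * self.s.size(b)

    def _e_count(self, a: int, b: int) -> int:
        return self.internal[a] if a == b else self.adj[a].get(b, 0)

    def pair_stats(self, a: int, b: int) -> PairEncoding:
        self._check(a)
        self._check(b)
        a, b = min(a, b), max(a, b)
        e = self._e_count(a, b)
        f = self._f_possible(a, b)
        return PairEncoding(a, b, e, f, _pair_mode(e, f))

    def _weighted_pair_cost(self, e: int, f: int, imp_sum: float) -> float:
        if e == 0:
            return 0.0
        return _pair_cost(e, f) * (imp_sum / e)

    def pair_cost(self, a: int, b: int) -> float:
        """Encoding cost of one pair, importance-scaled when personalized."""
        e = self._e_count(a, b)
        f = self._f_possible(a, b)
        if self.imp is None:
            return float(_pair_cost(e, f))
        if a == b:
            isum = self.internal_imp[a]  # type: ignore[index]
        else:
            isum = self.adj_imp[a].get(b, 0.0)  # type: ignore[index]
        return self._weighted_pair_cost(e, f, isum)

    def node_cost(self, a: int) -> float:
        """Cost(a, S): full cost of every pair incident to a (self included)."""
        self._check(a)
        total = self.pair_cost(a, a)
        for b in self.adj[a]:
            total += self.pair_cost(a, b)
        return total

    # -- merge evaluation --------------------------------------------------

    def merge_saving(self, a: int, b: int, costs: "CostTable | None" = None) -> float:
        """Merge saving of hypothetically combining a and b (see module docs)."""
        self._check(a)
        self._check(b)
        if a == b:
            raise InvalidMergeError(f"cannot merge super node {a} with itself")
        ca = costs.get(a) if costs is not None else self.node_cost(a)
        cb = costs.get(b) if costs is not None else self.node_cost(b)
        denom = ca + cb
        if denom == 0:
            raise UndefinedSavingError(f"both super nodes {a}, {b} have zero cost")
        return 1.0 - self.merged_cost(a, b) / denom

    def merged_cost(self, a: int, b: int) -> float:
        """Cost(a u b): node cost of the hypothetical merged super node."""
        m = self.s.size(a) + self.s.size(b)
        # self pair of the union: internals of both plus the a-b pair
        e_self = self.internal[a] + self.internal[b] + self.adj[a].get(b, 0)
        f_self = m * (m - 1) // 2
        if self.imp is None:
            total = float(_pair_cost(e_self, f_self))
        else:
            isum = (
                self.internal_imp[a]  # type: ignore[index]
                + self.internal_imp[b]  # type: ignore[index]
                + self.adj_imp[a].get(b, 0.0)  # type: ignore[index]
            )
            total = self._weighted_pair_cost(e_self, f_self, isum)
        for c in set(self.adj[a]) | set(self.adj[b]):
            if c in (a, b):
                continue
            e = self.adj[a].get(c, 0) + self.adj[b].get(c, 0)
            f = m * self.s.size(c)
            if self.imp is None:
                total += _pair_cost(e, f)
            else:
                isum = self.adj_imp[a].get(c, 0.0) + self.adj_imp[b].get(c, 0.0)  # type: ignore[index]
                total += self._weighted_pair_cost(e, f, isum)
        return total

    def apply_merge(self, a: int, b: int, costs: "CostTable | None" = None) -> int:
        """Merge b into a (survivor = smaller id); returns the survivor."""
        self._check(a)
        self._check(b)
        if a == b:
            raise InvalidMergeError(f"cannot merge super node {a} with itself")
        keep, gone = min(a, b), max(a, b)
        s = self.s
        for m in s.super_to_members[gone]:
            s.node_to_super[m] = keep
        s.super_to_members[keep] |= s.super_to_members.pop(gone)

        self.internal[keep] += self.internal.pop(gone) + self.adj[keep].pop(gone, 0)
        gone_adj = self.adj.pop(gone)
        gone_adj.pop(keep, None)
        touched = set(gone_adj) | set(self.adj[keep])
        for c, e in gone_adj.items():
            self.adj[keep][c] = self.adj[keep].get(c, 0) + e
            del self.adj[c][gone]
            self.adj[c][keep] = self.adj[keep][c]
        for c in self.adj[keep]:
            self.adj[c][keep] = self.adj[keep][c]
        if self.imp is not None:
            self.internal_imp[keep] += self.internal_imp.pop(gone) + self.adj_imp[keep].pop(gone, 0.0)  # type: ignore[index]
            gone_imp = self.adj_imp.pop(gone)  # type: ignore[union-attr]
            gone_imp.pop(keep, None)
            for c, w in gone_imp.items():
                self.adj_imp[keep][c] = self.adj_imp[keep].get(c, 0.0) + w  # type: ignore[index]
                del self.adj_imp[c][gone]  # type: ignore[index]
                self.adj_imp[c][keep] = self.adj_imp[keep][c]  # type: ignore[index]
        if costs is not None:
            costs.invalidate({keep, gone} | touched)
        return keep

    def total_size(self) -> int:
        """|E/| + |C+| + |C-| of the current partition (unweighted counts)."""
        total = 0
        for a in self.s.super_to_members:
            total += _pair_cost(self.internal[a], self._f_possible(a, a))
            for b, e in self.adj[a].items():
                if a < b:
                    total += _pair_cost(e, self._f_possible(a, b))
        return total


class CostTable:
    """Lazily cached Cost(a, S) values over a :class:`SummaryState`.

    Entries are invalidated by :meth:`SummaryState.apply_merge` for the
    merged node and every neighbor whose pair statistics changed.
    """

    def __init__(self, state: SummaryState) -> None:
        self.state = state
        self._cache: dict[int, float] = {}

    def get(self, a: int) -> float:
        if a not in self._cache:
            self._cache[a] = self.state.node_cost(a)
        return self._cache[a]

    def invalidate(self, ids) -> None:
        for a in ids:
            self._cache.pop(a, None)

    @property
    def total_size(self) -> int:
        return self.state.total_size()


# -- functional API over (g, s) -------------------------------------------


def pair_stats(a: int, b: int, g: Graph, s: SuperNodeMap) -> PairEncoding:
    return SummaryState(g, s).pair_stats(a, b)


def node_cost(a: int, g: Graph, s: SuperNodeMap) -> float:
    return SummaryState(g, s).node_cost(a)


def merge_saving(a: int, b: int, g: Graph, s: SuperNodeMap, costs: CostTable | None = None) -> float:
    return SummaryState(g, s).merge_saving(a, b, costs)


def apply_merge(a: int, b: int, s: SuperNodeMap, costs: CostTable | None = None) -> int:
    """Merge on a bare partition (no cached state); survivor = min id."""
    if a == b:
        raise InvalidMergeError(f"cannot merge super node {a} with itself")
    if a not in s.super_to_members or b not in s.super_to_members:
        raise InvalidMergeError(f"unknown super node in merge ({a}, {b})")
    keep, gone = min(a, b), max(a, b)
    for m in s.super_to_members[gone]:
        s.node_to_super[m] = keep
    s.super_to_members[keep] |= s.super_to_members.pop(gone)
    if costs is not None:
        costs.invalidate({keep, gone})
    return keep


def _member_edges(g: Graph, members_a, members_b, self_pair: bool) -> tuple[list[Edge], list[Edge]]:
    """Present and absent member pairs of one super pair, both sorted."""
    if self_pair:
        pairs = itertools.combinations(sorted(members_a), 2)
    else:
        pairs = (canon(u, v) for u in members_a for v in members_b)
    present, absent = [], []
    for p in pairs:
        (present if p in g.edges else absent).append(p)
    return sorted(present), sorted(absent)


def encode_pair(
    pe: PairEncoding, g: Graph, s: SuperNodeMap
) -> tuple[tuple[int, int] | None, list[Edge], list[Edge]]:
    """Materialize one pair: (superedge or None, C+ additions, C- additions)."""
    a, b = pe.super_a, pe.super_b
    present, absent = _member_edges(
        g, s.super_to_members[a], s.super_to_members[b], self_pair=a == b
    )
    if len(present) != pe.e_count or len(present) + len(absent) != pe.f_possible:
        raise ValueError("PairEncoding inconsistent with graph and partition")
    if pe.e_count == 0:
        return None, [], []
    if pe.mode is EncodeMode.CORRECTIONS_ONLY:
        return None, present, []
    return (a, b), [], absent


def encode_all(g: Graph, s: SuperNodeMap) -> tuple[SummaryGraph, CorrectionSets]:
    """Encode every member-pair class of the partition; deterministic order."""
    pair_present: dict[tuple[int, int], list[Edge]] = {}
    for u, v in g.edges:
        a, b = s.node_to_super[u], s.node_to_super[v]
        key = (a, b) if a <= b else (b, a)
        pair_present.setdefault(key, []).append(canon(u, v))
    superedges: set[tuple[int, int]] = set()
    corr = CorrectionSets()
    for (a, b), present in sorted(pair_present.items()):
        e = len(present)
        if a == b:
            na = len(s.super_to_members[a])
            f = na * (na - 1) // 2
        else:
            f = len(s.super_to_members[a]) * len(s.super_to_members[b])
        if 2 * e <= f:
            corr.c_plus.extend(sorted(present))
        else:
            superedges.add((a, b))
            _, absent = _member_edges(
                g, s.super_to_members[a], s.super_to_members[b], self_pair=a == b
            )
            corr.c_minus.extend(absent)
    corr.c_plus.sort()
    corr.c_minus.sort()
    return SummaryGraph(s.copy(), superedges), corr


def decode(sg: SummaryGraph, c: CorrectionSets, n_nodes: int) -> Graph:
    """Reconstruct the original graph exactly from a summary.

    Raises :class:`CorruptSummaryError` if a C+ edge is already implied by a
    super edge or a C- edge is not implied.
    """
    edges: set[Edge] = set()
    members = sg.supernodes.super_to_members
    for a, b in sg.superedges:
        present, absent = [], []
        if a == b:
            it = itertools.combinations(sorted(members[a]), 2)
        else:
            it = (canon(u, v) for u in members[a] for v in members[b])
        edges.update(it)
    for e in c.c_minus:
        e = canon(*e)
        if e not in edges:
            raise CorruptSummaryError(f"C- edge {e} is not implied by any super edge")
        edges.remove(e)
    for e in c.c_plus:
        e = canon(*e)
        if e in edges:
            raise CorruptSummaryError(f"C+ edge {e} is already implied by a super edge")
        edges.add(e)
    return Graph(n_nodes=n_nodes, edges=frozenset(edges))


# -- summary serialization (TSV dialect) -----------------------------------


def write_summary(prefix: str | Path, sg: SummaryGraph, c: CorrectionSets, idmap: NodeIdMap) -> None:
    """Write ``<prefix>.{supernodes,superedges,cplus,cminus}.tsv`` sorted."""
    prefix = str(prefix)
    with open(prefix + ".supernodes.tsv", "w") as fh:
        for sid in sorted(sg.supernodes.super_to_members):
            for m in sorted(sg.supernodes.super_to_members[sid]):
                fh.write(f"{sid}\t{idmap.label(m)}\n")
    with open(prefix + ".superedges.tsv", "w") as fh:
        for a, b in sorted(sg.superedges):
            fh.write(f"{a}\t{b}\n")
    for name, lst in (("cplus", c.c_plus), ("cminus", c.c_minus)):
        with open(f"{prefix}.{name}.tsv", "w") as fh:
            for u, v in sorted(canon(*e) for e in lst):
                fh.write(f"{idmap.label(u)}\t{idmap.label(v)}\n")


def read_summary(prefix: str | Path) -> tuple[SummaryGraph, CorrectionSets, NodeIdMap]:
    """Inverse of :func:`write_summary`; ids are re-assigned by row order."""
    prefix = str(prefix)
    idmap = NodeIdMap()
    node_to_super: dict[int, int] = {}
    super_to_members: dict[int, set[int]] = {}
    with open(prefix + ".supernodes.tsv") as fh:
        for line in fh:
            sid_s, label = line.rstrip("\n").split("\t")
            sid = int(sid_s)
            i = idmap.add(label)
            node_to_super[i] = sid
            super_to_members.setdefault(sid, set()).add(i)
    superedges: set[tuple[int, int]] = set()
    with open(prefix + ".superedges.tsv") as fh:
        for line in fh:
            a, b = (int(t) for t in line.split())
            superedges.add((min(a, b), max(a, b)))
    corr = CorrectionSets()
    for name, lst in (("cplus", corr.c_plus), ("cminus", corr.c_minus)):
        with open(f"{prefix}.{name}.tsv") as fh:
            for line in fh:
                lu, lv = line.rstrip("\n").split("\t")
                lst.append(canon(idmap.id(lu), idmap.id(lv)))
    sg = SummaryGraph(SuperNodeMap(node_to_super, super_to_members), superedges)
    return sg, corr, idmap
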