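"""Edge-list input/output and visualization export.

Graphs are simple and undirected: each edge is stored once as an ordered
pair ``(u, v)`` with ``u < v``.  External node labels are mapped to
contiguous 0-based internal ids in first-appearance order; every other
module operates on ids only.

The on-disk dialect is a SNAP-style TSV edge list: one edge per line,
``src<TAB>dst`` with an optional third positive-integer weight column, and
``#``-prefixed comment lines.  Real-world dumps routinely contain duplicate
lines, reversed duplicates and self loops; these are cleaned (and counted in
the log), not treated as fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .exceptions import ParseError

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


def canon(u: int, v: int) -> Edge:
    """Canonical undirected edge: smaller endpoint first."""
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Graph:
    """A simple undirected graph over ids ``0..n_nodes-1``.

    ``weights`` maps canonical edges to positive integers; ``None`` means
    the graph is unweighted (all weights 1).
    """

    n_nodes: int
    edges: frozenset[Edge]
    weights: Mapping[Edge, int] | None = None

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if not (0 <= u < v < self.n_nodes):
                raise ValueError(f"invalid edge ({u}, {v}) for n_nodes={self.n_nodes}")
        if self.weights is not None:
            if set(self.weights) != set(self.edges):
                raise ValueError("weights must cover exactly the edge set")
            if any(w < 1 or int(w) != w for w in self.weights.values()):
                raise ValueError("edge weights must be integers >= 1")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, u: int, v: int) -> int:
        e = canon(u, v)
        if e not in self.edges:
            raise KeyError(f"no edge {e}")
        return 1 if self.weights is None else int(self.weights[e])

    def adjacency(self) -> list[dict[int, int]]:
        """Per-node neighbor→weight maps."""
        adj: list[dict[int, int]] = [dict() for _ in range(self.n_nodes)]
        for u, v in self.edges:
            w = 1 if self.weights is None else int(self.weights[(u, v)])
            adj[u][v] = w
            adj[v][u] = w
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for u, v in self.edges:
            g.add_edge(u, v, weight=self.weight(u, v))
        return g


@dataclass
class NodeIdMap:
    """Bijection between external labels and contiguous internal ids."""

    id_to_label: list[str] = field(default_factory=list)
    label_to_id: dict[str, int] = field(default_factory=dict)

    def add(self, label: str) -> int:
        if label in self.label_to_id:
            return self.label_to_id[label]
        i = len(self.id_to_label)
        self.id_to_label.append(label)
        self.label_to_id[label] = i
        return i

    def label(self, i: int) -> str:
        return self.id_to_label[i]

    def id(self, label: str) -> int:
        return self.label_to_id[label]

    def __len__(self) -> int:
        return len(self.id_to_label)

    @classmethod
    def identity(cls, n: int) -> "NodeIdMap":
        m = cls()
        for i in range(n):
            m.add(str(i))
        return m


def read_edge_list(path: str | Path, weighted: bool = False) -> tuple[Graph, NodeIdMap]:
    """Parse a SNAP-style TSV edge list.

    Labels are mapped to ids in first-appearance order.  Duplicate lines and
    reversed duplicates collapse to one edge (first weight wins, with a
    warning); self-loop lines are dropped and counted.  A malformed line
    raises :class:`ParseError` with its line number.
    """
    idmap = NodeIdMap()
    weights: dict[Edge, int] = {}
    n_dupes = n_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("# nodes:"):
                # optional node roster: pins label order and isolated nodes
                for label in line[len("# nodes:"):].split():
                    idmap.add(label)
                continue
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if weighted and len(toks) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns (weighted), got {len(toks)}")
            if len(toks) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(toks)}")
            u = idmap.add(toks[0])
            v = idmap.add(toks[1])
            if weighted:
                try:
                    w = int(toks[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: weight {toks[2]!r} is not an integer") from None
                if w < 1:
                    raise ParseError(f"{path}:{lineno}: weight must be >= 1, got {w}")
            else:
                w = 1
            if u == v:
                n_loops += 1
                continue
            e = canon(u, v)
            if e in weights:
                n_dupes += 1
            else:
                weights[e] = w
    if n_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_loops)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate edge line(s) (kept first weight)", path, n_dupes)
    g = Graph(
        n_nodes=len(idmap),
        edges=frozenset(weights),
        weights=dict(weights) if weighted else None,
    )
    return g, idmap


def write_edge_list(g: Graph, idmap: NodeIdMap, path: str | Path) -> None:
    """Write ``g`` in the same dialect, deterministically sorted by id pair."""
    with open(path, "w") as fh:
        fh.write(f"# ipgs edge list: {g.n_nodes} nodes, {g.n_edges} edges\n")
        if g.n_nodes:
            roster = "\t".join(idmap.label(i) for i in range(g.n_nodes))
            fh.write(f"# nodes:\t{roster}\n")
        for u, v in sorted(g.edges):
            if g.weights is None:
                fh.write(f"{idmap.label(u)}\t{idmap.label(v)}\n")
            else:
                fh.write(f"{idmap.label(u)}\t{idmap.label(v)}\t{g.weights[(u, v)]}\n")


def export_visualization(
    g_or_summary,
    idmap: NodeIdMap,
    path: str | Path,
    format: str = "graphml",
    targets: Iterable[int] = (),
) -> None:
    """Export a graph or summary graph for Gephi-class visualization tools.

    Super nodes carry a comma-joined ``members`` attribute and an integer
    ``size``; target nodes carry ``is_target=true``.  Formats: GraphML, GML.
    """
    from .summary_core import SummaryGraph  # local import avoids a cycle

    fmt = format.lower()
    if fmt not in ("graphml", "gml"):
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'gml'")
    targets = set(targets)
    out = nx.Graph()
    if isinstance(g_or_summary, SummaryGraph):
        sn = g_or_summary.supernodes
        for sid in sorted(sn.super_to_members):
            members = sorted(sn.super_to_members[sid])
            out.add_node(
                f"S{sid}",
                members=",".join(idmap.label(m) for m in members),
                size=len(members),
                is_target=bool(targets & set(members)),
            )
        for a, b in sorted(g_or_summary.superedges):
            out.add_edge(f"S{a}", f"S{b}")
    elif isinstance(g_or_summary, Graph):
        g = g_or_summary
        for i in range(g.n_nodes):
            out.add_node(idmap.label(i), size=1, is_target=i in targets)
        for u, v in sorted(g.edges):
            out.add_edge(idmap.label(u), idmap.label(v), weight=g.weight(u, v))
    else:
        raise TypeError(f"cannot export {type(g_or_summary).__name__}")
    if fmt == "graphml":
        nx.write_graphml(out, path)
    else:
        nx.write_gml(out, path)
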