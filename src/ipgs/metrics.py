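"""Size accounting and the compression ratio.

Sizes are information-theoretic estimates in bits: each original edge costs
two node ids of log2(n) bits, so

    size(original) = O_edges * 2 * log2(O_nodes),
    size(summary)  = S_edges * 2 * log2(S_nodes) + O_nodes * log2(S_nodes),

where S_edges counts super edges plus both correction lists (the summary is
lossless, so corrections are part of the stored representation) and the
second term is the node-to-super-node membership map.  The compression
ratio is size(summary) / size(original); below 1 means the summary is
smaller.  log2 is real-valued, not rounded up per id.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

from .exceptions import CorruptSummaryError, UndefinedSizeError
from .graph_io import Graph
from .summary_core import CorrectionSets, SummaryGraph, decode

__all__ = ["CompressionReport", "original_size", "summary_size", "compression_ratio"]


@dataclass
class CompressionReport:
    o_nodes: int
    o_edges: int
    s_nodes: int
    superedges: int
    c_plus_size: int
    c_minus_size: int
    s_edges_total: int  # |E/| + |C+| + |C-|
    size_original_bits: float
    size_summary_bits: float
    ratio: float | None  # None when undefined (empty or degenerate graph)

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2, sort_keys=True)


def original_size(o_edges: int, o_nodes: int) -> float:
    """Estimated bit size of the original graph: O_edges * 2 * log2(O_nodes)."""
    if o_nodes < 2:
        raise UndefinedSizeError(f"original size undefined for {o_nodes} node(s)")
    return o_edges * 2.0 * math.log2(o_nodes)


def summary_size(s_edges: int, s_nodes: int, o_nodes: int) -> float:
    """Estimated bit size of the summary, membership map included."""
    if s_nodes < 2:
        raise UndefinedSizeError(f"summary size undefined for {s_nodes} super node(s)")
    return s_edges * 2.0 * math.log2(s_nodes) + o_nodes * math.log2(s_nodes)


def compression_ratio(
    summary: SummaryGraph | "object",
    corrections: CorrectionSets | None = None,
    g: Graph | None = None,
) -> CompressionReport:
    """Build a :class:`CompressionReport`; audits losslessness first.

    Accepts either ``(SummaryGraph, CorrectionSets, Graph)`` or a
    ``SummaryResult``-like object (with ``.summary``/``.corrections``) plus
    the graph.
    """
    if corrections is None or g is None:
        if g is None:
            raise TypeError("compression_ratio needs the original graph")
        sg = summary.summary  # type: ignore[attr-defined]
        corrections = summary.corrections  # type: ignore[attr-defined]
    else:
        sg = summary
    if decode(sg, corrections, g.n_nodes).edges != g.edges:
        raise CorruptSummaryError("summary does not decode to the original graph")
    s_nodes = len(sg.supernodes.super_to_members)
    s_edges_total = len(sg.superedges) + len(corrections.c_plus) + len(corrections.c_minus)
    defined = g.n_nodes >= 2 and s_nodes >= 2 and g.n_edges > 0
    size_o = original_size(g.n_edges, g.n_nodes) if g.n_nodes >= 2 else 0.0
    size_s = summary_size(s_edges_total, s_nodes, g.n_nodes) if s_nodes >= 2 else 0.0
    return CompressionReport(
        o_nodes=g.n_nodes,
        o_edges=g.n_edges,
        s_nodes=s_nodes,
        superedges=len(sg.superedges),
        c_plus_size=len(corrections.c_plus),
        c_minus_size=len(corrections.c_minus),
        s_edges_total=s_edges_total,
        size_original_bits=size_o,
        size_summary_bits=size_s,
        ratio=(size_s / size_o) if defined else None,
    )
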