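"""The iterative summarization drivers.

Each iteration builds weighted neighborhood vectors for the current super
nodes, signs them with DOPH, groups equal signatures into candidate groups,
and greedily merges within each group: super nodes are visited in a seeded
random order and each one takes its maximum-saving partner if the saving
clears the iteration's acceptance threshold theta(t) = 1/(1+t) — greedy
early, permissive late.  Merging is virtual; after the last iteration the
partition is materialized into super edges and correction sets, which makes
the result lossless by construction (and it is audited by decoding).

The personalized variant first computes flow rates from the target set,
pins every target as a singleton super node, scales neighborhood vectors
and pair-encoding costs by edge importance, and otherwise runs the same
loop — with an empty target set and alpha = 0 it degenerates to the
non-personalized run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import IpgsError
from .graph_io import Graph
from .metrics import CompressionReport, compression_ratio
from .personalize import PersonalizationConfig, edge_importance, flow_rates
from .summary_core import (
    CorrectionSets,
    CostTable,
    SummaryGraph,
    SummaryState,
    encode_all,
)
from .wlsh import DophConfig, Signature, divide_groups, mix64, neighbor_vector, _sign

__all__ = ["SummarizerConfig", "SummaryResult", "threshold", "merge_phase", "summarize", "summarize_personalized"]


@dataclass(frozen=True)
class SummarizerConfig:
    iterations: int = 20  # T
    signature_length: int = 5  # K
    seed: int = 42
    max_group_size: int = 500
    weight_cap: int = 16
    threshold_schedule: Callable[[int], float] | None = None
    personalization: PersonalizationConfig = PersonalizationConfig()

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SummaryResult:
    summary: SummaryGraph
    corrections: CorrectionSets
    report: CompressionReport
    trace: list[tuple[int, int]] = field(default_factory=list)  # (merges, total_size)


def threshold(t: int, cfg: SummarizerConfig | None = None) -> float:
    """Merge-acceptance threshold at iteration t; default 1/(1+t) -> 0."""
    if cfg is not None and cfg.threshold_schedule is not None:
        return cfg.threshold_schedule(t)
    return 1.0 / (1.0 + t)


def merge_phase(
    groups: Sequence[set[int]],
    t: int,
    state: SummaryState,
    costs: CostTable,
    cfg: SummarizerConfig,
    rng: np.random.Generator,
    pinned: frozenset[int] = frozenset(),
) -> int:
    """Greedy within-group merging at iteration t; returns accepted merges.

    Within each group the super nodes are visited in a seeded random order;
    the visited node takes the partner with the maximum merge saving
    (ties -> smallest id) and the merge is accepted iff saving >= theta(t).
    Pinned (target) nodes never participate.  Accepted merges update the
    state immediately, so later visits see the new partition.
    """
    theta = threshold(t, cfg)
    accepted = 0
    for group in groups:
        if len(group) < 2:
            continue
        order = sorted(group)
        rng.shuffle(order)
        for u in order:
            if u in pinned or u not in state.s.super_to_members:
                continue
            best_saving, best_v = -np.inf, None
            for v in sorted(group):
                if v == u or v in pinned or v not in state.s.super_to_members:
                    continue
                cu, cv = costs.get(u), costs.get(v)
                if cu + cv == 0:
                    continue  # both isolated; saving undefined
                saving = 1.0 - state.merged_cost(u, v) / (cu + cv)
                if saving > best_saving:
                    best_saving, best_v = saving, v
            if best_v is not None and best_saving >= theta:
                state.apply_merge(u, best_v, costs)
                accepted += 1
    return accepted


def _run(
    g: Graph,
    cfg: SummarizerConfig,
    target_ids: Sequence[int] = (),
) -> SummaryResult:
    targets = frozenset(target_ids)
    imp = None
    if targets:
        fr = flow_rates(g, set(targets))
        imp = edge_importance(g, fr, cfg.personalization.alpha)
    state = SummaryState(g, edge_importance=imp)
    costs = CostTable(state)
    trace: list[tuple[int, int]] = []
    for t in range(1, cfg.iterations + 1):
        sigs: list[Signature] = []
        binvecs = {}
        singleton_groups: list[set[int]] = []
        doph_cfg = DophConfig(
            signature_length=cfg.signature_length,
            seed=mix64(cfg.seed ^ (t * 0x5851F42D)) & 0x7FFFFFFF,
            weight_cap=cfg.weight_cap,
        )
        for a in sorted(state.s.super_to_members):
            vec = neighbor_vector(a, g, state.s, importance=imp)
            if not vec.entries:
                singleton_groups.append({a})  # isolated super node: never merges
                continue
            binvecs[a] = vec
            sigs.append(_sign(vec, doph_cfg))
        groups = divide_groups(sigs, cfg.max_group_size, doph_cfg, binvecs)
        groups.groups.extend(singleton_groups)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, t]))
        merges = merge_phase(groups.groups, t, state, costs, cfg, rng, pinned=targets)
        trace.append((merges, state.total_size()))
    sg, corr = encode_all(g, state.s)
    report = compression_ratio(sg, corr, g)
    return SummaryResult(summary=sg, corrections=corr, report=report, trace=trace)


def summarize(g: Graph, cfg: SummarizerConfig | None = None) -> SummaryResult:
    """Summarize ``g``: T rounds of sign/divide/merge, then encode."""
    return _run(g, cfg or SummarizerConfig())


def summarize_personalized(
    g: Graph,
    target_ids: Sequence[int],
    cfg: SummarizerConfig | None = None,
) -> SummaryResult:
    """Personalized summarization: targets pinned, costs importance-weighted.

    The result is exactly as lossless as the plain variant; with no targets
    it is identical to :func:`summarize` under the same seed.
    """
    cfg = cfg or SummarizerConfig()
    for t in target_ids:
        if not 0 <= t < g.n_nodes:
            raise IpgsError(f"unknown target node id {t}")
    return _run(g, cfg, target_ids=target_ids)
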