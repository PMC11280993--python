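"""Weighted Jaccard similarity and DOPH candidate grouping.

Super nodes are compared by their weighted neighborhood vectors: entry v of
the vector of super node A is the total edge weight from members of A to
original node v.  Similarity is the weighted Jaccard

    Jw(A, B) = sum_v min(A_v, B_v) / sum_v max(A_v, B_v),

and candidate merge groups are built with densified one-permutation hashing
(DOPH): the vector is binarized by unary expansion (an entry of weight w
occupies min(w, cap) slots), slot indices are permuted by a seeded 64-bit
bijective mixer, the permuted space is split into K equal bins, each bin
keeps its smallest permuted index, and empty bins borrow from the nearest
non-empty bin to the right (cyclically).  Two vectors collide in a bin with
probability Jw, so equal signatures flag likely merge partners in a single
pass — no per-hash repetition as in classic minhash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .exceptions import EmptyVectorError, UndefinedSimilarityError
from .graph_io import Graph, canon
from .summary_core import SuperNodeMap

__all__ = [
    "WeightedNeighborVector",
    "DophConfig",
    "Signature",
    "CandidateGroups",
    "neighbor_vector",
    "weighted_jaccard",
    "binarize_expand",
    "doph_signature",
    "divide_groups",
]

_GOLDEN = 0x9E3779B97F4A7C15


def mix64(x: np.ndarray | int) -> np.ndarray | int:
    """Bijective 64-bit finalizer (splitmix64); injective on any slot set."""
    scalar = np.isscalar(x)
    z = np.asarray(x, dtype=np.uint64).copy()
    with np.errstate(over="ignore"):
        z ^= z >> np.uint64(30)
        z *= np.uint64(0xBF58476D1CE4E5B9)
        z ^= z >> np.uint64(27)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(31)
    return int(z) if scalar else z


@dataclass(frozen=True)
class WeightedNeighborVector:
    """Sparse integer-weighted neighborhood of one super node."""

    owner: int
    entries: dict[int, int]  # node id -> weight >= 1
    dimension: int

    def __post_init__(self) -> None:
        for v, w in self.entries.items():
            if not 0 <= v < self.dimension:
                raise ValueError(f"entry {v} outside dimension {self.dimension}")
            if w < 1:
                raise ValueError(f"weight {w} for entry {v} must be >= 1")


@dataclass(frozen=True)
class DophConfig:
    signature_length: int = 5  # K
    seed: int = 0
    weight_cap: int = 16  # max unary slots per entry

    def __post_init__(self) -> None:
        if self.signature_length < 1:
            raise ValueError("signature_length must be >= 1")
        if self.weight_cap < 1:
            raise ValueError("weight_cap must be >= 1")


@dataclass(frozen=True)
class Signature:
    owner: int
    bins: tuple[int, ...]


@dataclass
class CandidateGroups:
    groups: list[set[int]] = field(default_factory=list)


def neighbor_vector(
    a: int,
    g: Graph,
    s: SuperNodeMap,
    importance: dict[tuple[int, int], float] | None = None,
) -> WeightedNeighborVector:
    """Weighted neighborhood of super node ``a`` over original node ids.

    Entry v sums the weights of edges from members of ``a`` to v.  With an
    ``importance`` map (personalized mode) each edge's contribution is
    scaled by its importance and the entry is rounded up to stay a positive
    integer, so corrections near targets dominate the similarity.
    """
    entries: dict[int, float] = {}
    members = s.super_to_members[a]
    for m in members:
        for v, w in _adjacency(g)[m].items():
            scale = 1.0 if importance is None else importance[canon(m, v)]
            entries[v] = entries.get(v, 0.0) + w * scale
    return WeightedNeighborVector(
        owner=a,
        entries={v: max(1, ceil(w)) for v, w in entries.items()},
        dimension=g.n_nodes,
    )


# adjacency is rebuilt per Graph instance; memoized on id for the iteration loop
_adj_cache: dict[int, tuple[Graph, list[dict[int, int]]]] = {}


def _adjacency(g: Graph) -> list[dict[int, int]]:
    hit = _adj_cache.get(id(g))
    if hit is not None and hit[0] is g:
        return hit[1]
    adj = g.adjacency()
    _adj_cache.clear()
    _adj_cache[id(g)] = (g, adj)
    return adj


def weighted_jaccard(x: WeightedNeighborVector, y: WeightedNeighborVector) -> float:
    """Jw = sum min / sum max over the union of supports; in [0, 1]."""
    if x.dimension != y.dimension:
        raise ValueError("vectors have different dimensions")
    support = set(x.entries) | set(y.entries)
    if not support:
        raise UndefinedSimilarityError("both vectors are all-zero")
    num = den = 0
    for v in support:
        a, b = x.entries.get(v, 0), y.entries.get(v, 0)
        num += min(a, b)
        den += max(a, b)
    return num / den


def binarize_expand(x: WeightedNeighborVector, cap: int) -> np.ndarray:
    """Unary expansion: entry (v, w) sets slots v*cap + j for j < min(w, cap).

    Returns the sorted array of set slot indices in a space of size
    ``dimension * cap``.  All-weights-1 vectors set one slot per neighbor.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    slots: list[int] = []
    for v, w in x.entries.items():
        base = v * cap
        slots.extend(range(base, base + min(w, cap)))
    return np.array(sorted(slots), dtype=np.uint64)


def doph_signature(binvec: np.ndarray, cfg: DophConfig) -> Signature:
    """One-permutation K-bin minhash signature with right-cyclic densification.

    Slot indices are sent through a seeded bijective 64-bit mix; the 64-bit
    key space is split into K equal bins; each bin's value is the smallest
    key that lands in it, and an empty bin copies the value of the nearest
    non-empty bin to its right (wrapping around).
    """
    binvec = np.asarray(binvec, dtype=np.uint64)
    if binvec.size == 0:
        raise EmptyVectorError("cannot sign an all-zero vector")
    k = cfg.signature_length
    key_salt = np.uint64(mix64((cfg.seed & 0xFFFFFFFFFFFFFFFF) ^ _GOLDEN))
    keys = mix64(binvec ^ key_salt)
    # bin index via the top 32 bits: floor(key / 2^64 * K) without bigints
    idx = ((keys >> np.uint64(32)) * np.uint64(k)) >> np.uint64(32)
    bins: list[int | None] = [None] * k
    for i, key in zip(idx.tolist(), keys.tolist()):
        if bins[i] is None or key < bins[i]:
            bins[i] = key
    # densify: borrow from the nearest non-empty bin to the right, cyclically
    out = list(bins)
    for i in range(k):
        if out[i] is None:
            for step in range(1, k):
                cand = bins[(i + step) % k]
                if cand is not None:
                    out[i] = cand
                    break
    return Signature(owner=-1, bins=tuple(out))  # owner set by callers


def _sign(vec: WeightedNeighborVector, cfg: DophConfig) -> Signature:
    sig = doph_signature(binarize_expand(vec, cfg.weight_cap), cfg)
    return Signature(owner=vec.owner, bins=sig.bins)


def divide_groups(
    signatures: list[Signature],
    max_group_size: int,
    cfg: DophConfig,
    binvecs: dict[int, WeightedNeighborVector] | None = None,
) -> CandidateGroups:
    """Partition super nodes into candidate groups by signature equality.

    Groups exceeding ``max_group_size`` are recursively split by re-signing
    their members with one more bin and a derived seed; a group whose
    members' vectors are identical is irreducible and kept as is.
    """
    groups = _group_by_signature(signatures)
    if binvecs is None:
        return CandidateGroups(groups=[set(g) for g in groups])
    out: list[set[int]] = []
    for g in groups:
        out.extend(_split(g, max_group_size, cfg, binvecs, depth=1))
    return CandidateGroups(groups=out)


def _group_by_signature(signatures: list[Signature]) -> list[list[int]]:
    buckets: dict[tuple[int, ...], list[int]] = {}
    for sig in signatures:
        buckets.setdefault(sig.bins, []).append(sig.owner)
    return [sorted(v) for _, v in sorted(buckets.items())]


def _split(
    members: list[int],
    max_group_size: int,
    cfg: DophConfig,
    binvecs: dict[int, WeightedNeighborVector],
    depth: int,
) -> list[set[int]]:
    if len(members) <= max_group_size or depth > 64:
        return [set(members)]
    sub_cfg = DophConfig(
        signature_length=cfg.signature_length + depth,
        seed=mix64(cfg.seed ^ depth) & 0x7FFFFFFFFFFFFFFF,
        weight_cap=cfg.weight_cap,
    )
    sigs = [_sign(binvecs[m], sub_cfg) for m in members]
    sub = _group_by_signature(sigs)
    if len(sub) == 1:  # identical signatures — try deeper, may be irreducible
        vecs = {tuple(sorted(binvecs[m].entries.items())) for m in members}
        if len(vecs) == 1:
            return [set(members)]
    out: list[set[int]] = []
    for grp in sub:
        out.extend(_split(grp, max_group_size, cfg, binvecs, depth + 1))
    return out
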