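# Methods

## Representation and cost model

A summary is a partition `V/` of the vertex set plus super edges `E/` and
correction lists `C+`, `C-`. All costs are entry counts in
`|E/| + |C+| + |C-|`; edge weights never enter the cost model (corrections
are unweighted edge lists) — weights feed only the similarity signatures
and the personalized mode.

For one super pair with `e` present member edges out of `f` possible
member pairs, the half rule gives an encoding cost

    c(e, f) = 0            if e = 0
            = e            if 2e <= f     (corrections only)
            = 1 + f - e    if 2e > f      (super edge + C-)

equivalently `min(e, 1 + f - e)` for `e > 0`. The boundary `2e = f` is
deliberately kept on the corrections side. `Cost(A, S)` attributes the
*full* cost of every pair incident to `A` (self pair included) to `A`.
The shared-pair cost of `(A, B)` is therefore counted in both `Cost(A)`
and `Cost(B)`; since the same attribution is used in the numerator and
denominator of the merge saving

    saving(1, 2) = 1 - Cost(1 ∪ 2) / (Cost(1) + Cost(2)),

the ratio is well defined. In `Cost(1 ∪ 2)` the former (1,2) pair folds
into the merged node's self pair. Two worked invariants pin the scale:
twin nodes sharing three singleton neighbors save exactly 1/2, and a merge
of two unrelated well-compressed nodes is penalized (saving −1/2 in the
canonical fixture).

Note that `c(e, f)` is not subadditive in corner cases (merging can turn a
cheap super-edge pair into a more expensive mixed pair), so iteration-level
size monotonicity is an empirical property of thresholded merging, not a
theorem; the trace is asserted non-increasing on all tested fixtures.

Merging is *virtual*: during iterations only the partition and per-pair
edge counts are maintained (O(1) pair statistics, incremental updates on
merge); `C+`/`C-` are materialized once at the end, and every report first
audits `decode(encode(...)) == G`.

## Signatures and grouping

Neighborhood vectors live over original node ids: entry `v` of super node
`A` sums the edge weights from members of `A` to `v`. Weighted minhash is
realized by unary expansion: entry `(v, w)` occupies slots
`v·cap + 0 .. v·cap + min(w, cap) - 1`. The cap (default 16) bounds
signature cost; weights beyond it saturate, a deliberate coarsening that
only matters when weights are both large and discriminative. Binary graphs
reduce to one slot per neighbor for any cap.

The permutation is a seeded splitmix64-style finalizer — a bijection on
the 64-bit integers, hence injective on any slot set — applied to
`slot XOR mix(seed)`. The permuted key space is split into `K` equal bins
(via the top 32 bits, exact for `K < 2^32`); each bin keeps its minimum
key; empty bins copy the nearest non-empty bin to the right, wrapping
around. The direction is fixed for determinism. Per-bin collision
probability equals `Jw` (checked by Monte-Carlo against the exact formula:
2000 seeded replicates at `Jw ∈ {0.2, 0.5, 0.8}` fall within three
standard errors).

Candidate groups are the equivalence classes of the full `K`-bin
signature. Because co-grouping probability scales like `Jw^K`, `K` is the
recall/precision dial: `K = 1` (single-bin grouping, classic minhash
bucketing) maximizes candidate recall and is what the bundled desk-scale
studies use; larger `K` (CLI default 5) only groups near-duplicate
neighborhoods and suits very large or highly redundant graphs where group
size, not recall, is the binding constraint. Groups exceeding
`max_group_size` (default 500) are split recursively with one extra bin
and a derived seed; groups of identical vectors are irreducible and kept
whole. Within a group the search is exhaustive: each super node, visited
in seeded random order, takes its maximum-saving partner (ties to the
smallest id) and the merge is accepted when the saving reaches the
iteration threshold.

`θ(t) = 1/(1+t)` decays from 0.5 toward 0: early iterations take only
safe merges (twins clear 0.5 immediately), late ones accept marginal
gains. Signatures are re-seeded per iteration from `(seed, t)` so unlucky
groupings are not repeated. Both choices make runs deterministic given
`(input, config, seed)`.

## Flow rates and personalization

Flow semantics: nodes are layered by hop count from the target set
(multi-source BFS) and

    r(v) = max { r(u) + w(u, v) : u adjacent to v, one layer closer },

with `r(target) = 0`, parent = the argmax (ties to the smallest id), and
`r` undefined off the reachable set. This layered max-sum is the unique
simple semantics reproducing the worked example's four printed rates
(5, 4, then 9 = 4+5 through the intermediate node, 12 = 9+3 beyond it);
it is *not* max-flow (no capacity splitting) and not a diffusion — rates
accumulate along minimum-hop paths only. A corollary worth knowing:
adding an edge can *lower* a rate when it shortens a hop distance,
because the affected node changes layer; monotonicity under edge addition
holds only for layering-preserving additions, and the tests assert
exactly that.

Personalization enters the summarizer in two ways. Targets are pinned —
never merged, each a singleton super node in the output. And both the
neighborhood vectors and the pair-encoding costs are scaled by edge
importance `1 + α·max(ρ(u), ρ(v))`, where `ρ` is `r` normalized by its
maximum (targets at 1, unreachable nodes at 0) — scale-invariant under
global weight rescaling. Pair costs are multiplied by the mean importance
of the pair's present member edges, making corrections near targets more
expensive, hence rarer. `α` (default 1) sets the strength; `α = 0` with an
empty target set reproduces the non-personalized run exactly (same RNG
stream). Losslessness is unaffected: personalization only reshapes which
merges are chosen.

The flow view picks the `l` reachable nodes with the largest rates, keeps
their parent chains plus the targets, groups retained non-target nodes by
the strongest flow using them (overflow beyond `k` clusters folds into the
last), and reports the summed terminal rates as the objective. It is lossy
by design and intended for visualization export, never for reconstruction.

## Synthetic studies

The generators define the test conditions:

- `planted_partition(n, k, p_in, p_out, seed)` — community redundancy; the
  standard compressibility study is 200 nodes, 10 blocks, `p_in = 0.3`,
  `p_out = 0.01`, seed 7 (~700 edges), where the summarizer reaches a
  ratio ≈ 0.77 < 1 while the identity (no-merge) summary sits above 1.
- `twins(n_pairs, shared_degree)` — guaranteed-positive-saving pairs
  (`Jw = 1`, saving 1/2); ≥ 90% of pairs merge within 5 iterations.
- `erdos_renyi(n, p, seed)` — unstructured noise; used for losslessness
  (100 graphs at n = 50, p ∈ {0.05, 0.2}, both variants) and for greedy
  parity (n = 30, 20 seeds: final size within 1.2× of an exhaustive
  best-pair greedy oracle; measured median 1.0).
- the 5-node weighted influence example with target A — the exact
  flow-rate fixture.

These graphs emulate redundancy and community structure but not the
heavy-tailed degree distributions, assortativity, or multi-scale overlap
of real interaction networks; passing tests demonstrate correctness of
the machinery and sane behaviour on idealized structure, not field
performance on any particular biological dataset. Problem sizes (50–200
nodes, ≤ 30 for exhaustive-oracle comparisons) are chosen so every oracle
remains brute-force tractable.

## Numerical and degenerate-input choices

- Survivor of a merge = smaller super id; all outputs sorted; files are
  TSV with deterministic ordering.
- The edge-list writer records a `# nodes:` roster comment so isolated
  nodes and label order survive a round trip; the reader treats any other
  `#` line as a comment. Duplicate and self-loop lines are cleaned and
  counted, not fatal.
- Size formulas use real-valued `log2` (no per-id ceiling).
  `S_edges` counts super edges *plus both correction lists*, since the
  summary is lossless only with corrections stored. Ratios are flagged
  undefined (`null` in reports) for empty or single-node graphs.
- Saving is undefined when both nodes cost 0 (two isolated nodes); such
  pairs are skipped. Isolated super nodes get no signature and form
  singleton groups.
- Decoding validates both correction lists (a `C+` entry already implied,
  or a `C-` entry not implied, raises a corrupt-summary error).

## Known limitations

- Candidate recall depends on `K` as described; with the strict default on
  small sparse graphs the summarizer may find few merges. Use `--sig-len 1`
  at desk scale.
- The flow view's `k`/`l` control only the extracted view, not the
  summarizer itself.
- Correction sets are unweighted; decoding a weighted graph recovers its
  topology, not its weights.
- Single-threaded, in-memory; no streaming or incremental updates.
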