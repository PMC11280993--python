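"""Correction-set encoding: pair statistics, costs, merges, exact decode."""

import itertools

import numpy as np
import pytest

from ipgs.exceptions import CorruptSummaryError, InvalidMergeError, UndefinedSavingError
from ipgs.graph_io import Graph
from ipgs.summary_core import (
    CorrectionSets,
    CostTable,
    EncodeMode,
    SummaryGraph,
    SummaryState,
    SuperNodeMap,
    decode,
    encode_all,
    encode_pair,
    merge_saving,
    node_cost,
    pair_stats,
)
from ipgs.summarizer import SummarizerConfig, summarize
from ipgs.synth_fixtures import erdos_renyi, planted_partition, twins

from conftest import oracle_merge_saving, oracle_node_cost, oracle_total_size


def _partition(s: SuperNodeMap) -> list[set]:
    return [set(m) for _, m in sorted(s.super_to_members.items())]


class TestPairStats:
    def test_singleton_pair_with_edge_is_superedge(self):
        g = Graph(3, frozenset({(1, 2)}))
        pe = pair_stats(1, 2, g, SuperNodeMap.identity(3))
        assert (pe.e_count, pe.f_possible, pe.mode) == (1, 1, EncodeMode.SUPEREDGE)

    def test_half_boundary_is_corrections_only(self):
        g = Graph(5, frozenset({(1, 3), (2, 4)}))
        s = SuperNodeMap({0: 0, 1: 1, 2: 1, 3: 3, 4: 3}, {0: {0}, 1: {1, 2}, 3: {3, 4}})
        pe = pair_stats(1, 3, g, s)
        assert (pe.e_count, pe.f_possible) == (2, 4)
        assert pe.mode is EncodeMode.CORRECTIONS_ONLY  # e == f/2 stays corrections

    def test_self_pair_above_half_is_superedge(self):
        g = Graph(4, frozenset({(1, 2), (1, 3)}))
        s = SuperNodeMap({0: 0, 1: 1, 2: 1, 3: 1}, {0: {0}, 1: {1, 2, 3}})
        pe = pair_stats(1, 1, g, s)
        assert (pe.e_count, pe.f_possible, pe.mode) == (2, 3, EncodeMode.SUPEREDGE)

    def test_unknown_super_id_rejected(self):
        g = Graph(2, frozenset({(0, 1)}))
        with pytest.raises(InvalidMergeError):
            pair_stats(0, 7, g, SuperNodeMap.identity(2))


class TestEncodePair:
    def test_corrections_only_lists_present_edges(self):
        g = Graph(5, frozenset({(1, 3), (2, 4)}))
        s = SuperNodeMap({0: 0, 1: 1, 2: 1, 3: 3, 4: 3}, {0: {0}, 1: {1, 2}, 3: {3, 4}})
        se, cp, cm = encode_pair(pair_stats(1, 3, g, s), g, s)
        assert se is None and cm == [] and sorted(cp) == [(1, 3), (2, 4)]

    def test_superedge_lists_absent_pairs(self):
        g = Graph(5, frozenset({(1, 3), (1, 4), (2, 3)}))
        s = SuperNodeMap({0: 0, 1: 1, 2: 1, 3: 3, 4: 3}, {0: {0}, 1: {1, 2}, 3: {3, 4}})
        se, cp, cm = encode_pair(pair_stats(1, 3, g, s), g, s)
        assert se == (1, 3) and cp == [] and cm == [(2, 4)]

    def test_empty_pair_costs_nothing(self):
        g = Graph(6, frozenset({(0, 5)}))
        s = SuperNodeMap(
            {0: 0, 5: 5, 1: 1, 2: 1, 3: 3, 4: 3},
            {0: {0}, 5: {5}, 1: {1, 2}, 3: {3, 4}},
        )
        se, cp, cm = encode_pair(pair_stats(1, 3, g, s), g, s)
        assert se is None and cp == [] and cm == []


class TestNodeCost:
    def test_singleton_with_three_singleton_neighbors(self, twin_fixture):
        s = SuperNodeMap.identity(5)
        assert node_cost(0, twin_fixture, s) == 3
        assert node_cost(0, twin_fixture, s) == oracle_node_cost(
            twin_fixture, _partition(s), 0
        )

    def test_isolated_node_costs_zero(self):
        g = Graph(3, frozenset({(1, 2)}))
        assert node_cost(0, g, SuperNodeMap.identity(3)) == 0

    def test_merged_pair_fully_connected_to_singleton(self):
        g = Graph(4, frozenset({(1, 3), (2, 3)}))
        s = SuperNodeMap({0: 0, 1: 1, 2: 1, 3: 3}, {0: {0}, 1: {1, 2}, 3: {3}})
        assert node_cost(1, g, s) == 1  # one super edge, no corrections

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_graphs(self, seed):
        g = erdos_renyi(10, 0.3, seed)
        s = SuperNodeMap.identity(10)
        part = _partition(s)
        for a in range(10):
            assert node_cost(a, g, s) == oracle_node_cost(g, part, a)


class TestMergeSaving:
    def test_twins_save_half(self, twin_fixture):
        s = SuperNodeMap.identity(5)
        assert merge_saving(0, 1, twin_fixture, s) == pytest.approx(0.5)

    def test_unrelated_merge_is_negative(self):
        # {1,2} superedge-connected to {3}; singleton 6 adjacent only to {7}
        g = Graph(8, frozenset({(1, 3), (2, 3), (6, 7)}))
        s = SuperNodeMap(
            {0: 0, 1: 1, 2: 1, 3: 3, 4: 4, 5: 5, 6: 6, 7: 7},
            {0: {0}, 1: {1, 2}, 3: {3}, 4: {4}, 5: {5}, 6: {6}, 7: {7}},
        )
        assert merge_saving(1, 6, g, s) == pytest.approx(-0.5)

    def test_self_merge_rejected(self, twin_fixture):
        with pytest.raises(InvalidMergeError):
            merge_saving(1, 1, twin_fixture, SuperNodeMap.identity(5))

    def test_both_isolated_is_undefined(self):
        g = Graph(3, frozenset({(1, 2)}))
        with pytest.raises(UndefinedSavingError):
            merge_saving(0, 1, Graph(3, frozenset()), SuperNodeMap.identity(3))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_all_pairs(self, seed):
        g = erdos_renyi(9, 0.35, 50 + seed)
        st = SummaryState(g)
        part = _partition(st.s)
        ids = sorted(st.s.super_to_members)
        for i, j in itertools.combinations(range(len(ids)), 2):
            ca = st.node_cost(ids[i])
            cb = st.node_cost(ids[j])
            if ca + cb == 0:
                continue
            assert st.merge_saving(ids[i], ids[j]) == pytest.approx(
                oracle_merge_saving(g, part, i, j)
            )


class TestApplyMerge:
    def test_survivor_is_smaller_id(self, twin_fixture):
        st = SummaryState(twin_fixture)
        assert st.apply_merge(1, 0) == 0
        assert st.s.super_to_members[0] == {0, 1}
        st.s.check_partition(5)

    def test_cost_cache_coherent_after_random_merges(self):
        g = erdos_renyi(20, 0.25, 4)
        st = SummaryState(g)
        costs = CostTable(st)
        rng = np.random.default_rng(0)
        for _ in range(10):
            ids = sorted(st.s.super_to_members)
            a, b = rng.choice(ids, size=2, replace=False)
            _ = costs.get(int(a)), costs.get(int(b))
            st.apply_merge(int(a), int(b), costs)
            for x in sorted(st.s.super_to_members):
                assert costs.get(x) == st.node_cost(x)
        st.s.check_partition(20)

    def test_partition_invariant_after_many_merges(self):
        g = planted_partition(60, 6, 0.4, 0.02, 1)
        st = SummaryState(g)
        rng = np.random.default_rng(1)
        for _ in range(50):
            ids = sorted(st.s.super_to_members)
            if len(ids) < 2:
                break
            a, b = rng.choice(ids, size=2, replace=False)
            st.apply_merge(int(a), int(b))
        st.s.check_partition(60)
        assert st.total_size() == oracle_total_size(g, _partition(st.s))


class TestEncodeDecode:
    def test_identity_partition_yields_edge_isomorphic_summary(self, path3):
        sg, corr = encode_all(path3, SuperNodeMap.identity(3))
        assert sg.superedges == {(0, 1), (1, 2)}
        assert corr.c_plus == [] and corr.c_minus == []
        assert decode(sg, corr, 3).edges == path3.edges

    def test_merged_twins_summary_is_smaller_and_exact(self):
        # two merged twin pairs sharing neighbors: summary beats |E|
        g = twins(1, 3)
        st = SummaryState(g)
        st.apply_merge(0, 1)
        sg, corr = encode_all(g, st.s)
        size = len(sg.superedges) + len(corr.c_plus) + len(corr.c_minus)
        assert size < g.n_edges
        assert size == oracle_total_size(g, _partition(st.s))
        assert decode(sg, corr, g.n_nodes).edges == g.edges

    def test_empty_graph_encodes_to_empty_summary(self):
        g = Graph(0, frozenset())
        sg, corr = encode_all(g, SuperNodeMap.identity(0))
        assert not sg.superedges and not corr.c_plus and not corr.c_minus
        assert decode(sg, corr, 0).edges == frozenset()

    def test_corrupt_cminus_detected(self, path3):
        sg, corr = encode_all(path3, SuperNodeMap.identity(3))
        corr.c_minus.append((0, 2))  # not implied by any super edge
        with pytest.raises(CorruptSummaryError):
            decode(sg, corr, 3)

    def test_corrupt_cplus_detected(self, path3):
        sg, corr = encode_all(path3, SuperNodeMap.identity(3))
        corr.c_plus.append((0, 1))  # already implied
        with pytest.raises(CorruptSummaryError):
            decode(sg, corr, 3)

    @pytest.mark.parametrize("seed", range(15))
    def test_half_rule_auditable_from_decoded_graph(self, seed):
        g = erdos_renyi(30, 0.2, seed)
        res = summarize(g, SummarizerConfig(iterations=4, seed=seed, signature_length=1))
        sg, corr = res.summary, res.corrections
        back = decode(sg, corr, g.n_nodes)
        assert back.edges == g.edges
        # re-derive each pair's stats from the decoded graph; audit the rule
        st = SummaryState(back, sg.supernodes)
        for a, b in sg.superedges:
            pe = st.pair_stats(a, b)
            assert 2 * pe.e_count > pe.f_possible
        cplus = set(corr.c_plus)
        for u, v in cplus:
            a = sg.supernodes.node_to_super[u]
            b = sg.supernodes.node_to_super[v]
            pe = st.pair_stats(a, b)
            assert 2 * pe.e_count <= pe.f_possible
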