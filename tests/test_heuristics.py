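"""Topology encoders: exact rule lists and structural properties."""

import numpy as np
import pytest

from genenet import (
    binary_tree_ruleset,
    build_graph,
    ffn_ruleset,
    hierarchical_ruleset,
    homophily_ruleset,
    scale_free_ruleset,
)


def rule_texts(rs):
    return [f"({r.source.text})O({r.destination.text})" for r in rs.rules]


class TestScaleFree:
    def test_b4_variant1_exact_rules(self):
        assert rule_texts(scale_free_ruleset(4, 1)) == [
            "(0000)O(XXXX)",
            "(000X)O(XXX0)",
            "(00XX)O(XX00)",
            "(0XXX)O(X000)",
            "(XXXX)O(0000)",
        ]

    def test_b6_variant2_exact_rules(self):
        assert rule_texts(scale_free_ruleset(6, 2)) == [
            "(000000)O(XXXXXX)",
            "(0000XX)O(XXXXX0)",
            "(00XXXX)O(XXXX00)",
            "(XXXXXX)O(XXX000)",
        ]

    def test_b6_variant3_exact_rules(self):
        assert rule_texts(scale_free_ruleset(6, 3)) == [
            "(000000)O(XXXXXX)",
            "(000XXX)O(XXXXX0)",
            "(XXXXXX)O(XXXX00)",
        ]

    @pytest.mark.parametrize("b, variant", [(5, 2), (7, 3)])
    def test_divisibility_enforced(self, b, variant):
        with pytest.raises(ValueError):
            scale_free_ruleset(b, variant)

    @pytest.mark.parametrize("b", [4, 8, 12])
    def test_variant1_degree_multiplicities(self, b):
        """Finite-size p(k) = 0.5/k: one node at 2^b, 2^(j-1) at 2^(b-j)."""
        g = build_graph(scale_free_ruleset(b, 1)).to_networkx()
        for degree_of in (g.out_degree, g.in_degree):
            counts = {}
            for _, k in degree_of():
                counts[k] = counts.get(k, 0) + 1
            expected = {2**b: 1}
            for j in range(1, b + 1):
                expected[2 ** (b - j)] = expected.get(2 ** (b - j), 0) + 2 ** (j - 1)
            assert counts == expected
        # the multiplicity sequence is a normalized distribution
        total = sum(counts.values())
        assert total == 2**b
        assert sum(v / total for v in counts.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("variant, slope", [(2, -2.0), (3, -3.0)])
    def test_steep_degree_slopes(self, variant, slope):
        """Log-log degree law of variants 2 and 3 near k^-2 and k^-3.

        Widening the source sets faster than the destinations shrink puts
        the steep power law on the source side: measured on the out-degree
        sequence of the generated rule lists (the complementary
        destination-side law is the shallow k^-1/2 / k^-1/3 branch).
        """
        b = 12
        g = build_graph(scale_free_ruleset(b, variant)).to_networkx()
        counts = {}
        for _, k in g.out_degree():
            if k > 0:
                counts[k] = counts.get(k, 0) + 1
        ks = np.array(sorted(counts))
        pk = np.array([counts[k] for k in ks], dtype=float) / 2**b
        fit = np.polyfit(np.log(ks), np.log(pk), 1)[0]
        assert fit == pytest.approx(slope, abs=0.2)


class TestFFN:
    LAYERS = ["00XXX", "010XX", "10XXX", "110XX", "111XX"]

    def test_five_layers_make_four_chained_rules(self):
        rs = ffn_ruleset(self.LAYERS, b=5)
        assert len(rs.rules) == 4
        assert rule_texts(rs)[:2] == ["(00XXX)O(010XX)", "(010XX)O(10XXX)"]
        for prev, nxt in zip(rs.rules, rs.rules[1:]):
            assert prev.destination == nxt.source

    def test_two_singleton_layers(self):
        rs = ffn_ruleset(["0", "1"], b=1)
        g = build_graph(rs)
        assert g.unique_link_count == 1

    def test_overlapping_layers_rejected_naming_barcode(self):
        with pytest.raises(ValueError, match="01000"):
            ffn_ruleset(["0XXXX", "010XX"], b=5)

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            ffn_ruleset(["0XX"], b=3)


class TestBinaryTree:
    def test_first_rules_match_buffer_trace(self):
        rs = binary_tree_ruleset(4)
        texts = rule_texts(rs)
        assert texts[0] == "(0001)O(001X)"
        # second level: the buffer algorithm forces sources 0010 then 0011
        assert texts[1] == "(0010)O(010X)"
        assert texts[2] == "(0011)O(011X)"

    @pytest.mark.parametrize("b", [2, 4, 6])
    def test_rooted_complete_binary_tree(self, b):
        rs = binary_tree_ruleset(b)
        assert len(rs.rules) == 2 ** (b - 1) - 1
        g = build_graph(rs).to_networkx()
        import networkx as nx

        assert g.number_of_nodes() == 2**b - 1
        assert nx.is_directed_acyclic_graph(g)
        root = 1  # barcode 0^(b-1) 1
        assert g.in_degree(root) == 0
        leaves = [u for u in g if g.out_degree(u) == 0]
        internal = [u for u in g if g.out_degree(u) > 0]
        assert len(leaves) == 2 ** (b - 1)
        assert all(g.out_degree(u) == 2 for u in internal)
        assert all(g.in_degree(u) == 1 for u in g if u != root)


class TestHierarchical:
    def test_depth1_is_five_clique_core(self):
        h = hierarchical_ruleset(1)
        assert len(h.clique_groups) == 1
        assert h.hierarchy_levels == {}
        und = build_graph(h.ruleset).to_networkx(directed=False, self_loops=False)
        assert und.number_of_nodes() == 5
        assert und.number_of_edges() == 10  # complete graph K5

    def test_depth2_counts_and_hub(self):
        h = hierarchical_ruleset(2)
        assert len(h.clique_groups) == 5
        assert len(h.hierarchy_levels[1]) == 1
        assert len(h.ruleset.universe) == 25
        und = build_graph(h.ruleset).to_networkx(directed=False, self_loops=False)
        degrees = dict(und.degree())
        assert max(degrees, key=degrees.get) == 0  # barcode 000000

    def test_depth3_level_counts(self):
        h = hierarchical_ruleset(3)
        assert len(h.clique_groups) == 25
        assert len(h.hierarchy_levels[1]) == 5
        assert len(h.hierarchy_levels[2]) == 1
        assert len(h.ruleset.universe) == 125

    def test_depth2_matches_direct_construction(self):
        """25-node module: 5 K5 cliques + 16 doubly-peripheral->hub links."""
        import networkx as nx

        h = hierarchical_ruleset(2)
        got = build_graph(h.ruleset).to_networkx(directed=False, self_loops=False)

        ref = nx.Graph()
        groups = ["000", "100", "101", "110", "111"]
        labels = [a + b for a in groups for b in groups]
        for prefix in groups:  # one 5-clique per outer position
            clique = [prefix + g for g in groups]
            ref.add_edges_from(
                (u, v) for i, u in enumerate(clique) for v in clique[i + 1 :]
            )
        for outer in groups[1:]:  # doubly peripheral back to global center
            for inner in groups[1:]:
                ref.add_edge(outer + inner, "000000")
        mapping = {lbl: int(lbl, 2) for lbl in labels}
        ref = nx.relabel_nodes(ref, mapping)
        assert set(ref.nodes) == set(got.nodes)
        assert {frozenset(e) for e in ref.edges} == {
            frozenset(e) for e in got.edges
        }

    def test_modes_are_identical(self):
        a = hierarchical_ruleset(2, mode="strict")
        b = hierarchical_ruleset(2, mode="collapsed")
        assert rule_texts(a.ruleset) == rule_texts(b.ruleset)

    def test_bad_depth(self):
        with pytest.raises(ValueError):
            hierarchical_ruleset(0)


class TestHomophily:
    def test_rule_count(self):
        from math import comb

        for b, o in [(3, 2), (5, 3)]:
            assert len(homophily_ruleset(b, o).rules) == comb(b, o) * 2**o

    def test_o_zero_is_complete_with_loops(self):
        g = build_graph(homophily_ruleset(3, 0))
        assert g.unique_link_count == 64

    def test_o_equals_b_is_self_loops_only(self):
        g = build_graph(homophily_ruleset(3, 3))
        assert g.unique_link_count == 8
        assert np.all(g.src == g.dst)

    @pytest.mark.parametrize("b", range(2, 9))
    def test_hamming_threshold_oracle(self, b):
        """edge(u,v) iff the barcodes agree on >= o positions, all o."""
        codes = np.arange(2**b)
        xor = codes[:, None] ^ codes[None, :]
        hamming = np.array(
            [[int(v).bit_count() for v in row] for row in xor]
        )
        for o in range(b + 1):
            g = build_graph(homophily_ruleset(b, o))
            adj = np.zeros((2**b, 2**b), dtype=bool)
            adj[g.src, g.dst] = True
            assert np.array_equal(adj, hamming <= b - o)

    def test_b3_o2_neighbors_are_hamming1_partners(self):
        und = build_graph(homophily_ruleset(3, 2)).to_networkx(
            directed=False, self_loops=False
        )
        for u in und:
            assert sorted(und.neighbors(u)) == sorted(u ^ (1 << i) for i in range(3))

    def test_o_out_of_range(self):
        with pytest.raises(ValueError):
            homophily_ruleset(3, 4)
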