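import networkx as nx
import numpy as np
import pytest

from brsgkit.network import (DEFAULT_TIERS, TierSpec, edges_per_node,
                             enrichment_report, expected_edges_density,
                             permutation_enrichment, read_string_links,
                             tier_subgraph, write_string_links)
from brsgkit.simulate import SyntheticPpiSpec, generate_ppi


def _write(tmp_path, text):
    p = tmp_path / "links.tsv"
    p.write_text(text)
    return p


class TestReadStringLinks:
    def test_bidirectional_duplicate_keeps_max(self, tmp_path):
        p = _write(tmp_path, "protein1\tprotein2\tcombined_score\n"
                             "a\tb\t400\nb\ta\t700\n")
        g = read_string_links(p)
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["score"] == pytest.approx(0.7)

    def test_self_loop_dropped(self, tmp_path):
        p = _write(tmp_path, "protein1\tprotein2\tcombined_score\n"
                             "a\ta\t900\na\tb\t500\n")
        g = read_string_links(p)
        assert list(g.edges) == [("a", "b")]

    def test_explicit_scale_violation(self, tmp_path):
        p = _write(tmp_path, "protein1\tprotein2\tcombined_score\n"
                             "a\tb\t1500\n")
        with pytest.raises(ValueError, match="outside"):
            read_string_links(p, score_scale="0-1000")
        p = _write(tmp_path, "protein1\tprotein2\tcombined_score\na\tb\t0.5\n")
        g = read_string_links(p, score_scale="0-1")
        assert g["a"]["b"]["score"] == 0.5

    def test_round_trip(self, tmp_path):
        genes = [f"g{i}" for i in range(30)]
        graph, _ = generate_ppi(SyntheticPpiSpec(background_prob=0.2, seed=4),
                                genes)
        path = tmp_path / "out.tsv"
        write_string_links(graph, path)
        back = read_string_links(path)
        assert {frozenset(e) for e in back.edges} == \
            {frozenset(e) for e in graph.edges}
        for a, b in graph.edges:
            assert back[a][b]["score"] == pytest.approx(graph[a][b]["score"])


class TestTierSubgraph:
    def test_cutoff_above_all_scores(self):
        g = nx.Graph()
        g.add_edge("a", "b", score=0.3)
        sub = tier_subgraph(g, ["a", "b"], cutoff=0.9)
        assert sub.number_of_edges() == 0 and sub.number_of_nodes() == 2

    def test_complete_graph_high_tier(self):
        g = nx.Graph()
        nodes = [f"n{i}" for i in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                g.add_edge(nodes[i], nodes[j], score=0.95)
        sub = tier_subgraph(g, nodes, cutoff=DEFAULT_TIERS.cutoff("high"))
        assert sub.number_of_edges() == 45

    def test_matches_double_loop_filter(self, rng):
        genes = [f"g{i}" for i in range(40)]
        graph, _ = generate_ppi(SyntheticPpiSpec(background_prob=0.25, seed=9),
                                genes)
        subset = list(rng.choice(genes, size=15, replace=False))
        for _, cutoff in DEFAULT_TIERS:
            expected = 0
            for i in range(len(subset)):
                for j in range(i + 1, len(subset)):
                    a, b = subset[i], subset[j]
                    if graph.has_edge(a, b) and graph[a][b]["score"] > cutoff:
                        expected += 1
            assert tier_subgraph(graph, subset, cutoff).number_of_edges() \
                == expected

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            tier_subgraph(nx.Graph(), [], 0.4)


def test_edges_per_node_rounding_and_edge_cases():
    assert edges_per_node(144, 52) == 2.8
    assert edges_per_node(82, 34) == 2.4
    assert edges_per_node(0, 5) == 0.0
    assert edges_per_node(3, 0) is None


class TestExpectedEdges:
    def test_complete_graph(self):
        g = nx.complete_graph(8)
        assert expected_edges_density(g, 5) == pytest.approx(10.0)

    def test_small_set_is_zero(self):
        assert expected_edges_density(nx.complete_graph(4), 1) == 0.0

    def test_matches_permutation_mean_on_er_graph(self):
        g = nx.gnp_random_graph(80, 0.05, seed=12)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(80)})
        nx.set_edge_attributes(g, 0.5, "score")
        analytic = expected_edges_density(g, 30, cutoff=0.4)
        res = permutation_enrichment(g, list(g.nodes)[:30], cutoff=0.4,
                                     n_permutations=2000, seed=0)
        assert res.expected == pytest.approx(analytic, rel=0.05)


class TestPermutationEnrichment:
    def test_whole_graph_set_gives_p_one(self):
        g = nx.gnp_random_graph(30, 0.2, seed=1)
        nx.set_edge_attributes(g, 0.5, "score")
        res = permutation_enrichment(g, list(g.nodes), cutoff=0.15,
                                     n_permutations=99, seed=0)
        assert res.p_value == 1.0

    def test_planted_module_is_significant(self):
        genes = [f"g{i}" for i in range(200)]
        module = genes[:30]
        graph, _ = generate_ppi(
            SyntheticPpiSpec(background_prob=0.02, module_prob=0.3, seed=2),
            genes, {"mod": module},
        )
        res = permutation_enrichment(graph, module, cutoff=0.15,
                                     n_permutations=999, seed=0)
        assert res.p_value <= 0.01
        assert res.observed > res.expected

    def test_seeded_determinism_and_p_floor(self):
        g = nx.gnp_random_graph(50, 0.1, seed=3)
        nx.set_edge_attributes(g, 0.5, "score")
        nodes = [str(n) for n in range(20)]
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
        r1 = permutation_enrichment(g, nodes, 0.4, 199, seed=7)
        r2 = permutation_enrichment(g, nodes, 0.4, 199, seed=7)
        assert r1.p_value == r2.p_value and r1.expected == r2.expected
        assert r1.p_value >= 1 / 200

    def test_degree_binned_null_runs(self):
        g = nx.barabasi_albert_graph(100, 2, seed=5)
        g = nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes})
        nx.set_edge_attributes(g, 0.5, "score")
        hubs = sorted(g.degree, key=lambda kv: -kv[1])[:15]
        res = permutation_enrichment(g, [n for n, _ in hubs], 0.4, 199,
                                     seed=1, degree_binned=True)
        assert res.null_method == "degree-binned node permutation"

    def test_validation_errors(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.5, "score")
        with pytest.raises(ValueError, match="99"):
            permutation_enrichment(g, [0, 1], 0.4, n_permutations=10)
        with pytest.raises(ValueError, match="exceeds"):
            permutation_enrichment(g, list(range(9)), 0.4, 99)


class TestEnrichmentReport:
    def test_shape_and_absent_flag(self):
        genes = [f"g{i}" for i in range(60)]
        graph, _ = generate_ppi(SyntheticPpiSpec(background_prob=0.1, seed=6),
                                genes)
        sets = {"A": genes[:10], "B": genes[10:25], "ghost": ["zz1", "zz2"]}
        rep = enrichment_report(graph, sets, n_permutations=99, seed=0)
        assert len(rep) == 3 * len(DEFAULT_TIERS.cutoffs)
        assert (rep.loc[rep["region"] == "ghost", "status"] == "absent").all()
        # observed edge counts never increase with the cutoff
        for name in ("A", "B"):
            obs = rep.loc[rep["region"] == name].sort_values("cutoff")["observed"]
            assert (obs.diff().dropna() <= 0).all()

    def test_tierspec_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            TierSpec(cutoffs=(("a", 0.5), ("b", 0.4)))
        with pytest.raises(ValueError, match="in \\(0, 1\\)"):
            TierSpec(cutoffs=(("a", 0.0),))
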