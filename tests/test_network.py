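import numpy as np
import pandas as pd
import pytest

from diffcorrnet.datasets import (
    example_networks,
    function_example_edges,
    pain_example_edges,
)
from diffcorrnet.diffcorr import EDGE_COLUMNS, differential_statistic, edge_sign, fisher_z
from diffcorrnet.network import (
    build_network,
    export_edgelist,
    export_graphml,
    hub_nodes,
    metabolite_class,
    overlap,
    read_graphml,
)


def _toy_edges(rows):
    """rows: (i, j, p_perm, r_case, r_control) tuples -> edge table."""
    out = []
    for i, j, p, rc, rr in rows:
        rd = differential_statistic(rc, rr, 67, 378)
        out.append({
            "metabolite_i": i, "metabolite_j": j, "r_case": rc, "r_control": rr,
            "z_case": fisher_z(rc), "z_control": fisher_z(rr),
            "n_case": 67, "n_control": 378, "r_diff": rd, "p_normal": np.nan,
            "p_perm": p, "sign": edge_sign(rd),
        })
    return pd.DataFrame(out, columns=EDGE_COLUMNS)


class TestBuildNetwork:
    def test_threshold_filter_is_strict(self):
        edges = _toy_edges([
            ("A", "B", 0.005, 0.6, 0.1),
            ("C", "D", 0.02, 0.6, 0.1),
            ("E", "F", 0.01, 0.6, 0.1),  # exactly alpha: dropped
        ])
        net = build_network(edges, alpha=0.01)
        assert net.n_edges == 1 and net.n_nodes == 2
        assert set(net.graph.nodes) == {"A", "B"}

    def test_empty_network_is_not_an_error(self):
        edges = _toy_edges([("A", "B", 0.5, 0.6, 0.1)])
        net = build_network(edges, alpha=0.01)
        assert net.n_nodes == 0 and net.component_sizes == []

    def test_missing_pvalues_raise(self):
        edges = _toy_edges([("A", "B", 0.005, 0.6, 0.1)])
        edges.loc[0, "p_perm"] = np.nan
        with pytest.raises(ValueError, match="permutation p-values"):
            build_network(edges, alpha=0.01)

    def test_edge_colors_follow_sign(self):
        edges = _toy_edges([
            ("A", "B", 0.005, 0.6, 0.1),
            ("C", "D", 0.005, 0.1, 0.6),
        ])
        net = build_network(edges, alpha=0.01)
        assert net.graph["A"]["B"]["color"] == "red"
        assert net.graph["C"]["D"]["color"] == "blue"

    def test_alpha_nesting_monotone(self):
        rng = np.random.default_rng(0)
        rows = [(f"A{k}", f"B{k}", float(p), 0.6, 0.1)
                for k, p in enumerate(rng.random(40))]
        edges = _toy_edges(rows)
        strict = build_network(edges, alpha=0.01)
        loose = build_network(edges, alpha=0.05)
        assert set(strict.graph.nodes) <= set(loose.graph.nodes)
        assert set(strict.graph.edges) <= set(loose.graph.edges)


class TestComponents:
    def test_agrees_with_union_find_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n_nodes = int(rng.integers(5, 50))
            names = [f"N{k}" for k in range(n_nodes)]
            pairs = [
                (names[a], names[b], 0.001, 0.6, 0.1)
                for a, b in rng.integers(0, n_nodes, size=(n_nodes, 2))
                if a != b
            ]
            if not pairs:
                continue
            net = build_network(_toy_edges(pairs), alpha=0.01)

            parent = {u: u for e in pairs for u in e[:2]}

            def find(u):
                while parent[u] != u:
                    parent[u] = parent[parent[u]]
                    u = parent[u]
                return u

            for u, v, *_ in pairs:
                parent[find(u)] = find(v)
            roots = {}
            for u in parent:
                roots.setdefault(find(u), set()).add(u)
            expected = sorted(map(frozenset, roots.values()), key=len, reverse=True)
            got = sorted(map(frozenset, net.components), key=len, reverse=True)
            assert sorted(got, key=sorted) == sorted(expected, key=sorted)

    def test_degree_sum_is_twice_edge_count(self):
        net, _ = example_networks()
        assert sum(net.degrees.values()) == 2 * net.n_edges


class TestHubNodes:
    def test_star_graph_hub_degree(self):
        leaves = [(f"L{k}", "HUB", 0.001, 0.6, 0.1) for k in range(6)]
        net = build_network(_toy_edges(leaves), alpha=0.01)
        ranked = hub_nodes(net)
        assert ranked[0] == ("HUB", 6)

    def test_ties_broken_lexicographically(self):
        net = build_network(
            _toy_edges([("A", "B", 0.001, 0.6, 0.1), ("C", "D", 0.001, 0.6, 0.1)]),
            alpha=0.01,
        )
        assert [n for n, _ in hub_nodes(net)] == ["A", "B", "C", "D"]


class TestExampleTopologies:
    def test_pain_network_structure(self):
        net, _ = example_networks(alpha=0.01)
        assert net.n_nodes == 12
        assert net.component_sizes == [8, 2, 2]
        assert len(net.central_component) == 8
        hub, degree = hub_nodes(net)[0]
        assert hub == "Proline" and degree == 3

    def test_function_network_structure(self):
        _, net = example_networks(alpha=0.01)
        assert net.n_nodes == 23
        assert net.component_sizes == [14, 3, 2, 2, 2]
        hub, degree = hub_nodes(net)[0]
        assert hub == "PC aa C36:8" and degree == 5

    def test_five_metabolite_overlap(self):
        pain, function = example_networks(alpha=0.01)
        report = overlap(pain, function)
        assert report.shared_nodes == {
            "Glutamine", "Isoleucine", "PC aa C38:0", "PC aa C38:6", "PC aa C40:6",
        }
        assert ("Glutamine", "PC aa C38:6", "negative") in report.shared_edges

    def test_overlap_identities(self):
        pain, function = example_networks(alpha=0.01)
        same = overlap(pain, pain)
        assert same.shared_nodes == set(pain.graph.nodes)
        assert len(same.shared_edges) == pain.n_edges
        none = overlap(
            build_network(pain_example_edges(), 0.01),
            build_network(_toy_edges([("X", "Y", 0.001, 0.6, 0.1)]), 0.01),
        )
        assert none.shared_nodes == set() and none.shared_edges == []

    def test_filler_edges_excluded_at_both_alphas(self):
        for table in (pain_example_edges(), function_example_edges()):
            for alpha in (0.01, 0.05):
                net = build_network(table, alpha)
                assert "Alanine" not in net.graph.nodes


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        net, _ = example_networks()
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        back = read_graphml(path, alpha=net.alpha)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in net.graph.edges
        }
        for u, v, data in net.graph.edges(data=True):
            assert back.graph[u][v]["sign"] == data["sign"]
            assert back.graph[u][v]["r_diff"] == pytest.approx(data["r_diff"])

    def test_empty_network_exports(self, tmp_path):
        net = build_network(_toy_edges([("A", "B", 0.9, 0.6, 0.1)]), alpha=0.01)
        path = tmp_path / "empty.graphml"
        export_graphml(net, path)
        assert read_graphml(path, alpha=0.01).n_edges == 0

    def test_edgelist_export(self, tmp_path):
        net, _ = example_networks()
        path = tmp_path / "edges.tsv"
        export_edgelist(net, path)
        frame = pd.read_csv(path, sep="\t")
        assert len(frame) == net.n_edges


class TestMetaboliteClass:
    @pytest.mark.parametrize("name,expected", [
        ("PC aa C38:6", "glycerophospholipid"),
        ("PC ae C40:6", "glycerophospholipid"),
        ("lysoPC a C18:2", "lysoPC"),
        ("SM C24:1", "sphingolipid"),
        ("C2", "acylcarnitine"),
        ("C14:2", "acylcarnitine"),
        ("C0", "acylcarnitine"),
        ("Proline", "amino acid"),
        ("Taurine", "biogenic amine"),
        ("H1", "monosaccharide"),
        ("mystery-compound", "other"),
    ])
    def test_biocrates_prefixes(self, name, expected):
        assert metabolite_class(name) == expected
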