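import networkx as nx
import numpy as np
import pytest

from ignet.metrics import (CentralityReport, betweenness, centrality_report,
                           classify_phenotype, compare_profiles,
                           degree_distribution, group_means)
from ignet.network import (NetworkEdge, NetworkVertex, RepertoireNetwork,
                           build_network, build_network_from_reads,
                           collapse_reads)
from ignet.simulate import (ExpansionConfig, SimulationConfig,
                            simulate_repertoire)

from oracles import betweenness_enumeration


def net_from_graph(g: nx.Graph, multiplicities=None) -> RepertoireNetwork:
    """Wrap an arbitrary graph as a RepertoireNetwork (synthetic sequences:
    topology tests only care about the edge set)."""
    mult = multiplicities or {}
    vertices = [NetworkVertex(n, f"SEQ{n}", mult.get(n, 1))
                for n in sorted(g.nodes)]
    edges = [NetworkEdge(min(u, v), max(u, v), "substitution")
             for u, v in g.edges]
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(f"SEQ{i}" for i in c))
    by_id = {v.vertex_id: v for v in vertices}
    for cid, comp in enumerate(comps):
        for vid in comp:
            by_id[vid].component_id = cid
    return RepertoireNetwork(vertices, edges, comps)


class TestDegree:
    def test_triangle_all_two(self):
        net = build_network(collapse_reads(["AAA", "AAC", "AAG"]))
        deg, summary = degree_distribution(net)
        assert set(deg.index) == {0, 1, 2}
        assert all(d == 2 for d in deg.values)
        assert summary == {"max": 2, "mean": 2.0}

    def test_star(self):
        net = net_from_graph(nx.star_graph(4))
        deg, summary = degree_distribution(net)
        assert deg[0] == 4
        assert all(deg[i] == 1 for i in range(1, 5))

    def test_matches_adjacency_row_sums(self):
        g = nx.gnp_random_graph(30, 0.15, seed=2)
        net = net_from_graph(g)
        deg, _ = degree_distribution(net)
        a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        assert (deg.values == a.sum(axis=1)).all()


class TestBetweenness:
    def test_path_middle_is_one(self):
        net = net_from_graph(nx.path_graph(3))
        b = betweenness(net)
        assert b[1] == pytest.approx(1.0)
        assert b[0] == b[2] == 0.0

    def test_triangle_all_zero(self):
        net = net_from_graph(nx.cycle_graph(3))
        assert all(v == 0.0 for v in betweenness(net).values())

    def test_values_in_unit_interval(self):
        g = nx.gnp_random_graph(25, 0.1, seed=5)
        net = net_from_graph(g)
        for v in betweenness(net).values():
            assert 0.0 <= v <= 1.0

    @pytest.mark.parametrize("g", [
        nx.path_graph(6),
        nx.star_graph(5),
        nx.cycle_graph(7),
        nx.barbell_graph(4, 2),
        nx.lollipop_graph(5, 3),
        nx.gnp_random_graph(20, 0.12, seed=1),
        nx.gnp_random_graph(30, 0.08, seed=2),   # disconnected
        nx.gnp_random_graph(30, 0.2, seed=3),
        nx.empty_graph(5),
    ], ids=["path6", "star5", "cycle7", "barbell", "lollipop", "gnp20",
            "gnp30_sparse", "gnp30", "empty5"])
    def test_matches_geodesic_enumeration_oracle(self, g):
        """Brandes accumulation with per-component reachable-pair
        normalization equals explicit enumeration of every geodesic."""
        net = net_from_graph(g)
        got = betweenness(net)
        expected = betweenness_enumeration(g)
        for v in g.nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-9)


class TestPhenotype:
    def _report(self, largest_clone_percent):
        return CentralityReport(
            n_reads=100, n_vertices=50, n_edges=10, n_components=40,
            largest_component_fraction=0.1, n_isolated_vertices=30,
            max_degree=3, mean_degree=0.4, max_betweenness=0.1,
            mean_betweenness=0.01,
            largest_clone_percent=largest_clone_percent)

    def _tables(self, max_v_pct, max_j_pct):
        import pandas as pd
        return {
            "v": pd.DataFrame({"segment": ["V1"], "percent": [max_v_pct]}),
            "j": pd.DataFrame({"segment": ["J1"], "percent": [max_j_pct]}),
        }

    def test_boundary_clone_exactly_10_is_poorly(self):
        call = classify_phenotype(self._report(10.0), self._tables(5, 20))
        assert call.label == "poorly_connected"
        assert call.criteria_fired == ()

    def test_clone_criterion_fires(self):
        call = classify_phenotype(self._report(50.0), self._tables(5, 20))
        assert call.label == "highly_connected"
        assert any("clone" in c for c in call.criteria_fired)

    def test_germline_criterion_fires_at_40(self):
        call = classify_phenotype(self._report(5.0), self._tables(40.0, 20))
        assert call.label == "highly_connected"
        assert any("V_usage" in c for c in call.criteria_fired)

    def test_simulated_naive_vs_expanded(self, default_ref, default_assigner):
        from ignet.assignment import filter_repertoire, vj_usage_table
        labels = {}
        for name, exp in (("naive", None), ("expanded", ExpansionConfig())):
            cfg = SimulationConfig(n_sequences=150, seed=31, expansion=exp)
            rep = simulate_repertoire(default_ref, cfg)
            kept, _, _ = filter_repertoire(
                default_assigner.assign_repertoire(rep.reads))
            net = build_network_from_reads(rep.reads)
            call = classify_phenotype(centrality_report(net),
                                      vj_usage_table(kept, default_ref))
            labels[name] = call.label
        assert labels == {"naive": "poorly_connected",
                          "expanded": "highly_connected"}


class TestCompareProfiles:
    def _reports(self, default_ref):
        reports = []
        for seed, exp in ((1, None), (2, None), (1, ExpansionConfig()),
                          (2, ExpansionConfig())):
            cfg = SimulationConfig(n_sequences=100, seed=seed, expansion=exp)
            rep = simulate_repertoire(default_ref, cfg)
            reports.append(centrality_report(
                build_network_from_reads(rep.reads)))
        return reports

    def test_expanded_group_mean_exceeds_random(self, default_ref):
        reports = self._reports(default_ref)
        df = compare_profiles(reports, ["r1", "r2", "e1", "e2"],
                              groups=["random", "random", "expanded",
                                      "expanded"])
        means = group_means(df)
        assert means.loc["expanded", "largest_clone_percent"] > \
            means.loc["random", "largest_clone_percent"]
        assert means.loc["expanded", "max_degree"] > \
            means.loc["random", "max_degree"]

    def test_single_report_row(self, default_ref):
        rep = simulate_repertoire(default_ref,
                                  SimulationConfig(n_sequences=50, seed=9))
        report = centrality_report(build_network_from_reads(rep.reads))
        df = compare_profiles([report], ["only"])
        assert len(df) == 1
        assert "group" not in df.columns

    def test_identical_repertoires_zero_difference(self, default_ref):
        rep = simulate_repertoire(default_ref,
                                  SimulationConfig(n_sequences=50, seed=9))
        report = centrality_report(build_network_from_reads(rep.reads))
        df = compare_profiles([report, report], ["a", "b"],
                              groups=["g1", "g2"])
        means = group_means(df)
        assert (means.loc["g1"] == means.loc["g2"]).all()

    def test_label_mismatch_rejected(self, default_ref):
        with pytest.raises(ValueError):
            compare_profiles([], ["x"])


class TestCentralityReport:
    def test_counts_consistent(self, default_ref):
        rep = simulate_repertoire(default_ref,
                                  SimulationConfig(n_sequences=120, seed=13))
        net = build_network_from_reads(rep.reads)
        report = centrality_report(net)
        assert report.n_reads == 120
        assert report.n_vertices == len(net.vertices)
        assert report.n_components == len(net.components)
        assert 0 < report.largest_clone_percent <= 100
        assert report.n_isolated_vertices <= report.n_vertices
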