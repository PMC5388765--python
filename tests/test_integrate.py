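"""Multilayer assembly, subnetworks, module detection, centrality, export."""

import numpy as np
import pandas as pd
import pytest

from phenolnet.colocation import ColocationPair
from phenolnet.gcn import CoexpressionEdge
from phenolnet.integrate import (
    MultilayerNetwork,
    assemble,
    centrality_report,
    detect_modules,
    export,
    extract_subnetwork,
    import_graphml,
)

from .conftest import adjusted_rand_index


def coexp(a, b, r):
    return CoexpressionEdge(a, b, r, "positive" if r > 0 else "negative")


def _demo_network() -> MultilayerNetwork:
    gcn = [coexp(f"g{i}", f"g{i+1}", 0.9) for i in range(10)]  # chain of 10 edges
    lnc = [
        ColocationPair("lncA", "g0", 5000, "intergenic_neighbor", 0.92),
        ColocationPair("lncA", "g1", 9000, "intergenic_neighbor", 0.91),
    ]
    mir = pd.DataFrame(
        [("mir1", "g2", 1.5), ("mir1", "g3", 2.0), ("mir2", "g4", 0.5)],
        columns=["mirna", "gene", "expectation"],
    )
    return assemble(gcn, ["g5"], lnc, mir)


class TestAssemble:
    def test_edge_conservation_across_layers(self):
        net = _demo_network()
        assert len(net.edges) == 10 + 2 + 3

    def test_tf_edge_retyped_and_directed(self):
        net = assemble([coexp("TF1", "gA", 0.9)], tf_list=["TF1"])
        (e,) = net.edges
        assert e.edge_type == "tf_coexpression"
        assert (e.a, e.b) == ("TF1", "gA")
        assert net.nodes["TF1"]["node_type"] == "TF"

    def test_negative_tf_edge_stays_coexpression(self):
        net = assemble([coexp("TF1", "gA", -0.9)], tf_list=["TF1"])
        assert net.edges[0].edge_type == "coexpression_neg"

    def test_tf_tf_edge_stays_undirected(self):
        net = assemble([coexp("TF1", "TF2", 0.9)], tf_list=["TF1", "TF2"])
        assert net.edges[0].edge_type == "coexpression_pos"

    def test_empty_layers_valid_empty_network(self):
        net = assemble([], [], [], pd.DataFrame(columns=["mirna", "gene", "expectation"]))
        assert net.nodes == {} and net.edges == []

    def test_unknown_endpoint_rejected(self):
        net = MultilayerNetwork()
        net.add_node("a", "enzyme_gene")
        with pytest.raises(ValueError, match="ghost"):
            net.add_edge("a", "ghost", "coexpression_pos", 0.9)

    def test_id_collision_gets_prefix(self, caplog):
        gcn = [coexp("X", "gA", 0.9)]
        mir = pd.DataFrame([("X", "gA", 1.0)], columns=["mirna", "gene", "expectation"])
        net = assemble(gcn, [], [], mir)
        assert "miRNA:X".lower() in {n.lower() for n in net.nodes}
        assert "collision" in caplog.text


class TestExtractSubnetwork:
    def test_regulators_pulled_in(self):
        net = assemble([coexp("T", "A", 0.9), coexp("A", "B", 0.85)], tf_list=["T"])
        sub = extract_subnetwork(net, ["A", "B"], include_regulators=True)
        assert set(sub.nodes) == {"A", "B", "T"}

    def test_without_regulators_induced_only(self):
        net = assemble([coexp("T", "A", 0.9), coexp("A", "B", 0.85)], tf_list=["T"])
        sub = extract_subnetwork(net, ["A", "B"], include_regulators=False)
        assert set(sub.nodes) == {"A", "B"}

    def test_fixture_lncrna_attached_to_all_nine_cluster_genes(self, fixture_suite):
        res = fixture_suite / "results"
        cent = pd.read_csv(res / "subnetwork_centrality.tsv", sep="\t", index_col=0)
        assert cent.loc["lnc_STS_cluster", "lncrna_colocation"] == 9


class TestDetectModules:
    def test_negative_edges_never_join_modules(self):
        edges = [coexp("a1", "a2", 0.9), coexp("a1", "a3", 0.9), coexp("a2", "a3", 0.9),
                 coexp("b1", "b2", 0.9), coexp("b1", "b3", 0.9), coexp("b2", "b3", 0.9),
                 coexp("a1", "b1", -0.9), coexp("a2", "b2", -0.95)]
        net = assemble(edges)
        part = detect_modules(net)
        labels = part.labels
        assert labels["a1"] == labels["a2"] == labels["a3"]
        assert labels["b1"] == labels["b2"] == labels["b3"]
        assert labels["a1"] != labels["b1"]

    def test_single_positive_clique_one_module(self):
        edges = [coexp("a", "b", 0.9), coexp("b", "c", 0.9), coexp("a", "c", 0.9)]
        part = detect_modules(assemble(edges))
        assert len(set(part.labels.values())) == 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            detect_modules(MultilayerNetwork(), method="kmeans")

    def test_greedy_modularity_labels_every_node(self):
        net = _demo_network()
        part = detect_modules(net, method="greedy_modularity")
        assert set(part.labels) == set(net.nodes)

    def test_planted_modules_recovered_with_high_ari(self):
        from phenolnet.gcn import NetworkConfig, build_network, compute_pcc_matrix
        from phenolnet.simulate import PlantedModule, SimulationDesign, simulate_expression

        aris = []
        for seed in range(5):
            mods = [
                PlantedModule("m1", [f"a{i}" for i in range(8)], "ripening_up"),
                PlantedModule("m2", [f"b{i}" for i in range(8)], "early_up"),
                PlantedModule("m3", [f"c{i}" for i in range(8)], "mid_peak"),
            ]
            design = SimulationDesign(modules=mods, seed=seed)
            m = simulate_expression(design)
            corr = compute_pcc_matrix(m)
            net = assemble(build_network(corr, NetworkConfig(0.8)))
            part = detect_modules(net)
            planted = {g: mod.module_id for mod in mods for g in mod.gene_ids}
            common = sorted(set(planted) & set(part.labels))
            aris.append(adjusted_rand_index(
                [planted[g] for g in common], [part.labels[g] for g in common]
            ))
        assert np.mean(aris) >= 0.9


class TestCentrality:
    def test_isolated_node_degree_zero(self):
        net = MultilayerNetwork()
        net.add_node("solo", "enzyme_gene")
        report = centrality_report(net)
        assert report.loc["solo", "total"] == 0

    def test_lncrna_colocation_degree(self):
        net = _demo_network()
        report = centrality_report(net)
        assert report.loc["lncA", "lncrna_colocation"] == 2

    def test_handshake_identity(self):
        net = _demo_network()
        report = centrality_report(net)
        assert report["total"].sum() == 2 * len(net.edges)

    def test_sorted_hubs_first_ties_lexicographic(self):
        net = _demo_network()
        report = centrality_report(net)
        totals = report["total"].tolist()
        assert totals == sorted(totals, reverse=True)


class TestExport:
    def test_graphml_roundtrip(self, tmp_path):
        net = _demo_network()
        p = tmp_path / "net.graphml"
        export(net, "graphml", p)
        back = import_graphml(p)
        assert set(back.nodes) == set(net.nodes)
        assert {e.key() for e in back.edges} == {e.key() for e in net.edges}
        assert back.nodes["lncA"]["node_type"] == "lncRNA"

    def test_sif_line_format(self, tmp_path):
        net = MultilayerNetwork()
        net.add_node("mirX", "miRNA")
        net.add_node("geneY", "enzyme_gene")
        net.add_edge("mirX", "geneY", "mirna_target", 1.0)
        p = tmp_path / "net.sif"
        export(net, "sif", p)
        assert p.read_text() == "mirX\tmirna_target\tgeneY\n"

    def test_empty_network_valid_files(self, tmp_path):
        net = MultilayerNetwork()
        export(net, "sif", tmp_path / "e.sif")
        export(net, "graphml", tmp_path / "e.graphml")
        export(net, "tsv", tmp_path / "e")
        assert (tmp_path / "e.sif").read_text() == ""
        assert (tmp_path / "e.nodes.tsv").exists()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export(MultilayerNetwork(), "xlsx", tmp_path / "x")

    def test_exports_deterministic(self, tmp_path):
        net = _demo_network()
        export(net, "graphml", tmp_path / "a.graphml")
        export(net, "graphml", tmp_path / "b.graphml")
        assert (tmp_path / "a.graphml").read_bytes() == (tmp_path / "b.graphml").read_bytes()
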