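import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tsnetwork.network import (
    build_network,
    export_network,
    mcl_cluster,
    pearson_matrix,
    read_edgelist,
    read_graphml,
)


def corr_frame(values, genes):
    return pd.DataFrame(values, index=genes, columns=genes)


class TestPearsonMatrix:
    def test_diagonal_is_one(self, toy_expression):
        corr = pearson_matrix(toy_expression)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_perfect_anticorrelation(self):
        m = pd.DataFrame(
            {"s1": [1.0, 6.0], "s2": [2.0, 4.0], "s3": [3.0, 2.0]},
            index=["x", "y"],
        )
        assert pearson_matrix(m).loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_worked_r(self):
        # x=(1,2,3,4), y=(1,3,2,4): cov 1, sd^2 = 5/4 each -> r = 0.8
        m = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [2.0, 3.0], "s3": [3.0, 2.0],
             "s4": [4.0, 4.0]},
            index=["x", "y"],
        )
        assert pearson_matrix(m).loc["x", "y"] == pytest.approx(0.8)

    def test_too_few_samples_rejected(self, toy_expression):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_matrix(toy_expression, ["heart_r1", "heart_r2"])

    def test_zero_variance_gene_dropped(self, toy_expression, caplog):
        with caplog.at_level("WARNING"):
            corr = pearson_matrix(toy_expression)
        assert "g3" not in corr.index  # constant gene
        assert "zero-variance" in caplog.text

    def test_log_transform_requires_positive(self):
        m = pd.DataFrame(
            {"s1": [0.0, 1.0], "s2": [1.0, 2.0], "s3": [2.0, 4.0]},
            index=["x", "y"],
        )
        with pytest.raises(ValueError, match="positive"):
            pearson_matrix(m, log_transform=True)

    def test_one_factor_model_within_module_r(self, small_bundle,
                                              small_bundle_config):
        """Log-scale pairwise r should match loading^2/(loading^2+sd^2)."""
        matrix, annotation, _ = small_bundle
        cfg = small_bundle_config
        targets = annotation.loc[
            annotation["tissue"].isin(cfg.target_tissues), "sample_id"
        ].tolist()
        genes = [g for g in matrix.index if g.startswith("mod01_")]
        corr = pearson_matrix(matrix.loc[genes], targets, log_transform=True)
        vals = corr.to_numpy()[np.triu_indices(len(genes), k=1)]
        expected = cfg.factor_loading**2 / (
            cfg.factor_loading**2 + cfg.noise_sd_log**2
        )
        assert expected == pytest.approx(1 / (1 + 0.33**2))
        assert 0.85 <= vals.mean() <= 0.95


class TestBuildNetwork:
    def test_threshold_filter(self):
        genes = ["a", "b", "c"]
        vals = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.85], [0.5, 0.85, 1.0]])
        net = build_network(corr_frame(vals, genes), threshold=0.80)
        assert net.number_of_edges() == 2
        assert net.has_edge("a", "b") and net.has_edge("b", "c")

    def test_threshold_is_inclusive(self):
        genes = ["a", "b"]
        vals = np.array([[1.0, 0.80], [0.80, 1.0]])
        net = build_network(corr_frame(vals, genes), threshold=0.80)
        assert net.has_edge("a", "b")

    def test_threshold_one_gives_no_edges(self):
        genes = ["a", "b"]
        vals = np.array([[1.0, 0.999], [0.999, 1.0]])
        net = build_network(corr_frame(vals, genes), threshold=1.0)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 2  # isolates retained

    def test_no_self_edges(self, rng):
        genes = list("abcdef")
        raw = rng.uniform(-1, 1, size=(6, 6))
        vals = np.clip((raw + raw.T) / 2, -1, 1)
        np.fill_diagonal(vals, 1.0)
        net = build_network(corr_frame(vals, genes), threshold=0.0)
        assert all(a != b for a, b in net.edges)

    def test_edge_monotone_in_threshold(self, rng):
        genes = [f"g{i}" for i in range(10)]
        raw = rng.uniform(-1, 1, size=(10, 10))
        vals = np.clip((raw + raw.T) / 2, -1, 1)
        np.fill_diagonal(vals, 1.0)
        corr = corr_frame(vals, genes)
        loose = set(build_network(corr, threshold=0.2).edges)
        tight = set(build_network(corr, threshold=0.6).edges)
        assert tight <= loose

    def test_between_module_density_far_below_within(self, small_bundle,
                                                     small_bundle_config):
        matrix, annotation, manifest = small_bundle
        cfg = small_bundle_config
        targets = annotation.loc[
            annotation["tissue"].isin(cfg.target_tissues), "sample_id"
        ].tolist()
        module_genes = [
            g for g, mod in manifest.gene_module.items() if mod != "background"
        ]
        corr = pearson_matrix(
            matrix.loc[module_genes], targets, log_transform=True
        )
        net = build_network(corr, threshold=0.80)
        modules = manifest.gene_module
        within = between = 0
        for a, b in net.edges:
            if modules[a] == modules[b]:
                within += 1
            else:
                between += 1
        assert within > 0
        assert between <= 0.01 * within


def clique_graph(*sizes):
    graph = nx.Graph()
    node = 0
    for size in sizes:
        members = list(range(node, node + size))
        graph.add_nodes_from(members)
        graph.add_weighted_edges_from(
            (a, b, 1.0) for a, b in itertools.combinations(members, 2)
        )
        node += size
    return graph


class TestMCL:
    def test_two_disjoint_cliques_give_two_clusters(self):
        assignment = mcl_cluster(clique_graph(5, 5))
        assert sorted(assignment.sizes.values()) == [5, 5]
        labels = assignment.labels
        assert len({labels[i] for i in range(5)}) == 1
        assert len({labels[i] for i in range(5, 10)}) == 1

    def test_single_clique_is_one_cluster(self):
        assignment = mcl_cluster(clique_graph(4))
        assert list(assignment.sizes.values()) == [4]

    def test_isolated_nodes_become_singletons(self):
        graph = clique_graph(3)
        graph.add_nodes_from(["iso1", "iso2"])
        assignment = mcl_cluster(graph)
        assert sorted(assignment.sizes.values()) == [1, 1, 3]

    def test_cluster_ids_contiguous_and_size_ordered(self):
        assignment = mcl_cluster(clique_graph(2, 6, 4))
        assert list(assignment.sizes) == [1, 2, 3]
        assert list(assignment.sizes.values()) == [6, 4, 2]

    def test_iterates_stay_column_stochastic(self):
        seen = []

        def check(iteration, matrix):
            seen.append(iteration)
            np.testing.assert_allclose(matrix.sum(axis=0), 1.0, atol=1e-9)

        mcl_cluster(clique_graph(5, 3), on_iteration=check)
        assert seen  # callback actually ran

    def test_clusters_never_span_components(self, rng):
        graph = nx.Graph()
        offset = 0
        for size in (6, 5, 7):
            nodes = list(range(offset, offset + size))
            graph.add_nodes_from(nodes)
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.7:
                    graph.add_edge(a, b, weight=rng.uniform(0.5, 1.0))
            offset += size
        components = list(nx.connected_components(graph))
        assignment = mcl_cluster(graph)
        for cid, members in assignment.clusters().items():
            member_set = set(members)
            assert any(member_set <= comp for comp in components)

    def test_higher_inflation_never_coarsens(self, small_bundle,
                                             small_bundle_config):
        matrix, annotation, manifest = small_bundle
        cfg = small_bundle_config
        targets = annotation.loc[
            annotation["tissue"].isin(cfg.target_tissues), "sample_id"
        ].tolist()
        module_genes = [
            g for g, mod in manifest.gene_module.items() if mod != "background"
        ]
        corr = pearson_matrix(
            matrix.loc[module_genes], targets, log_transform=True
        )
        net = build_network(corr, threshold=0.80)
        counts = [
            len(mcl_cluster(net, inflation=inf).sizes)
            for inf in (1.4, 2.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_invalid_parameters_rejected(self):
        graph = clique_graph(3)
        with pytest.raises(ValueError, match="inflation"):
            mcl_cluster(graph, inflation=1.0)
        with pytest.raises(ValueError, match="expansion"):
            mcl_cluster(graph, expansion=1)
        with pytest.raises(ValueError, match="at least one node"):
            mcl_cluster(nx.Graph())

    def test_nonconvergence_warns_and_still_partitions(self, caplog):
        graph = nx.path_graph(8)
        nx.set_edge_attributes(graph, 1.0, "weight")
        with caplog.at_level("WARNING"):
            assignment = mcl_cluster(graph, max_iter=1)
        assert not assignment.converged
        assert "did not converge" in caplog.text
        assert sum(assignment.sizes.values()) == 8

    def test_recovers_planted_modules(self, small_bundle, small_bundle_config):
        from sklearn.metrics import adjusted_rand_score

        matrix, annotation, manifest = small_bundle
        cfg = small_bundle_config
        targets = annotation.loc[
            annotation["tissue"].isin(cfg.target_tissues), "sample_id"
        ].tolist()
        module_genes = [
            g for g, mod in manifest.gene_module.items() if mod != "background"
        ]
        corr = pearson_matrix(
            matrix.loc[module_genes], targets, log_transform=True
        )
        assignment = mcl_cluster(build_network(corr, threshold=0.80))
        truth = [manifest.gene_module[g] for g in module_genes]
        found = [assignment.labels[g] for g in module_genes]
        assert adjusted_rand_score(truth, found) >= 0.99


class TestExport:
    @pytest.fixture()
    def toy_net(self):
        corr = corr_frame(
            np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.85], [0.2, 0.85, 1.0]]),
            ["a", "b", "c"],
        )
        net = build_network(corr, threshold=0.80)
        return net, mcl_cluster(net)

    def test_edgelist_line_count(self, toy_net, tmp_path):
        net, assignment = toy_net
        path = export_network(net, assignment, tmp_path / "e.tsv", fmt="edgelist")
        lines = path.read_text().splitlines()
        assert lines[0] == "gene_a\tgene_b\tr"
        assert len(lines) == 1 + 2

    def test_edgelist_round_trip(self, toy_net, tmp_path):
        net, assignment = toy_net
        path = export_network(net, assignment, tmp_path / "e.tsv", fmt="edgelist")
        back = read_edgelist(path)
        assert set(back.edges) == set(net.edges)

    def test_graphml_round_trip_with_clusters(self, toy_net, tmp_path):
        net, assignment = toy_net
        path = export_network(net, assignment, tmp_path / "n.graphml",
                              fmt="graphml")
        back = read_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert set(back.edges) == set(net.edges)
        assert nx.get_node_attributes(back, "cluster") == assignment.labels

    def test_empty_network_exports(self, tmp_path):
        net = nx.Graph()
        net.add_nodes_from(["a", "b"])
        path = export_network(net, None, tmp_path / "e.tsv", fmt="edgelist")
        assert path.read_text().splitlines() == ["gene_a\tgene_b\tr"]
        gpath = export_network(net, None, tmp_path / "n.graphml", fmt="graphml")
        assert set(read_graphml(gpath).nodes) == {"a", "b"}

    def test_unknown_format_rejected(self, toy_net, tmp_path):
        net, assignment = toy_net
        with pytest.raises(ValueError, match="edgelist, graphml"):
            export_network(net, assignment, tmp_path / "x", fmt="dot")
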