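import networkx as nx
import numpy as np
import pytest

from papnet import (
    SimulationConfig,
    adjust_bonferroni,
    enrich,
    filter_high_confidence,
    generate_abundance_table,
    generate_go_resources,
    generate_ppi_network,
    mcc_scores,
    normalize_abundance,
    propagate_annotations,
    simulate_study,
)


def _one_cluster_config(size, clique_sizes, **kw):
    return SimulationConfig(
        n_proteins=size,
        n_clusters=1,
        cluster_sizes=(size,),
        centroid_matrix=((0.0,) * 6,),
        planted_clique_sizes=(clique_sizes,),
        **kw,
    )


class TestConfigValidation:
    def test_cluster_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(cluster_sizes=(12, 4, 11, 3, 16, 19))

    def test_enriched_prob_must_exceed_baseline(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(
                baseline_annotation_prob=0.5, enriched_annotation_prob=0.5
            )

    def test_low_scores_must_stay_below_threshold(self):
        with pytest.raises(ValueError, match="below the threshold"):
            SimulationConfig(score_low_range=(100, 750))


class TestAbundance:
    def test_published_cluster_sizes_planted_exactly(self):
        _, labels = generate_abundance_table(SimulationConfig(seed=1))
        assert labels.value_counts().sort_index().tolist() == [12, 4, 11, 3, 16, 20]
        assert len(labels) == 66

    def test_noise_free_single_cluster_normalizes_to_zero_profile(self):
        cfg = _one_cluster_config(5, (3,), noise_sd=0.0)
        table, _ = generate_abundance_table(cfg)
        profiles = normalize_abundance(table)
        assert np.allclose(profiles.to_numpy(), 0.0, atol=1e-12)

    def test_all_values_strictly_positive(self):
        table, _ = generate_abundance_table(SimulationConfig(seed=2))
        assert (table.to_numpy() > 0).all()

    def test_reproducible_for_identical_config(self):
        t1, l1 = generate_abundance_table(SimulationConfig(seed=9))
        t2, l2 = generate_abundance_table(SimulationConfig(seed=9))
        assert t1.equals(t2) and l1.equals(l2)
        t3, _ = generate_abundance_table(SimulationConfig(seed=10))
        assert not t1.equals(t3)


class TestPpi:
    def test_single_planted_clique_is_k4_after_filtering(self):
        cfg = _one_cluster_config(4, (4,), background_edge_prob=0.0)
        g, truth = generate_ppi_network(cfg, {0: ["h", "a", "b", "c"]})
        filtered = filter_high_confidence(g)
        assert nx.utils.graphs_equal(
            nx.Graph(filtered.edges()), nx.complete_graph(["h", "a", "b", "c"])
        )
        assert truth["hubs"]["0"] == "h"

    def test_hub_in_two_disjoint_triangles_has_mcc_four(self):
        cfg = _one_cluster_config(5, (3, 3), background_edge_prob=0.0)
        g, truth = generate_ppi_network(cfg, {0: ["h", "a", "b", "c", "d"]})
        filtered = filter_high_confidence(g)
        scores = mcc_scores(filtered)
        assert scores["h"] == 4
        assert truth["expected_hub_mcc"]["0"] == 4

    def test_score_partition_filters_to_planted_edges(self, study):
        filtered = filter_high_confidence(study.ppi)
        assert (
            filtered.number_of_edges() == study.ppi_truth["planted_edge_count"]
        )

    def test_duplicate_seed_ids_rejected(self):
        cfg = _one_cluster_config(4, (4,))
        cfg2 = SimulationConfig(
            n_proteins=8, n_clusters=2, cluster_sizes=(4, 4),
            centroid_matrix=((0.0,) * 6,) * 2,
            planted_clique_sizes=((4,), (4,)),
        )
        with pytest.raises(ValueError, match="duplicate"):
            generate_ppi_network(
                cfg2, {0: ["h", "a", "b", "c"], 1: ["h", "x", "y", "z"]}
            )
        del cfg

    def test_reproducible_edges_and_scores(self):
        cfg = SimulationConfig(seed=5)
        sa = {
            c: [f"P{c}{i}" for i in range(n)]
            for c, n in enumerate(cfg.cluster_sizes)
        }
        g1, _ = generate_ppi_network(cfg, sa)
        g2, _ = generate_ppi_network(cfg, sa)
        assert nx.utils.graphs_equal(g1, g2)


class TestGoResources:
    def test_degenerate_probabilities_annotate_exactly_designated_set(self):
        cfg = _one_cluster_config(
            4, (4,), baseline_annotation_prob=0.0, enriched_annotation_prob=1.0
        )
        genes = {f"g{i}" for i in range(20)}
        designated = frozenset(list(sorted(genes))[:5])
        dag, ann, planted = generate_go_resources(
            cfg, {"A": designated}, universe=genes
        )
        for namespace, term in planted["A"].items():
            annotated = {g for g, t in ann.direct if t == term}
            assert annotated == designated
        # nothing else is annotated anywhere
        planted_terms = set(planted["A"].values())
        assert {t for _, t in ann.direct} == planted_terms

    def test_three_namespaces_each_have_one_root(self):
        cfg = SimulationConfig(seed=4)
        dag, _, _ = generate_go_resources(
            cfg, {"A": {"g1"}}, universe={"g1", "g2"}
        )
        assert sorted(dag.roots) == [
            "biological_process", "cellular_component", "molecular_function",
        ]
        for term in dag.terms.values():
            assert term.namespace in dag.roots

    def test_planted_term_survives_bonferroni_across_seeds(self):
        # 30 study genes in a 300-gene background, 0.9 vs 0.05 annotation
        # contrast: the planted term must be significant in >= 95/100 seeds
        universe = {f"g{i:03d}" for i in range(300)}
        studyset = frozenset(sorted(universe)[:30])
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = _one_cluster_config(
                4, (4,), seed=seed,
                baseline_annotation_prob=0.05,
                enriched_annotation_prob=0.9,
                n_terms_per_namespace=20,
                dag_depth=3,
            )
            dag, ann, planted = generate_go_resources(
                cfg, {"A": studyset}, universe=universe
            )
            ann = propagate_annotations(dag, ann)
            term = planted["A"]["biological_process"]
            from papnet import annotated_universe

            eligible = studyset & annotated_universe(
                ann, dag, "biological_process"
            )
            results = adjust_bonferroni(
                enrich(eligible, ann, dag, "biological_process")
            )
            by_term = {r.term: r for r in results}
            if term in by_term and by_term[term].significant:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestWholeStudy:
    def test_identical_seed_reproduces_study_byte_identically(self, tmp_path):
        from papnet import write_abundance, write_annotations, write_obo, write_ppi_tsv

        files = {}
        for tag in ("x", "y"):
            s = simulate_study(SimulationConfig(seed=21))
            d = tmp_path / tag
            d.mkdir()
            write_abundance(s.abundance, d / "a.csv")
            write_ppi_tsv(s.ppi, d / "p.tsv")
            write_obo(s.dag, d / "o.obo")
            write_annotations(s.annotations, s.dag, d / "n.tsv")
            files[tag] = {
                f.name: f.read_bytes() for f in sorted(d.iterdir())
            }
        assert files["x"] == files["y"]

    def test_planted_terms_reference_subnetwork_genes(self, study, propagated):
        from papnet.enrichment import genes_by_term

        for label, by_ns in study.planted_terms.items():
            for namespace, term in by_ns.items():
                assert term in study.dag
                assert study.dag.namespace(term) == namespace
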