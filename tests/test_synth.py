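import filecmp

import networkx as nx
import pandas as pd
import pytest

from ppikit.apfilter import DEFAULT_CONTAMINANTS, occurrence_from_matrix
from ppikit.netgraph import build_graph, mcode_complexes
from ppikit.pipeline import run_interactome_pipeline
from ppikit.synth import (
    ConfigError,
    SynthConfig,
    gen_apms_dataset,
    gen_bret_screen,
    gen_control_occurrence,
    gen_gene_sets,
    gen_string_edges,
    write_all,
)


class TestConfigValidation:
    def test_negative_count_names_field(self):
        with pytest.raises(ConfigError, match="n_true_interactors"):
            SynthConfig(n_true_interactors=-1)

    def test_fraction_bounds(self):
        with pytest.raises(ConfigError, match="replicate_overlap_fraction"):
            SynthConfig(replicate_overlap_fraction=1.5)

    def test_density_bounds(self):
        with pytest.raises(ConfigError, match="densities"):
            SynthConfig(planted_clusters=((4, 0.0),))

    def test_negative_transfer_efficiency(self):
        with pytest.raises(ConfigError, match="bret_truth"):
            SynthConfig(bret_truth={"X": -0.1})

    def test_overlap_exceeding_sets(self):
        with pytest.raises(ConfigError, match="asd_id_overlap"):
            SynthConfig(n_asd=2, n_id=2, asd_id_overlap=3)


class TestDeterminism:
    def test_identical_seed_identical_tables(self):
        a = gen_apms_dataset(SynthConfig(seed=1))
        b = gen_apms_dataset(SynthConfig(seed=1))
        for rep in a.baits:
            pd.testing.assert_frame_equal(a.baits[rep], b.baits[rep])
        for rep in a.controls:
            pd.testing.assert_frame_equal(a.controls[rep], b.controls[rep])

    def test_different_seed_differs(self):
        a = gen_apms_dataset(SynthConfig(seed=1))
        b = gen_apms_dataset(SynthConfig(seed=2))
        assert not a.baits["AP1"].equals(b.baits["AP1"])

    def test_written_files_byte_identical(self, tmp_path):
        cfg = SynthConfig(seed=7, n_true_interactors=12, n_contaminant_shared=3,
                          n_crapome_frequent=2)
        paths_a = write_all(cfg, tmp_path / "a")
        paths_b = write_all(cfg, tmp_path / "b")
        assert sorted(paths_a) == sorted(paths_b)
        for name in paths_a:
            assert filecmp.cmp(paths_a[name], paths_b[name], shallow=False), name


class TestApmsDataset:
    def test_truth_sets_disjoint(self, default_cfg):
        truth = gen_apms_dataset(default_cfg).truth
        assert not truth.true_interactors & truth.contaminants

    def test_no_true_interactors_in_controls(self, default_cfg):
        ds = gen_apms_dataset(default_cfg)
        for table in ds.controls.values():
            assert not set(table["protein_id"]) & ds.truth.true_interactors

    def test_shared_contaminants_in_bait_and_control(self, default_cfg):
        ds = gen_apms_dataset(default_cfg)
        shared = {p for p in ds.truth.contaminants if p.startswith("SHC")}
        for table in list(ds.baits.values()) + list(ds.controls.values()):
            assert shared <= set(table["protein_id"])

    def test_zero_true_interactors_gives_contaminants_only(self):
        ds = gen_apms_dataset(SynthConfig(seed=1, n_true_interactors=0))
        for table in ds.baits.values():
            assert set(table["protein_id"]) <= (
                ds.truth.contaminants | ds.truth.crapome_excluded
            )

    def test_some_scores_below_threshold(self, default_cfg):
        ds = gen_apms_dataset(default_cfg)
        scores = ds.baits["AP1"]["mascot_score"]
        assert (scores < 40).any() and (scores >= 40).any()

    def test_peptide_counts_within_configured_ranges(self, default_cfg):
        ds = gen_apms_dataset(default_cfg)
        lo, hi = default_cfg.observable_peptide_range
        assert ds.observable_counts.between(lo, hi).all()
        kept = ds.baits["AP1"]
        kept = kept[kept["mascot_score"] >= 40]
        per_protein = kept.groupby("protein_id")["peptide_seq"].nunique()
        plo, phi = default_cfg.peptide_count_range
        assert per_protein.between(1, phi).all()

    def test_partial_overlap_split(self):
        cfg = SynthConfig(seed=4, n_true_interactors=10,
                          replicate_overlap_fraction=0.5)
        ds = gen_apms_dataset(cfg)
        both = ds.truth.true_in_both_replicates
        assert len(both) == 5
        in_ap1 = set(ds.baits["AP1"]["protein_id"]) & ds.truth.true_interactors
        in_ap2 = set(ds.baits["AP2"]["protein_id"]) & ds.truth.true_interactors
        assert in_ap1 & in_ap2 == both
        assert in_ap1 | in_ap2 == ds.truth.true_interactors


class TestControlOccurrence:
    def test_default_30_columns(self, default_cfg):
        assert gen_control_occurrence(default_cfg).shape[1] == 30

    def test_frequent_proteins_occur_at_least_twice(self, default_cfg):
        matrix = gen_control_occurrence(default_cfg)
        occurrence, _ = occurrence_from_matrix(matrix)
        truth = gen_apms_dataset(default_cfg).truth
        for protein in truth.crapome_excluded:
            assert occurrence[protein] >= 2
        for protein, occ in occurrence.items():
            if protein not in truth.crapome_excluded:
                assert occ <= 1

    def test_no_frequent_proteins_row_sums_at_most_one(self):
        cfg = SynthConfig(seed=1, n_crapome_frequent=0)
        matrix = gen_control_occurrence(cfg)
        assert (matrix.sum(axis=1) <= 1).all()


class TestStringEdges:
    def test_planted_cliques_recovered_downstream(self):
        cfg = SynthConfig(seed=1, n_true_interactors=30,
                          planted_clusters=((6, 1.0), (6, 1.0)),
                          background_edge_prob=0.0)
        edges, membership = gen_string_edges(None, cfg)
        graph = build_graph(sorted(set(membership)), edges)
        clusters = mcode_complexes(graph)
        assert len(clusters) == 2
        found = {frozenset(c.nodes) for c in clusters}
        planted = {
            frozenset(p for p, c in membership.items() if c == cid)
            for cid in set(membership.values())
        }
        assert found == planted

    def test_no_clusters_no_background_empty(self):
        cfg = SynthConfig(seed=1, planted_clusters=(), background_edge_prob=0.0)
        edges, membership = gen_string_edges(None, cfg)
        assert edges.empty and membership == {}

    def test_low_scores_filtered_to_empty_graph(self):
        cfg = SynthConfig(seed=1, planted_clusters=((5, 1.0),),
                          background_edge_prob=0.0)
        edges, _ = gen_string_edges(None, cfg)
        edges["combined_score"] = 0.5
        graph = build_graph(sorted(set(edges["protein_a"]) | set(edges["protein_b"])),
                            edges)
        assert graph.number_of_edges() == 0

    def test_planted_scores_high_confidence(self):
        cfg = SynthConfig(seed=1, planted_clusters=((6, 1.0),),
                          background_edge_prob=0.0)
        edges, _ = gen_string_edges(None, cfg)
        assert (edges["combined_score"] >= 0.700).all()

    def test_oversized_cluster_rejected(self):
        cfg = SynthConfig(seed=1, planted_clusters=((50, 1.0),))
        with pytest.raises(ConfigError, match="planted_clusters"):
            gen_string_edges(["A", "B"], cfg)


class TestGeneSets:
    def test_union_arithmetic(self):
        cfg = SynthConfig(seed=1, n_asd=11, n_id=24, asd_id_overlap=4)
        sets = gen_gene_sets(cfg)
        assert len(sets["ASD"]) == 11
        assert len(sets["ID"]) == 24
        assert len(sets["ASD"] & sets["ID"]) == 4
        assert len(sets["ASD"] | sets["ID"]) == 31

    def test_disjoint_sets(self):
        cfg = SynthConfig(seed=1, n_asd=5, n_id=7, asd_id_overlap=0)
        sets = gen_gene_sets(cfg)
        assert len(sets["ASD"] | sets["ID"]) == 12

    def test_nested_overlap(self):
        cfg = SynthConfig(seed=1, n_asd=5, n_id=7, asd_id_overlap=5)
        sets = gen_gene_sets(cfg)
        assert sets["ASD"] <= sets["ID"]
        assert len(sets["ASD"] | sets["ID"]) == 7


class TestTruthRecovery:
    def test_noise_free_end_to_end(self):
        cfg = SynthConfig(seed=11, n_true_interactors=50,
                          replicate_overlap_fraction=1.0)
        ds = gen_apms_dataset(cfg)
        occurrence, _ = occurrence_from_matrix(gen_control_occurrence(cfg))
        result = run_interactome_pipeline(
            ds.baits, ds.controls, ds.observable_counts, occurrence,
            DEFAULT_CONTAMINANTS,
        )
        assert result.final_hits == ds.truth.true_interactors
        assert set(result.abundance.index) == ds.truth.true_interactors
        assert sorted(result.abundance["rank"]) == list(range(1, 51))

    def test_designed_partial_overlap_recovered(self):
        cfg = SynthConfig(seed=12, n_true_interactors=20,
                          replicate_overlap_fraction=0.6)
        ds = gen_apms_dataset(cfg)
        occurrence, _ = occurrence_from_matrix(gen_control_occurrence(cfg))
        result = run_interactome_pipeline(
            ds.baits, ds.controls, ds.observable_counts, occurrence,
        )
        assert result.final_hits == ds.truth.true_in_both_replicates
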