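"""Synthetic-input generators: design structure, planted truths, determinism."""

import numpy as np
import pandas as pd
import pytest

from saltgenes.motifs import IUPAC_SETS, MotifConsensus, scan_motif
from saltgenes.network import find_modules, merge_isoforms
from saltgenes.qtl import map_genes_to_intervals
from saltgenes.simulate import (
    ExprSimConfig,
    GenomeSimConfig,
    NetworkSimConfig,
    PromoterSimConfig,
    simulate_expression,
    simulate_genome_qtls,
    simulate_network,
    simulate_promoters,
)


class TestExpression:
    def test_three_genotypes_three_reps_give_18_samples(self):
        matrix, _ = simulate_expression(ExprSimConfig(n_probes=50, n_informative=5))
        assert matrix.n_samples == 18
        labels = matrix.label_vector()
        assert (labels == 1).sum() == 9 and (labels == -1).sum() == 9

    def test_informative_probes_shift_class_means_by_effect(self):
        cfg = ExprSimConfig(n_probes=500, n_informative=50, effect_size=3.0, seed=3)
        matrix, truth = simulate_expression(cfg)
        labels = matrix.label_vector()
        X = matrix.values.to_numpy()
        diff = X[:, labels == -1].mean(axis=1) - X[:, labels == 1].mean(axis=1)
        inf = truth["informative"].to_numpy()
        assert diff[inf].mean() == pytest.approx(3.0, abs=0.3)
        assert abs(diff[~inf].mean()) < 0.3

    def test_zero_effect_leaves_classes_indistinguishable(self):
        matrix, truth = simulate_expression(
            ExprSimConfig(n_probes=300, n_informative=30, effect_size=0.0, seed=5)
        )
        labels = matrix.label_vector()
        X = matrix.values.to_numpy()
        diff = X[:, labels == -1].mean(axis=1) - X[:, labels == 1].mean(axis=1)
        inf = truth["informative"].to_numpy()
        assert abs(diff[inf].mean()) < 0.3

    def test_same_seed_reproduces_matrix(self):
        a, ta = simulate_expression(ExprSimConfig(n_probes=40, n_informative=4, seed=11))
        b, tb = simulate_expression(ExprSimConfig(n_probes=40, n_informative=4, seed=11))
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(ta, tb)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_probes=0),
            dict(n_informative=100, n_probes=50),
            dict(effect_size=-1.0),
            dict(noise_sd=0.0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExprSimConfig(**kwargs)


class TestGenomeQtls:
    def test_full_planting_puts_every_informative_gene_in_a_qtl(self):
        cfg = GenomeSimConfig(n_genes=200, n_qtls=5, planted_overlap_fraction=1.0, seed=2)
        informative = [f"PROBE_{i:05d}" for i in range(0, 40)]
        genes, qtls = simulate_genome_qtls(cfg, informative)
        hits = map_genes_to_intervals(genes, qtls, mode="original")
        assert set(informative) <= hits

    def test_no_qtls_gives_empty_interval_list(self):
        genes, qtls = simulate_genome_qtls(GenomeSimConfig(n_genes=50, n_qtls=0, seed=1))
        assert qtls == []
        assert map_genes_to_intervals(genes, qtls) == set()

    def test_intervals_lie_within_chromosomes_and_are_1_based(self):
        cfg = GenomeSimConfig(n_genes=100, n_qtls=20, seed=9)
        genes, qtls = simulate_genome_qtls(cfg)
        for q in qtls:
            assert 1 <= q.start <= q.end <= cfg.chrom_length
        assert (genes["start"] >= 1).all()
        assert (genes["end"] <= cfg.chrom_length).all()

    def test_same_seed_reproduces_coordinates(self):
        cfg = GenomeSimConfig(n_genes=80, n_qtls=4, seed=13)
        g1, q1 = simulate_genome_qtls(cfg)
        g2, q2 = simulate_genome_qtls(cfg)
        pd.testing.assert_frame_equal(g1, g2)
        assert q1 == q2

    def test_unknown_informative_id_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_genome_qtls(GenomeSimConfig(n_genes=10), ["NOT_A_GENE"])

    def test_oversized_qtl_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            GenomeSimConfig(chrom_length=1000, qtl_length_min=10, qtl_length_max=2000)


class TestNetwork:
    def test_zero_background_recovers_planted_partition(self):
        cfg = NetworkSimConfig(
            n_nodes=40, n_modules=5, within_module_edge_prob=1.0,
            background_edge_prob=0.0, isoform_rate=0.0, seed=3,
        )
        edges, truth = simulate_network(cfg)
        modules, singletons = find_modules(merge_isoforms(edges))
        found = {frozenset(m.members) for m in modules}
        planted = {
            frozenset(truth.index[truth["module"] == k])
            for k in truth["module"].unique()
            if (truth["module"] == k).sum() >= 2
        }
        assert found == planted

    def test_zero_isoform_rate_leaves_ids_unsuffixed(self):
        edges, _ = simulate_network(NetworkSimConfig(n_nodes=20, isoform_rate=0.0, seed=1))
        assert all("." not in a and "." not in b for a, b in edges)

    def test_complete_5_node_module_has_10_edges(self):
        cfg = NetworkSimConfig(
            n_nodes=5, n_modules=1, within_module_edge_prob=1.0,
            background_edge_prob=0.0, isoform_rate=0.0, seed=0,
        )
        edges, _ = simulate_network(cfg)
        modules, _ = find_modules(merge_isoforms(edges))
        assert len(modules) == 1
        assert modules[0].n_nodes == 5 and modules[0].n_edges == 10

    def test_isoform_duplicates_share_edges(self):
        cfg = NetworkSimConfig(
            n_nodes=10, n_modules=1, within_module_edge_prob=1.0,
            background_edge_prob=0.0, isoform_rate=1.0, seed=4,
        )
        edges, _ = simulate_network(cfg)
        assert all(a.count(".") == 1 for a, b in edges)
        merged = merge_isoforms(edges)
        assert merged.number_of_nodes() == 10 and merged.number_of_edges() == 45

    def test_same_seed_reproduces_edge_list(self):
        cfg = NetworkSimConfig(n_nodes=30, seed=8)
        assert simulate_network(cfg)[0] == simulate_network(cfg)[0]


class TestPromoters:
    def test_extreme_rates_give_clean_separation(self):
        cfg = PromoterSimConfig(
            n_target=20, n_background=20, promoter_length=200,
            target_presence_rate=1.0, background_presence_rate=0.0, seed=6,
        )
        target, background, truth = simulate_promoters(cfg)
        motif = MotifConsensus("planted", cfg.planted_motif)
        assert scan_motif(target, motif)["present"].all()
        assert truth.loc[list(target), "planted"].all()

    def test_motif_length_promoter_is_a_motif_realization(self):
        cfg = PromoterSimConfig(
            n_target=5, n_background=0, promoter_length=9,
            planted_motif="TCTCTCTCT", target_presence_rate=1.0, seed=2,
        )
        target, _, _ = simulate_promoters(cfg)
        for seq in target.values():
            assert len(seq) == 9
            assert all(base in IUPAC_SETS[m] for base, m in zip(seq, "TCTCTCTCT"))

    def test_sequences_use_acgt_only(self):
        target, background, _ = simulate_promoters(
            PromoterSimConfig(n_target=5, n_background=5, promoter_length=100, seed=3)
        )
        for seq in {**target, **background}.values():
            assert set(seq) <= set("ACGT")

    def test_motif_longer_than_promoter_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            PromoterSimConfig(promoter_length=5, planted_motif="TCTCTCTCT")

    def test_same_seed_reproduces_sequences(self):
        cfg = PromoterSimConfig(n_target=4, n_background=4, promoter_length=50, seed=10)
        assert simulate_promoters(cfg)[0] == simulate_promoters(cfg)[0]
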