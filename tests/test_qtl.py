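"""QTL dedupe/extension, gene-interval mapping and the hypergeometric test."""

import math

import numpy as np
import pandas as pd
import pytest

from saltgenes.qtl import (
    EnrichmentCounts,
    QtlInterval,
    dedupe_qtls,
    extend_interval,
    hit_percentage,
    load_salt_qtls,
    map_genes_to_intervals,
    microarray_qtl_test,
    term_enrichment,
)
from saltgenes.simulate import GenomeSimConfig, simulate_genome_qtls


def hypergeom_upper_tail_oracle(N: int, m: int, n: int, k: int) -> float:
    """Closed-form upper tail via binomial coefficients (independent of scipy)."""
    total = math.comb(N, n)
    return sum(math.comb(m, j) * math.comb(N - m, n - j) for j in range(k, min(m, n) + 1)) / total


class TestDedupe:
    def test_packaged_salt_qtls_17_to_13(self):
        qtls = load_salt_qtls()
        assert len(qtls) == 17
        unique = dedupe_qtls(qtls)
        assert len(unique) == 13
        by_id = {q.qtl_id: q for q in unique}
        # the four duplicate rows alias onto their first occurrence
        assert by_id["AQEM001"].aliases == ("AQEM008",)
        assert by_id["AQEM004"].aliases == ("AQEM010", "AQEM005", "AQEM011")

    def test_empty_list(self):
        assert dedupe_qtls([]) == []

    def test_two_of_three_identical(self):
        ivs = [
            QtlInterval("a", "1", 10, 20),
            QtlInterval("b", "1", 10, 20),
            QtlInterval("c", "2", 10, 20),
        ]
        out = dedupe_qtls(ivs)
        assert [q.qtl_id for q in out] == ["a", "c"]

    def test_malformed_interval_names_the_row(self):
        with pytest.raises(ValueError, match="bad_qtl"):
            QtlInterval("bad_qtl", "1", 50, 10)


class TestExtend:
    def test_gramene_aqgr001_arithmetic(self):
        q = QtlInterval("AQGR001", "1", 38_530_957, 38_531_467)
        assert q.length == 511
        out = extend_interval(q, chrom_length=45_000_000)
        assert out.extended_start == 38_530_446
        assert out.extended_end == 38_531_978

    def test_left_clip_at_chromosome_start(self):
        out = extend_interval(QtlInterval("q", "1", 1, 100), chrom_length=10_000)
        assert out.extended_start == 1
        assert out.extended_end == 200

    def test_unclipped_extended_length_is_3L(self):
        q = QtlInterval("q", "2", 1000, 1499)
        out = extend_interval(q, chrom_length=10_000)
        assert out.extended_end - out.extended_start + 1 == 3 * q.length

    def test_chromosome_shorter_than_interval_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            extend_interval(QtlInterval("q", "1", 10, 500), chrom_length=400)


class TestMapGenes:
    @pytest.fixture
    def intervals(self):
        q = QtlInterval("q1", "1", 1000, 2000)
        return [extend_interval(q, chrom_length=100_000)]

    def make_genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])

    def test_gene_inside_hits(self, intervals):
        genes = self.make_genes([("1", 1200, 1300, "g")])
        assert map_genes_to_intervals(genes, intervals) == {"g"}

    def test_gene_straddling_boundary_hits(self, intervals):
        genes = self.make_genes([("1", 1950, 2500, "g")])
        assert map_genes_to_intervals(genes, intervals) == {"g"}

    def test_adjacent_but_disjoint_misses(self, intervals):
        genes = self.make_genes([("1", 2001, 2500, "g")])
        assert map_genes_to_intervals(genes, intervals) == set()

    def test_other_chromosome_misses(self, intervals):
        genes = self.make_genes([("2", 1200, 1300, "g")])
        assert map_genes_to_intervals(genes, intervals) == set()

    def test_extended_hits_contain_original_hits(self):
        cfg = GenomeSimConfig(n_genes=300, n_qtls=6, seed=21)
        genes, qtls = simulate_genome_qtls(cfg)
        qtls = [extend_interval(q, cfg.chrom_length) for q in qtls]
        original = map_genes_to_intervals(genes, qtls, mode="original")
        extended = map_genes_to_intervals(genes, qtls, mode="extended")
        assert original <= extended

    def test_extended_mode_requires_extension(self):
        with pytest.raises(ValueError, match="extended bounds"):
            map_genes_to_intervals(
                self.make_genes([("1", 1, 10, "g")]),
                [QtlInterval("q", "1", 5, 8)],
                mode="extended",
            )


class TestMicroarrayQtlTest:
    def test_enumeration_spot_check(self):
        # N=10, m=3, n=4: of the 210 subsets, 70/210 have >= 2 successes
        assert microarray_qtl_test(EnrichmentCounts(10, 3, 4, 2)) == pytest.approx(1 / 3)

    def test_k_zero_is_certain(self):
        assert microarray_qtl_test(EnrichmentCounts(100, 10, 5, 0)) == 1.0

    def test_all_genes_covered_forces_k_equals_n(self):
        assert microarray_qtl_test(EnrichmentCounts(50, 50, 7, 7)) == pytest.approx(1.0)

    def test_matches_closed_form_oracle_on_a_grid(self):
        for N in (5, 8):
            for m in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(m, n) + 1):
                        expected = hypergeom_upper_tail_oracle(N, m, n, k)
                        got = microarray_qtl_test(EnrichmentCounts(N, m, n, k))
                        assert got == pytest.approx(expected, abs=1e-12), (N, m, n, k)

    def test_p_nonincreasing_in_k(self):
        ps = [microarray_qtl_test(EnrichmentCounts(200, 40, 30, k)) for k in range(31)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("N,m,n,k", [(10, 11, 4, 2), (10, 3, 4, 4), (10, 3, 11, 2)])
    def test_invariant_violations_rejected(self, N, m, n, k):
        with pytest.raises(ValueError):
            EnrichmentCounts(N, m, n, k)


class TestHitPercentage:
    @pytest.mark.parametrize("k,n,expected", [(34, 556, 6.12), (94, 556, 16.91), (0, 7, 0.0)])
    def test_rounded_percentages(self, k, n, expected):
        assert hit_percentage(k, n) == expected

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            hit_percentage(1, 0)


class TestTermEnrichment:
    def test_counts_and_p_against_oracle(self):
        background = {f"g{i}" for i in range(10)}
        selected = {"g0", "g1", "g2", "g3"}
        term_map = {
            "termA": {"g0", "g1", "g5"},     # m=3, k=2
            "termB": set(background),        # whole background -> p = 1
            "termC": {"g7", "g8"},           # m=2, k=0 -> p = 1
        }
        out = term_enrichment(selected, term_map, background)
        assert out.loc["termA", "n_selected"] == 2
        assert out.loc["termA", "p_value"] == pytest.approx(
            hypergeom_upper_tail_oracle(10, 3, 4, 2)
        )
        assert out.loc["termB", "p_value"] == pytest.approx(1.0)
        assert out.loc["termC", "p_value"] == pytest.approx(1.0)

    def test_bh_step_up_hand_case(self):
        # engineered so the raw p-values are strictly ordered; BH multiplies
        # by n_terms/rank and enforces monotonicity from the bottom up
        background = {f"g{i}" for i in range(10)}
        selected = {"g0", "g1", "g2", "g3"}
        term_map = {
            "t1": {"g0", "g1", "g2"},
            "t2": {"g0", "g1", "g5"},
            "t3": {"g0", "g5", "g6"},
        }
        out = term_enrichment(selected, term_map, background)
        p = out["p_value"].to_numpy()
        expected_bh = np.minimum.accumulate((p * 3 / np.arange(1, 4))[::-1])[::-1]
        np.testing.assert_allclose(out["fdr"].to_numpy(), np.minimum(expected_bh, 1.0))
        assert (np.diff(out["fdr"].to_numpy()) >= -1e-15).all()

    def test_empty_selected_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            term_enrichment(set(), {"t": {"g"}}, {"g"})

    def test_selected_outside_background_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            term_enrichment({"x"}, {"t": {"g"}}, {"g"})
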