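import numpy as np
import pytest
from scipy import stats

from chromcompare.enrichment import (
    GoTerm,
    SnpCatalog,
    enrichment_trend,
    go_enrichment,
    snp_associated_genes,
    snp_enrichment_score,
    snp_frequency,
)
from chromcompare.genome import DHSPeak, GeneModel, GenomeAssembly, GenomicInterval


def catalog(positions, chrom="chr1"):
    return SnpCatalog([(chrom, p) for p in positions])


class TestSnpFrequency:
    def test_per_kb_rate(self):
        peak = GenomicInterval("chr1", 0, 2500)
        assert snp_frequency(peak, catalog([10, 20, 30, 40, 50])) == pytest.approx(2.0)

    def test_zero_snps(self):
        assert snp_frequency(GenomicInterval("chr1", 0, 1000), catalog([5000])) == 0.0

    def test_hand_example(self):
        peak = GenomicInterval("chr1", 100, 700)
        assert snp_frequency(peak, catalog([100, 400, 699, 700])) == pytest.approx(5.0)

    def test_half_open_boundaries(self):
        peak = GenomicInterval("chr1", 100, 200)
        assert snp_frequency(peak, catalog([99, 100, 199, 200])) == pytest.approx(20.0)


class TestSnpEnrichmentScore:
    def test_closed_form(self):
        # 30 SNPs in 10 kb of peaks; 3000 SNPs over a 10 Mb genome -> ES = 10
        asm = GenomeAssembly("g", {"chr1": 10_000_000})
        peaks = [GenomicInterval("chr1", 0, 10_000)]
        inside = list(range(0, 9000, 300))
        outside = list(range(10_500, 10_500 + (3000 - 30) * 3000, 3000))
        res = snp_enrichment_score(peaks, catalog(inside + outside), asm)
        assert res.es == pytest.approx(10.0)
        assert res.enriched

    def test_whole_genome_is_exactly_one(self):
        asm = GenomeAssembly("g", {"chr1": 100_000})
        res = snp_enrichment_score([GenomicInterval("chr1", 0, 100_000)],
                                   catalog(range(0, 100_000, 97)), asm)
        assert res.es == 1.0

    def test_boundary_at_one_point_five(self):
        asm = GenomeAssembly("g", {"chr1": 100_000})
        peaks = [GenomicInterval("chr1", 0, 10_000)]
        res = snp_enrichment_score(peaks, catalog(list(range(0, 10_000, 667)) +
                                                  list(range(10_000, 95_000, 1000))), asm)
        assert res.enriched == (res.es >= 1.5)

    def test_overlapping_peaks_merged_first(self):
        asm = GenomeAssembly("g", {"chr1": 100_000})
        snps = catalog([500])
        single = snp_enrichment_score([GenomicInterval("chr1", 0, 1000)], snps, asm)
        doubled = snp_enrichment_score(
            [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 200, 900)],
            snps, asm)
        assert doubled.es == single.es

    def test_uniform_placement_mean_near_one(self, rng):
        """Poisson-placed SNPs on 1% peak coverage: mean ES ~ 1, rare false flags."""
        asm = GenomeAssembly("g", {"chr1": 1_000_000})
        peaks = [GenomicInterval("chr1", s, s + 500) for s in range(0, 20_000 * 20, 20_000)]
        es = []
        for _ in range(300):
            pos = rng.integers(0, 1_000_000, size=2000)
            es.append(snp_enrichment_score(peaks, SnpCatalog(("chr1", int(p)) for p in pos), asm).es)
        es = np.array(es)
        assert 0.95 <= es.mean() <= 1.05
        assert (es >= 1.5).mean() <= 0.05


class TestEnrichmentTrend:
    def test_planted_decreasing_trend(self):
        asm = GenomeAssembly("g", {"chr1": 1_000_000})
        snps = catalog(list(range(0, 30_000, 30)) + list(range(500_000, 999_000, 1000)))
        stage_sets = {
            "s1": [GenomicInterval("chr1", 0, 30_000)],                       # dense
            "s2": [GenomicInterval("chr1", 0, 30_000),
                   GenomicInterval("chr1", 500_000, 700_000)],                # diluted
            "s3": [GenomicInterval("chr1", 500_000, 900_000)],                # background
        }
        trend = enrichment_trend(stage_sets, snps, asm)
        assert trend.slope < 0
        assert list(trend.band["stage"]) == ["s1", "s2", "s3"]

    def test_identical_sets_flat(self):
        asm = GenomeAssembly("g", {"chr1": 1_000_000})
        snps = catalog(range(0, 999_000, 500))
        sets = {s: [GenomicInterval("chr1", 0, 100_000)] for s in ("s1", "s2", "s3")}
        assert enrichment_trend(sets, snps, asm).slope == pytest.approx(0.0, abs=1e-9)

    def test_single_stage_rejected(self):
        asm = GenomeAssembly("g", {"chr1": 1_000_000})
        with pytest.raises(ValueError):
            enrichment_trend({"s1": [GenomicInterval("chr1", 0, 1000)]},
                             catalog([5]), asm)


class TestSnpAssociatedGenes:
    def setup_method(self):
        self.asm = GenomeAssembly("g", {"chr1": 1_000_000})
        self.genes = [
            GeneModel("g_prom", "chr1", "+", 100_000,
                      GenomicInterval("chr1", 100_000, 110_000)),
            GeneModel("g_distal", "chr1", "+", 300_000,
                      GenomicInterval("chr1", 300_000, 310_000)),
            GeneModel("g_silent", "chr1", "+", 500_000,
                      GenomicInterval("chr1", 500_000, 510_000)),
        ]
        self.peaks = {"d1": DHSPeak(GenomicInterval("chr1", 350_000, 350_300), "d1",
                                    {"s1": True})}
        self.snps = catalog([100_500, 350_100, 500_100])

    def run(self, expressed, promoter_open, pairs):
        return snp_associated_genes(self.genes, expressed, promoter_open, pairs,
                                    self.peaks, self.snps, self.asm)

    def test_open_promoter_with_snp(self):
        out = self.run({"g_prom": True}, {"g_prom": True}, {})
        assert out == {"g_prom"}

    def test_paired_open_distal_element_with_snp(self):
        out = self.run({"g_distal": True}, {}, {"g_distal": ["d1"]})
        assert out == {"g_distal"}

    def test_expression_required(self):
        out = self.run({"g_silent": False}, {"g_silent": True}, {})
        assert out == set()


class TestGoEnrichment:
    def test_closed_form_es(self):
        universe = {f"g{i}" for i in range(20_000)}
        term = GoTerm("T", frozenset(f"g{i}" for i in range(100)))
        inputs = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10_000, 10_045)}
        res = go_enrichment(inputs, [term], universe)[0]
        assert res.es == pytest.approx(20.0)

    def test_term_equal_to_universe_gives_one(self):
        universe = {f"g{i}" for i in range(100)}
        term = GoTerm("ALL", frozenset(universe))
        res = go_enrichment({"g1", "g2"}, [term], universe)[0]
        assert res.es == pytest.approx(1.0)

    def test_p_matches_brute_force_tail_sum(self):
        M, K, n, k = 5000, 100, 50, 5
        universe = {f"g{i}" for i in range(M)}
        term = GoTerm("T", frozenset(f"g{i}" for i in range(K)))
        inputs = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(1000, 1000 + n - k)}
        res = go_enrichment(inputs, [term], universe)[0]
        brute = sum(stats.hypergeom.pmf(j, M, K, n) for j in range(k, min(K, n) + 1))
        assert res.p_value == pytest.approx(brute, abs=1e-10)

    def test_bh_q_monotone_in_p_rank(self, rng):
        universe = {f"g{i}" for i in range(2000)}
        terms = [GoTerm(f"T{j}", frozenset(
            str(x) for x in (f"g{i}" for i in rng.choice(2000, 50, replace=False))))
            for j in range(12)]
        inputs = {f"g{i}" for i in range(60)}
        res = go_enrichment(inputs, terms, universe)
        ordered = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in res)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment(set(), [GoTerm("T", frozenset(["g1"]))], {"g1"})
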