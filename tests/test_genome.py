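import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromcompare.genome import (
    AssemblyError,
    CpGSite,
    DHSPeak,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    annotate_peaks,
    assign_dhs_category,
    classify_promoter_openness,
    derive_promoter,
    extend_and_merge,
    promoter_cpg_density,
    promoter_methylation_level,
)


def gene(tss, strand="+", chrom="chr1", gid="g1", body=None):
    body = body or GenomicInterval(chrom, tss if strand == "+" else tss - 10_000,
                                   tss + 10_000 if strand == "+" else tss)
    return GeneModel(gid, chrom, strand, tss, body)


class TestPromoter:
    @pytest.mark.parametrize(
        "tss,strand,expected",
        [
            (10_000, "+", (8_000, 12_000)),
            (10_000, "-", (8_000, 12_000)),  # strand-symmetric window
            (1_000, "+", (0, 3_000)),  # clipped at chromosome start
        ],
    )
    def test_window(self, assembly, tss, strand, expected):
        prom = derive_promoter(gene(tss, strand), assembly)
        assert (prom.start, prom.end) == expected

    def test_unknown_chromosome(self, assembly):
        with pytest.raises(AssemblyError):
            derive_promoter(gene(10_000, chrom="chrZ"), assembly)


class TestDhsCategories:
    def make(self, start, end, pid="p1"):
        return DHSPeak(GenomicInterval("chr1", start, end), pid)

    def test_promoter_precedence_and_partition(self, assembly):
        g = gene(10_000)  # promoter [8000,12000), body [10000,20000)
        peaks = [self.make(8_100, 8_300, "a"),      # promoter
                 self.make(13_000, 13_200, "b"),    # body, not promoter
                 self.make(300_000, 300_200, "c")]  # intergenic
        cats = annotate_peaks(peaks, [g], assembly)
        assert cats == {"a": "promoter", "b": "gene_body", "c": "intergenic"}

    def test_no_genes_on_chromosome(self, assembly):
        peak = DHSPeak(GenomicInterval("chr2", 1000, 1200), "p")
        assert assign_dhs_category(peak, [gene(10_000)], assembly) == "intergenic"

    def test_every_peak_gets_exactly_one_label(self, assembly, rng):
        genes = [gene(int(t), gid=f"g{i}") for i, t in
                 enumerate(rng.integers(20_000, 900_000, size=12))]
        peaks = [DHSPeak(GenomicInterval("chr1", int(s), int(s) + 200), f"p{i}")
                 for i, s in enumerate(rng.integers(0, 990_000, size=100))]
        cats = annotate_peaks(peaks, genes, assembly)
        assert set(cats) == {p.peak_id for p in peaks}
        assert set(cats.values()) <= {"promoter", "gene_body", "intergenic"}


class TestExtendAndMerge:
    def test_pad_and_union(self, assembly):
        ivs = [GenomicInterval("chr1", 1000, 1200), GenomicInterval("chr1", 1900, 2100)]
        assert extend_and_merge(ivs, assembly, 500) == [GenomicInterval("chr1", 500, 2600)]

    def test_single_peak(self, assembly):
        out = extend_and_merge([GenomicInterval("chr1", 5000, 5100)], assembly, 500)
        assert out == [GenomicInterval("chr1", 4500, 5600)]

    def test_disjoint_stay_separate(self, assembly):
        ivs = [GenomicInterval("chr1", 1000, 1100), GenomicInterval("chr1", 11_000, 11_100)]
        assert len(extend_and_merge(ivs, assembly, 500)) == 2

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 300)),
                    min_size=1, max_size=20))
    def test_matches_base_pair_set_union(self, spans):
        assembly = GenomeAssembly("t", {"c": 10_000})
        ivs = [GenomicInterval("c", s, s + l) for s, l in spans]
        merged = extend_and_merge(ivs, assembly, 50)
        # brute force: union of padded base sets
        expected = set()
        for s, l in spans:
            expected.update(range(max(0, s - 50), min(10_000, s + l + 50)))
        got = set()
        for iv in merged:
            assert not any(iv != o and iv.overlaps(o) for o in merged)
            got.update(range(iv.start, iv.end))
        assert got == expected


class TestCpGAndMethylation:
    def test_density_formula(self):
        prom = GenomicInterval("chr1", 8000, 12_000)
        assert promoter_cpg_density(prom, range(8000, 12_000, 20)) == 5.0
        assert promoter_cpg_density(prom, []) == 0.0
        assert promoter_cpg_density(prom, list(range(9000, 9120))) == 3.0

    def test_density_ignores_outside_sites(self):
        prom = GenomicInterval("chr1", 100, 200)
        assert promoter_cpg_density(prom, [50, 100, 150, 199, 200, 250]) == 3.0

    def test_methylation_mean_of_site_ratios(self):
        prom = GenomicInterval("chr1", 0, 1000)
        sites = [CpGSite("chr1", 10, 3, 4), CpGSite("chr1", 20, 1, 4)]
        assert promoter_methylation_level(prom, sites) == pytest.approx(0.5)
        sites = [CpGSite("chr1", 10, 5, 5), CpGSite("chr1", 20, 0, 10),
                 CpGSite("chr1", 30, 2, 4)]
        assert promoter_methylation_level(prom, sites) == pytest.approx(0.5)

    def test_no_covered_sites_is_undefined_not_zero(self):
        prom = GenomicInterval("chr1", 0, 1000)
        assert promoter_methylation_level(prom, []) is None
        uncovered = [CpGSite("chr1", 10, 0, 0)]
        assert promoter_methylation_level(prom, uncovered) is None

    def test_level_in_unit_interval(self, rng):
        prom = GenomicInterval("chr1", 0, 10_000)
        sites = [CpGSite("chr1", int(p), int(m), int(m) + int(u))
                 for p, m, u in zip(rng.integers(0, 10_000, 50),
                                    rng.integers(0, 20, 50), rng.integers(1, 20, 50))]
        ml = promoter_methylation_level(prom, sites)
        assert 0.0 <= ml <= 1.0


class TestPromoterOpenness:
    def peak(self, start, end, open_stages, pid="p"):
        return DHSPeak(GenomicInterval("chr1", start, end), pid,
                       {s: (s in open_stages) for s in ("s1", "s2", "s3")})

    def test_openness_follows_overlapping_peak_stages(self):
        prom = GenomicInterval("chr1", 8000, 12_000)
        out = classify_promoter_openness(prom, [self.peak(9000, 9200, {"s1", "s3"})],
                                         ["s1", "s2", "s3"])
        assert out == {"s1": True, "s2": False, "s3": True}

    def test_no_overlap_means_closed(self):
        prom = GenomicInterval("chr1", 8000, 12_000)
        out = classify_promoter_openness(prom, [self.peak(20_000, 20_200, {"s1"})],
                                         ["s1", "s2", "s3"])
        assert not any(out.values())

    def test_union_over_peaks(self):
        prom = GenomicInterval("chr1", 8000, 12_000)
        peaks = [self.peak(8100, 8200, {"s1"}, "a"), self.peak(11_000, 11_500, {"s3"}, "b")]
        out = classify_promoter_openness(prom, peaks, ["s1", "s2", "s3"])
        assert out == {"s1": True, "s2": False, "s3": True}
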