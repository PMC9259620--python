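import numpy as np
import pytest

from chromcompare.crossmap import (
    ChainBlock,
    ChainMap,
    lift_interval,
    liftability_classes,
    newly_emerged,
    promoter_conservation,
    reciprocal_conserved_pairs,
    species_specific_open,
    synteny_check,
)
from chromcompare.genome import DHSPeak, GeneModel, GenomeAssembly, GenomicInterval


def identity_chain(length=1_000_000, chrom_a="chrA", chrom_b="chrB", cid=1):
    return ChainMap([ChainBlock(chrom_a, 0, length, chrom_b, 0, length, "+", cid)])


def iv(s, e, chrom="chrA"):
    return GenomicInterval(chrom, s, e)


class TestLiftInterval:
    def test_identity_round_trip(self, rng):
        chain = identity_chain()
        back = chain.invert()
        for s in rng.integers(0, 999_000, size=200):
            q = iv(int(s), int(s) + 500)
            out = lift_interval(q, chain)
            assert out.status == "unique" and out.mapped_fraction == 1.0
            again = lift_interval(out.target, back)
            assert (again.target.start, again.target.end) == (q.start, q.end)

    def test_deleted_region_unmapped(self):
        chain = ChainMap([
            ChainBlock("chrA", 0, 1000, "chrB", 0, 1000, "+", 1),
            ChainBlock("chrA", 2000, 3000, "chrB", 1000, 2000, "+", 1),
        ])
        assert lift_interval(iv(1200, 1500), chain).status == "unmapped"
        # partial overlap below the mapped-fraction floor is unmapped too
        assert lift_interval(iv(900, 1900), chain).status == "unmapped"

    def test_two_chains_give_multiple(self):
        chain = ChainMap([
            ChainBlock("chrA", 0, 1000, "chrB", 0, 1000, "+", 1),
            ChainBlock("chrA", 0, 1000, "chrB", 5000, 6000, "+", 2),
        ])
        assert lift_interval(iv(100, 300), chain).status == "multiple"

    def test_inversion_preserves_length_and_flips(self):
        chain = ChainMap([ChainBlock("chrA", 1000, 2000, "chrB", 7000, 8000, "-", 1)])
        out = lift_interval(iv(1000, 1100), chain)
        assert out.status == "unique"
        assert out.target.length == 100
        # the first 100 bases of the source map to the last 100 of the target
        assert (out.target.start, out.target.end) == (7900, 8000)

    def test_span_across_gap_within_one_chain(self):
        chain = ChainMap([
            ChainBlock("chrA", 0, 1000, "chrB", 0, 1000, "+", 1),
            ChainBlock("chrA", 1010, 2000, "chrB", 1500, 2490, "+", 1),
        ])
        out = lift_interval(iv(900, 1100), chain, min_mapped=0.9)
        assert out.status == "unique"
        assert (out.target.start, out.target.end) == (900, 1590)


class TestLiftabilityClasses:
    def test_three_way_classification(self):
        chain = ChainMap([
            ChainBlock("chrA", 0, 10_000, "chrB", 0, 10_000, "+", 1),
        ])
        peaks = [
            DHSPeak(iv(1000, 1300), "overlaps"),
            DHSPeak(iv(5000, 5300), "no_overlap"),
            DHSPeak(iv(50_000, 50_300), "unmappable"),
        ]
        target_ext = [GenomicInterval("chrB", 900, 1500)]
        classes, _ = liftability_classes(peaks, chain, target_ext)
        assert classes == {
            "overlaps": "maps_and_overlaps",
            "no_overlap": "maps_no_overlap",
            "unmappable": "unmappable",
        }


def two_species_fixture():
    """Identity-mapped genomes with orthologous flanking genes."""
    n = 1_000_000
    asm_a = GenomeAssembly("A", {"chrA": n})
    asm_b = GenomeAssembly("B", {"chrB": n})
    chain = identity_chain(n)
    genes_a, genes_b = [], []
    for i, tss in enumerate(range(100_000, 900_000, 100_000)):
        genes_a.append(GeneModel(f"gA{i}", "chrA", "+", tss,
                                 GenomicInterval("chrA", tss, tss + 10_000), f"gB{i}"))
        genes_b.append(GeneModel(f"gB{i}", "chrB", "+", tss,
                                 GenomicInterval("chrB", tss, tss + 10_000), f"gA{i}"))
    return asm_a, asm_b, chain, genes_a, genes_b


class TestReciprocalConservation:
    def run(self, peak_a_span, peak_b_span, min_frac=0.5, pad=0):
        asm_a, asm_b, chain, genes_a, genes_b = two_species_fixture()
        peaks_a = [DHSPeak(iv(*peak_a_span), "a1")]
        peaks_b = [DHSPeak(GenomicInterval("chrB", *peak_b_span), "b1")]
        return reciprocal_conserved_pairs(
            peaks_a, peaks_b, chain, chain.invert(), genes_a, genes_b,
            asm_a, asm_b, min_frac=min_frac, pad=pad,
        )

    def test_reciprocal_overlap_pairs(self):
        # lifted a = [150000,150600); b = [150100,151000): overlap 500/600
        assert self.run((150_000, 150_600), (150_100, 151_000)) == [("a1", "b1")]

    def test_below_threshold_rejected(self):
        # overlap 200/600 = 0.33
        assert self.run((150_000, 150_600), (150_400, 151_300)) == []

    def test_exactly_half_rejected_strict(self):
        # overlap 300/600 = 0.5 exactly -> strict > rejects
        assert self.run((150_000, 150_600), (150_300, 151_200)) == []

    def test_just_above_half_accepted(self):
        # overlap 301/600 > 0.5
        assert self.run((150_000, 150_600), (150_299, 151_199)) == []  # reciprocal: 301/900 < 0.5
        assert self.run((150_000, 150_600), (150_299, 150_899)) == [("a1", "b1")]

    def test_identity_peak_sets_pair_with_themselves(self, rng):
        asm_a, asm_b, chain, genes_a, genes_b = two_species_fixture()
        starts = [10_000 + 24_000 * i + int(j) for i, j in
                  enumerate(rng.integers(0, 10_000, size=40))]
        peaks_a = [DHSPeak(iv(s, s + 300), f"p{i}") for i, s in enumerate(starts)]
        peaks_b = [DHSPeak(GenomicInterval("chrB", p.interval.start, p.interval.end),
                           f"q{i}") for i, p in enumerate(peaks_a)]
        pairs = reciprocal_conserved_pairs(
            peaks_a, peaks_b, chain, chain.invert(), genes_a, genes_b, asm_a, asm_b)
        assert set(pairs) == {(f"p{i}", f"q{i}") for i in range(len(peaks_a))}


class TestSynteny:
    def test_matching_flanks_pass(self):
        _, _, _, genes_a, genes_b = two_species_fixture()
        assert synteny_check(iv(150_000, 150_300),
                             GenomicInterval("chrB", 150_000, 150_300),
                             genes_a, genes_b)

    def test_translocated_region_fails(self):
        _, _, _, genes_a, genes_b = two_species_fixture()
        # same element, but the lifted locus sits next to different orthologs
        assert not synteny_check(iv(150_000, 150_300),
                                 GenomicInterval("chrB", 650_000, 650_300),
                                 genes_a, genes_b)

    def test_single_flank_suffices(self):
        _, _, _, genes_a, genes_b = two_species_fixture()
        # before the first gene there is only a downstream flank
        assert synteny_check(iv(50_000, 50_300),
                             GenomicInterval("chrB", 50_000, 50_300),
                             genes_a, genes_b)

    def test_translocation_excludes_reciprocal_pair(self):
        """A planted translocation passes reciprocal overlap but fails synteny."""
        n = 1_000_000
        asm_a = GenomeAssembly("A", {"chrA": n})
        asm_b = GenomeAssembly("B", {"chrB": n})
        # [150000,160000) maps to [650000,660000): a translocated segment
        chain = ChainMap([
            ChainBlock("chrA", 0, 150_000, "chrB", 0, 150_000, "+", 1),
            ChainBlock("chrA", 150_000, 160_000, "chrB", 650_000, 660_000, "+", 2),
        ])
        _, _, _, genes_a, genes_b = two_species_fixture()
        peaks_a = [DHSPeak(iv(151_000, 151_300), "a1")]
        peaks_b = [DHSPeak(GenomicInterval("chrB", 651_000, 651_300), "b1")]
        args = (peaks_a, peaks_b, chain, chain.invert(), genes_a, genes_b, asm_a, asm_b)
        assert reciprocal_conserved_pairs(*args, require_synteny=False) == [("a1", "b1")]
        assert reciprocal_conserved_pairs(*args) == []


class TestSpeciesSpecificOpen:
    def peak(self, pid, n_open, n_stages=6):
        flags = {f"s{i}": i < n_open for i in range(n_stages)}
        return DHSPeak(iv(1000, 1300), pid, flags)

    def test_stage_thresholds(self):
        peaks = [self.peak("two", 2), self.peak("one", 1)]
        classes = {"two": "maps_no_overlap", "one": "maps_no_overlap"}
        assert species_specific_open(peaks, classes, min_open_stages=2) == {"two"}
        assert species_specific_open(peaks, classes, min_open_stages=1) == {"two", "one"}

    def test_only_class_two_eligible(self):
        peaks = [self.peak("conserved_peak", 6)]
        assert species_specific_open(peaks, {"conserved_peak": "maps_and_overlaps"}, 1) == set()


class TestNewlyEmerged:
    def test_unmapped_in_all_outgroups(self):
        gapped = ChainMap([
            ChainBlock("chrA", 0, 1000, "og", 0, 1000, "+", 1),
            ChainBlock("chrA", 2000, 3000, "og", 1000, 2000, "+", 1),
        ])
        full = identity_chain(3000)
        inside_gap = DHSPeak(iv(1200, 1500), "gap")
        mapped = DHSPeak(iv(100, 400), "ok")
        out = newly_emerged([inside_gap, mapped],
                            {"og1": gapped, "og2": gapped, "og3": gapped})
        assert out == {"gap"}
        # mapping in a single outgroup rescues the element
        out = newly_emerged([inside_gap], {"og1": gapped, "og2": full})
        assert out == set()

    def test_requires_outgroups(self):
        with pytest.raises(ValueError):
            newly_emerged([], {})


class TestPromoterConservation:
    def flags(self, n_open, n):
        return {f"s{i}": i < n_open for i in range(n)}

    @pytest.mark.parametrize(
        "open_a,open_b,expected",
        [
            ((6, 6), (0, 3), "a_specific_open"),
            ((0, 6), (3, 3), "b_specific_open"),
            ((6, 6), (3, 3), "conserved_open"),
            ((5, 6), (0, 3), "other"),  # "each stage" is strict
            ((6, 6), (1, 3), "other"),
        ],
    )
    def test_classes(self, open_a, open_b, expected):
        assert promoter_conservation(
            self.flags(open_a[0], open_a[1]), self.flags(open_b[0], open_b[1])
        ) == expected
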