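import numpy as np
import pandas as pd
import pytest

from chromcompare.genome import DHSPeak, GeneModel, GenomeAssembly, GenomicInterval
from chromcompare.pairing import (
    InteractionRecord,
    correlate_pair,
    enumerate_candidates,
    hic_support,
    pair_elements,
    stage_masked_pairing,
)


@pytest.fixture
def big_assembly():
    return GenomeAssembly("toy", {"chr1": 10_000_000})


def make_gene(tss, gid="g1", chrom="chr1"):
    return GeneModel(gid, chrom, "+", tss, GenomicInterval(chrom, tss, tss + 10_000))


def make_peak(start, pid, chrom="chr1"):
    return DHSPeak(GenomicInterval(chrom, start, start + 300), pid)


class TestCandidateWindow:
    def test_distal_window_inclusion(self, big_assembly):
        g = make_gene(5_000_000)  # promoter [4998000, 5002000)
        peaks = [
            make_peak(4_100_000, "in_900kb_upstream"),
            make_peak(6_300_000, "out_1p3mb"),
            make_peak(4_999_000, "in_promoter"),
            make_peak(5_999_800, "at_downstream_edge"),
        ]
        ids = {p.peak_id for p in enumerate_candidates(g, peaks, big_assembly)}
        assert "in_900kb_upstream" in ids
        assert "in_promoter" in ids
        assert "at_downstream_edge" in ids
        assert "out_1p3mb" not in ids

    def test_window_clipped_at_chromosome_start(self, big_assembly):
        g = make_gene(100_000)
        assert enumerate_candidates(g, [make_peak(50_000, "p")], big_assembly)


class TestCorrelatePair:
    def test_proportional_signals_pass(self):
        sig = np.array([1, 2, 3, 4, 5, 6.0])
        c = correlate_pair(sig, 2 * sig)
        assert c.pearson_r == pytest.approx(1.0)
        assert c.p_value == 0.0
        assert c.passed

    def test_anticorrelated_not_passed(self):
        sig = np.array([1, 2, 3, 4, 5, 6.0])
        c = correlate_pair(sig, -sig)
        assert c.pearson_r == pytest.approx(-1.0)
        assert not c.passed

    def test_p_value_matches_t_tail(self, rng):
        # construct vectors with r = 0.9 exactly: n = 6, t = r*sqrt(4/(1-r^2))
        # = 4.1295 on 4 df -> two-sided p = 0.0145
        x = rng.normal(size=6)
        z = rng.normal(size=6)
        xs = (x - x.mean()) / np.std(x)
        zs = z - z.mean() - np.dot(z - z.mean(), xs) / np.dot(xs, xs) * xs
        zs /= np.std(zs)
        y = 0.9 * xs + np.sqrt(1 - 0.81) * zs
        c = correlate_pair(x, y)
        assert c.pearson_r == pytest.approx(0.9, abs=1e-12)
        assert c.p_value == pytest.approx(0.0145, abs=5e-4)
        assert c.passed

    def test_zero_variance_not_passed(self):
        c = correlate_pair([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(c.pearson_r)
        assert not c.passed

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=8)
        assert correlate_pair(x, x).pearson_r == pytest.approx(1.0)


class TestPairElementsOracle:
    def _brute_force(self, genes, peaks, acc, expr, assembly):
        """Direct per-pair Pearson + exact t tail over every in-window combo."""
        from scipy import stats

        out = set()
        for g in genes:
            prom_lo, prom_hi = g.tss - 2000, g.tss + 2000
            lo, hi = prom_lo - 998_000, prom_hi + 998_000
            e = expr.loc[g.gene_id].to_numpy()
            for p in peaks:
                if p.interval.chrom != g.chrom:
                    continue
                if p.interval.end <= max(0, lo) or p.interval.start >= hi:
                    continue
                s = acc.loc[p.peak_id].to_numpy()
                if np.std(s) == 0 or np.std(e) == 0:
                    continue
                r, pv = stats.pearsonr(s, e)
                if r > 0.8 and pv < 0.05:
                    out.add((p.peak_id, g.gene_id))
        return out

    def test_set_identical_to_brute_force(self, big_assembly, rng):
        genes = [make_gene(int(t), f"g{i}") for i, t in
                 enumerate(np.linspace(50_000, 9_900_000, 200))]
        peaks = [make_peak(int(s), f"p{i}") for i, s in
                 enumerate(rng.integers(0, 9_990_000, size=500))]
        acc = pd.DataFrame(rng.normal(size=(500, 6)),
                           index=[p.peak_id for p in peaks])
        expr = pd.DataFrame(rng.normal(size=(200, 6)),
                            index=[g.gene_id for g in genes])
        got = {(p.peak_id, p.gene_id)
               for p in pair_elements(genes, peaks, acc, expr, big_assembly)}
        assert got == self._brute_force(genes, peaks, acc, expr, big_assembly)

    def test_out_of_window_never_paired(self, big_assembly):
        g = make_gene(1_000_000)
        far = make_peak(8_000_000, "far")
        acc = pd.DataFrame([[1, 2, 3, 4, 5, 6.0]], index=["far"])
        expr = pd.DataFrame([[1, 2, 3, 4, 5, 6.0]], index=["g1"])
        assert pair_elements([g], [far], acc, expr, big_assembly) == []


class TestStageMaskedPairing:
    def build(self):
        gene = make_gene(5_000_000)
        peaks = [make_peak(4_500_000, "early_elem"),
                 make_peak(5_500_000, "late_elem"),
                 make_peak(5_200_000, "both_elem")]
        acc = pd.DataFrame(
            {
                "early_elem": [5.0, 0.2, 0.1, 0.2, 0.3, 0.2],
                "late_elem": [0.2, 0.1, 0.3, 0.2, 0.1, 5.0],
                "both_elem": [5.0, 0.2, 0.2, 0.1, 0.2, 5.0],
            }
        ).T
        expr = pd.DataFrame({"g1": [5.0, 0.2, 0.2, 0.1, 0.2, 5.0]}).T
        return gene, peaks, acc, expr

    def test_early_late_sets(self, big_assembly):
        gene, peaks, acc, expr = self.build()
        early, late = stage_masked_pairing(gene, peaks, acc, expr, big_assembly)
        early_ids = {p.peak_id for p in early}
        late_ids = {p.peak_id for p in late}
        assert "early_elem" in early_ids and "early_elem" not in late_ids
        assert "late_elem" in late_ids and "late_elem" not in early_ids
        # an element active at both flanks appears in both sets
        assert "both_elem" in early_ids and "both_elem" in late_ids
        assert all(p.phase == "early" for p in early)

    def test_monotone_gene_rejected(self, big_assembly):
        gene, peaks, acc, _ = self.build()
        expr = pd.DataFrame({"g1": [0.0, 1, 2, 3, 4, 5.0]}).T
        with pytest.raises(ValueError):
            stage_masked_pairing(gene, peaks, acc, expr, big_assembly)


class TestHicSupport:
    def iv(self, s, e):
        return GenomicInterval("chr1", s, e)

    def test_opposite_anchor_overlap_supports(self):
        rec = InteractionRecord(self.iv(1000, 2000), self.iv(9000, 10_000))
        assert hic_support(self.iv(1500, 1600), self.iv(9100, 9200), [rec])
        assert hic_support(self.iv(9100, 9200), self.iv(1500, 1600), [rec])

    def test_same_anchor_is_not_support(self):
        rec = InteractionRecord(self.iv(1000, 2000), self.iv(9000, 10_000))
        assert not hic_support(self.iv(1100, 1200), self.iv(1500, 1600), [rec])

    def test_no_record_no_support(self):
        assert not hic_support(self.iv(0, 10), self.iv(20, 30), [])
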