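"""SNP frequency/enrichment and GO term enrichment.

SNP frequency of one peak is SNPs per kb.  The enrichment score of a peak set
is the ratio of SNP density inside the (merged) peaks to the genome-wide SNP
density; a score of at least 1.5 counts as enriched.  GO enrichment uses the
analogous ratio of the term's share among the input genes to its share of the
genome, with an upper-tail hypergeometric p-value and Benjamini-Hochberg
adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import (
    DHSPeak,
    GeneModel,
    GenomicInterval,
    GenomeAssembly,
    derive_promoter,
    extend_and_merge,
)

__all__ = [
    "SnpCatalog",
    "GoTerm",
    "EnrichmentResult",
    "TrendResult",
    "snp_frequency",
    "snp_enrichment_score",
    "enrichment_trend",
    "snp_associated_genes",
    "go_enrichment",
]

ES_ENRICHED_MIN = 1.5


class SnpCatalog:
    """Unique SNP positions, indexed per chromosome for range counting."""

    def __init__(self, positions: Iterable[tuple[str, int]], source: str = ""):
        self.source = source
        by_chrom: dict[str, set[int]] = {}
        for chrom, pos in positions:
            by_chrom.setdefault(chrom, set()).add(int(pos))
        self._sorted = {
            chrom: np.array(sorted(posset), dtype=np.int64)
            for chrom, posset in by_chrom.items()
        }

    @property
    def total(self) -> int:
        return sum(arr.size for arr in self._sorted.values())

    def count_in(self, iv: GenomicInterval) -> int:
        """SNPs with start <= position < end (half-open, like the intervals)."""
        arr = self._sorted.get(iv.chrom)
        if arr is None:
            return 0
        return int(
            np.searchsorted(arr, iv.end, side="left")
            - np.searchsorted(arr, iv.start, side="left")
        )

    def positions(self) -> Iterable[tuple[str, int]]:
        for chrom in sorted(self._sorted):
            for pos in self._sorted[chrom]:
                yield chrom, int(pos)


@dataclass(frozen=True)
class GoTerm:
    term_id: str
    member_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"GO term {self.term_id} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    es: float
    enriched: bool
    p_value: float | None = None
    q_value: float | None = None


@dataclass(frozen=True)
class TrendResult:
    es_by_stage: dict[str, float]
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    band: pd.DataFrame  # fitted value with lower/upper 95% bounds per stage


def snp_frequency(peak: GenomicInterval, snps: SnpCatalog) -> float:
    """SNPs per kb of one peak: count / (length / 1000)."""
    return snps.count_in(peak) / (peak.length / 1000)


def snp_enrichment_score(
    peaks: Sequence[GenomicInterval],
    snps: SnpCatalog,
    assembly: GenomeAssembly,
    label: str = "",
) -> EnrichmentResult:
    """Observed vs expected SNP density of a peak set.

    ES = (SNPs in peaks / total peak length) / (total SNPs / genome length).
    Peaks are merged first so no base or SNP is double-counted.  Enriched iff
    ES >= 1.5.
    """
    merged = extend_and_merge(peaks, assembly, pad=0)
    peak_len = sum(iv.length for iv in merged)
    if peak_len == 0:
        raise ValueError("peak set has zero total length")
    if snps.total == 0:
        raise ValueError("empty SNP catalog")
    in_peaks = sum(snps.count_in(iv) for iv in merged)
    es = (in_peaks / peak_len) / (snps.total / assembly.total_length)
    return EnrichmentResult(label, float(es), bool(es >= ES_ENRICHED_MIN))


def enrichment_trend(
    stage_peak_sets: Mapping[str, Sequence[GenomicInterval]],
    snps: SnpCatalog,
    assembly: GenomeAssembly,
) -> TrendResult:
    """Per-stage enrichment scores with an OLS trend and 95% confidence band."""
    import statsmodels.api as sm

    if len(stage_peak_sets) < 2:
        raise ValueError("trend needs at least two stages")
    stages = list(stage_peak_sets)
    es = {
        s: snp_enrichment_score(stage_peak_sets[s], snps, assembly, label=s).es
        for s in stages
    }
    x = np.arange(len(stages), dtype=float)
    y = np.array([es[s] for s in stages])
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    band = pd.DataFrame(
        {
            "stage": stages,
            "fitted": pred["mean"].to_numpy(),
            "lower": pred["mean_ci_lower"].to_numpy(),
            "upper": pred["mean_ci_upper"].to_numpy(),
        }
    )
    ci = fit.conf_int(alpha=0.05)
    return TrendResult(
        es_by_stage=es,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        band=band,
    )


def snp_associated_genes(
    genes: Sequence[GeneModel],
    expressed: Mapping[str, bool],
    promoter_open: Mapping[str, bool],
    pairs_by_gene: Mapping[str, Sequence[str]],
    peaks_by_id: Mapping[str, DHSPeak],
    snps: SnpCatalog,
    assembly: GenomeAssembly,
    promoter_flank: int = 2000,
) -> set[str]:
    """Genes whose open promoter or paired open distal element harbors a SNP.

    A gene qualifies when it is expressed AND either (1) its promoter is open
    and contains a catalog SNP, or (2) at least one of its paired elements is
    open at some stage and contains a catalog SNP.
    """
    out: set[str] = set()
    for gene in genes:
        if not expressed.get(gene.gene_id, False):
            continue
        promoter = derive_promoter(gene, assembly, promoter_flank)
        if promoter_open.get(gene.gene_id, False) and snps.count_in(promoter) > 0:
            out.add(gene.gene_id)
            continue
        for pid in pairs_by_gene.get(gene.gene_id, ()):
            peak = peaks_by_id.get(pid)
            if (
                peak is not None
                and peak.n_open_stages > 0
                and snps.count_in(peak.interval) > 0
            ):
                out.add(gene.gene_id)
                break
    return out


def go_enrichment(
    input_genes: set[str],
    terms: Sequence[GoTerm],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Per-term enrichment of an input gene list against the genome background.

    ES = (members among input / input size) / (term size / genome size);
    p is the upper-tail (accumulative) hypergeometric probability of at least
    the observed member count; q applies Benjamini-Hochberg across terms.
    """
    if not input_genes:
        raise ValueError("empty input gene set")
    if not input_genes <= universe:
        raise ValueError("input genes must be drawn from the universe")
    n_universe = len(universe)
    n_input = len(input_genes)
    results = []
    pvals = []
    for term in terms:
        members = term.member_genes & universe
        k = len(members & input_genes)
        es = (k / n_input) / (len(members) / n_universe) if members else 0.0
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(members), n_input))
        pvals.append(p)
        results.append((term.term_id, es, p))
    _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(tid, float(es), es >= ES_ENRICHED_MIN, p, float(q))
        for (tid, es, p), q in zip(results, qvals)
    ]
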