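"""Coordinate conventions, gene/promoter geometry and promoter-level summaries.

All coordinates are 0-based half-open (BED-native).  A promoter is the
strand-symmetric window ``[TSS - flank, TSS + flank)`` (default flank 2 kb),
clipped to the chromosome.  DHS annotation follows the usual precedence rule:
a peak overlapping any promoter is a promoter DHS; otherwise a peak
overlapping any gene body is a gene-body DHS; everything else is intergenic.
Overlap means at least one shared base pair unless a fractional threshold is
stated explicitly (see :mod:`chromcompare.crossmap`).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomeAssembly",
    "GenomicInterval",
    "GeneModel",
    "DHSPeak",
    "CpGSite",
    "AssemblyError",
    "derive_promoter",
    "assign_dhs_category",
    "annotate_peaks",
    "extend_and_merge",
    "promoter_cpg_density",
    "promoter_methylation_level",
    "classify_promoter_openness",
]


class AssemblyError(ValueError):
    """Raised for coordinates referencing unknown chromosomes or invalid spans."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_position(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome name -> length table; the coordinate universe of one species."""

    name: str
    chromosomes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    @property
    def total_length(self) -> int:
        """Whole-genome length: the sum of all chromosome lengths."""
        return sum(self.chromosomes.values())

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise AssemblyError(
                f"chromosome {chrom!r} not in assembly {self.name!r}"
            ) from None

    def clip(self, iv: GenomicInterval) -> GenomicInterval:
        length = self.chrom_length(iv.chrom)
        return GenomicInterval(iv.chrom, max(0, iv.start), min(length, iv.end))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval
    ortholog_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.body.start <= self.tss <= self.body.end:
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")


@dataclass
class DHSPeak:
    """Open-chromatin peak with per-stage open flags and log2 FPKM signal."""

    interval: GenomicInterval
    peak_id: str
    open_by_stage: dict[str, bool] = field(default_factory=dict)
    signal_by_stage: dict[str, float] = field(default_factory=dict)

    @property
    def n_open_stages(self) -> int:
        return sum(bool(v) for v in self.open_by_stage.values())


@dataclass(frozen=True)
class CpGSite:
    chrom: str
    position: int
    methylated_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.methylated_reads <= self.total_reads:
            raise ValueError(
                f"CpG {self.chrom}:{self.position}: methylated > total reads"
            )

    @property
    def methylation_level(self) -> float:
        return self.methylated_reads / self.total_reads


def derive_promoter(
    gene: GeneModel, assembly: GenomeAssembly, flank: int = 2000
) -> GenomicInterval:
    """Promoter window ``[TSS - flank, TSS + flank)`` clipped to the chromosome.

    The window is strand-symmetric, so the gene's strand does not affect it.
    """
    return assembly.clip(
        GenomicInterval(gene.chrom, max(0, gene.tss - flank), gene.tss + flank)
    )


class _IntervalIndex:
    """Sorted per-chromosome interval lookup (max-end prefix trick)."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        tmp: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in tmp.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            starts = [iv.start for iv in ivs]
            ends = [iv.end for iv in ivs]
            max_end = []
            running = 0
            for e in ends:
                running = max(running, e)
                max_end.append(running)
            self._by_chrom[chrom] = (starts, ends, max_end)

    def any_overlap(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, _ends, max_end = entry
        hi = bisect_right(starts, iv.end - 1)
        return hi > 0 and max_end[hi - 1] > iv.start


def assign_dhs_category(
    dhs: DHSPeak,
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    promoter_flank: int = 2000,
) -> str:
    """Label one peak as ``promoter``, ``gene_body`` or ``intergenic``."""
    return annotate_peaks([dhs], genes, assembly, promoter_flank)[dhs.peak_id]


def annotate_peaks(
    peaks: Sequence[DHSPeak],
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    promoter_flank: int = 2000,
) -> dict[str, str]:
    """Categorize every peak; promoters take precedence over gene bodies."""
    promoters = _IntervalIndex(
        derive_promoter(g, assembly, promoter_flank) for g in genes
    )
    bodies = _IntervalIndex(g.body for g in genes)
    out: dict[str, str] = {}
    for peak in peaks:
        if promoters.any_overlap(peak.interval):
            out[peak.peak_id] = "promoter"
        elif bodies.any_overlap(peak.interval):
            out[peak.peak_id] = "gene_body"
        else:
            out[peak.peak_id] = "intergenic"
    return out


def extend_and_merge(
    intervals: Iterable[GenomicInterval | DHSPeak],
    assembly: GenomeAssembly,
    pad: int = 500,
) -> list[GenomicInterval]:
    """Pad every interval by ``pad`` bp on both sides, clip, and merge overlaps.

    Book-ended padded intervals (touching ends) are merged as well.  Output is
    sorted by (chromosome, start) and pairwise disjoint.
    """
    padded = []
    for item in intervals:
        iv = item.interval if isinstance(item, DHSPeak) else item
        padded.append(
            assembly.clip(
                GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad)
            )
        )
    padded.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in padded:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def promoter_cpg_density(
    promoter: GenomicInterval, cpg_positions: Iterable[int]
) -> float:
    """Average number of CpG sites per 100 bp of promoter.

    ``cpg_positions`` are positions on the promoter's chromosome; only those
    inside the promoter window are counted.
    """
    if promoter.length <= 0:
        raise ValueError("zero-length promoter")
    n = sum(1 for p in cpg_positions if promoter.start <= p < promoter.end)
    return n / (promoter.length / 100)


def promoter_methylation_level(
    promoter: GenomicInterval, sites: Iterable[CpGSite]
) -> float | None:
    """Mean per-site methylation ratio over covered CpGs inside the promoter.

    Sites with zero total reads are ignored.  Returns ``None`` (not 0) when no
    covered site falls in the window: missing data is not unmethylated.
    """
    levels = [
        s.methylation_level
        for s in sites
        if s.total_reads > 0 and promoter.contains_position(s.chrom, s.position)
    ]
    if not levels:
        return None
    return sum(levels) / len(levels)


def classify_promoter_openness(
    promoter: GenomicInterval, peaks: Iterable[DHSPeak], stages: Sequence[str]
) -> dict[str, bool]:
    """Open at a stage iff the promoter overlaps >=1 peak open at that stage."""
    open_at = {s: False for s in stages}
    for peak in peaks:
        if promoter.overlaps(peak.interval):
            for s in stages:
                if peak.open_by_stage.get(s, False):
                    open_at[s] = True
    return open_at
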