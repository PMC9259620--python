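"""Chain-based coordinate lifting and cross-species DHS conservation calls.

A chain map is an ordered set of ungapped aligned blocks relating two
assemblies; lifting projects an interval through the blocks of each chain.
Peaks that project through more than one chain are ambiguous ("multiple")
and removed from conservation analysis, mirroring how liftOver hits with
multiple targets are discarded.

Conservation logic between species A and B:

* class 1 (``maps_and_overlaps``): the peak lifts uniquely and overlaps an
  extended (+-500 bp, merged) peak of the other species;
* class 2 (``maps_no_overlap``): lifts uniquely, no overlapping peak;
* class 3 (``unmappable``): cannot be lifted.

A conserved pair requires reciprocal overlap: the lifted A peak must overlap
the (extended) B peak with fraction > 0.5 of the lifted interval, the lifted
B peak must overlap the A peak the same way, and the flanking orthologous
genes must be consistent (synteny).  Class-2 peaks open in enough stages are
flagged species-specific open (defaults: 2+ stages for the 6-stage species,
1+ for the 3-stage species).  Peaks unmappable to *every* outgroup assembly
are newly emerged.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome import DHSPeak, GeneModel, GenomicInterval, GenomeAssembly, extend_and_merge

__all__ = [
    "ChainBlock",
    "ChainMap",
    "LiftResult",
    "ConservationCall",
    "lift_interval",
    "liftability_classes",
    "reciprocal_conserved_pairs",
    "synteny_check",
    "species_specific_open",
    "newly_emerged",
    "promoter_conservation",
    "conservation_calls",
]


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped aligned block; src and tgt spans have equal length."""

    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    strand: str = "+"
    chain_id: int = 0

    def __post_init__(self) -> None:
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ValueError("chain block sides differ in length")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad block strand {self.strand!r}")


class ChainMap:
    """Ordered aligned blocks between a source and a target assembly."""

    def __init__(
        self,
        blocks: Iterable[ChainBlock],
        source_assembly: str = "",
        target_assembly: str = "",
    ):
        self.source_assembly = source_assembly
        self.target_assembly = target_assembly
        self.blocks = sorted(blocks, key=lambda b: (b.src_chrom, b.src_start))
        self._index: dict[str, tuple[list[int], list[int], list[ChainBlock]]] = {}
        by_chrom: dict[str, list[ChainBlock]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.src_chrom, []).append(b)
        for chrom, blist in by_chrom.items():
            starts = [b.src_start for b in blist]
            ends = [b.src_end for b in blist]
            self._index[chrom] = (starts, ends, blist)

    def overlapping_blocks(self, iv: GenomicInterval) -> list[ChainBlock]:
        entry = self._index.get(iv.chrom)
        if entry is None:
            return []
        starts, _ends, blist = entry
        # blocks per chromosome come from few chains; scan the start window
        lo = 0
        hi = bisect_left(starts, iv.end)
        return [b for b in blist[lo:hi] if b.src_end > iv.start]

    def invert(self) -> "ChainMap":
        inv = [
            ChainBlock(
                b.tgt_chrom,
                b.tgt_start,
                b.tgt_end,
                b.src_chrom,
                b.src_start,
                b.src_end,
                b.strand,
                b.chain_id,
            )
            for b in self.blocks
        ]
        return ChainMap(inv, self.target_assembly, self.source_assembly)


@dataclass(frozen=True)
class LiftResult:
    status: str  # unique | multiple | unmapped
    target: GenomicInterval | None = None
    mapped_fraction: float = 0.0


def _project_block(b: ChainBlock, a: int, e: int) -> tuple[int, int]:
    """Project source sub-span [a, e) of block b onto the target."""
    if b.strand == "+":
        return b.tgt_start + (a - b.src_start), b.tgt_start + (e - b.src_start)
    return b.tgt_end - (e - b.src_start), b.tgt_end - (a - b.src_start)


def lift_interval(
    iv: GenomicInterval, chain: ChainMap, min_mapped: float = 0.95
) -> LiftResult:
    """Project an interval through a chain map.

    Chains are considered independently; a chain qualifies when it maps at
    least ``min_mapped`` of the query bases.  Two or more qualifying chains
    make the lift ambiguous (``multiple``); exactly one yields a ``unique``
    lift whose target is the span of the projected bases (orientation-aware);
    none means ``unmapped``.
    """
    per_chain: dict[int, list[tuple[ChainBlock, int, int]]] = {}
    for b in chain.overlapping_blocks(iv):
        a = max(iv.start, b.src_start)
        e = min(iv.end, b.src_end)
        if a < e:
            per_chain.setdefault(b.chain_id, []).append((b, a, e))
    if not per_chain:
        return LiftResult("unmapped", None, 0.0)
    qualified = []
    best_fraction = 0.0
    for chain_id, pieces in per_chain.items():
        mapped = sum(e - a for _b, a, e in pieces)
        frac = mapped / iv.length
        best_fraction = max(best_fraction, frac)
        if frac >= min_mapped:
            qualified.append((chain_id, pieces, frac))
    if len(qualified) > 1:
        return LiftResult("multiple", None, best_fraction)
    if not qualified:
        return LiftResult("unmapped", None, best_fraction)
    _cid, pieces, frac = qualified[0]
    tgt_chroms = {b.tgt_chrom for b, _a, _e in pieces}
    if len(tgt_chroms) != 1:
        return LiftResult("unmapped", None, frac)
    spans = [_project_block(b, a, e) for b, a, e in pieces]
    start = min(s for s, _ in spans)
    end = max(e for _, e in spans)
    return LiftResult("unique", GenomicInterval(tgt_chroms.pop(), start, end), frac)


def liftability_classes(
    peaks_a: Sequence[DHSPeak],
    chain_ab: ChainMap,
    peaks_b_extended: Sequence[GenomicInterval],
    min_mapped: float = 0.95,
) -> tuple[dict[str, str], dict[str, LiftResult]]:
    """Classify each peak of species A against species B.

    Returns (class per peak id, lift result per peak id).  Classes are
    ``maps_and_overlaps`` / ``maps_no_overlap`` / ``unmappable``; ambiguous
    lifts are labelled ``multiple`` and excluded from all three classes.
    """
    index = _SortedIntervals(peaks_b_extended)
    classes: dict[str, str] = {}
    lifts: dict[str, LiftResult] = {}
    for peak in peaks_a:
        res = lift_interval(peak.interval, chain_ab, min_mapped)
        lifts[peak.peak_id] = res
        if res.status == "multiple":
            classes[peak.peak_id] = "multiple"
        elif res.status == "unmapped":
            classes[peak.peak_id] = "unmappable"
        elif index.any_overlap(res.target):
            classes[peak.peak_id] = "maps_and_overlaps"
        else:
            classes[peak.peak_id] = "maps_no_overlap"
    return classes, lifts


class _SortedIntervals:
    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        tmp: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in tmp.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            max_end: list[int] = []
            running = 0
            for iv in ivs:
                running = max(running, iv.end)
                max_end.append(running)
            self._by_chrom[chrom] = ([iv.start for iv in ivs], max_end)

    def any_overlap(self, iv: GenomicInterval) -> bool:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, max_end = entry
        hi = bisect_left(starts, iv.end)
        return hi > 0 and max_end[hi - 1] > iv.start


def synteny_check(
    region_a: GenomicInterval,
    region_b: GenomicInterval,
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
) -> bool:
    """Nearest flanking 1-to-1 orthologs must agree between the two regions.

    The closest ortholog-bearing gene TSS upstream and downstream of each
    region is found; the call passes when the two flanking-ortholog sets
    match (order may flip under inversion).  With a single flank on either
    side, one matching flank suffices.
    """
    flanks_a = _flanking_orthologs(region_a, genes_a)
    flanks_b = _flanking_orthologs(region_b, genes_b, use_ortholog_id=False)
    # compare in ortholog-id space: genes_a carry ortholog ids naming B genes
    if not flanks_a or not flanks_b:
        return False
    if len(flanks_a) == 1 or len(flanks_b) == 1:
        return bool(flanks_a & flanks_b)
    return flanks_a == flanks_b


def _flanking_orthologs(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    use_ortholog_id: bool = True,
) -> set[str]:
    """Identifiers of the nearest ortholog-mapped genes up/downstream."""
    candidates = [
        g
        for g in genes
        if g.chrom == region.chrom and g.ortholog_id is not None
    ]
    if not candidates:
        return set()
    mid = region.midpoint
    up = [g for g in candidates if g.tss <= mid]
    down = [g for g in candidates if g.tss > mid]
    flanks = set()
    if up:
        g = max(up, key=lambda g: g.tss)
        flanks.add(g.ortholog_id if use_ortholog_id else g.gene_id)
    if down:
        g = min(down, key=lambda g: g.tss)
        flanks.add(g.ortholog_id if use_ortholog_id else g.gene_id)
    return flanks


@dataclass
class ConservationCall:
    peak_id_a: str
    peak_id_b: str | None
    category: str  # conserved_pair | sequence_conserved_divergent_state | genome_specific
    lift_class: str
    species_specific_open: bool = False
    newly_emerged: bool = False


def _best_reciprocal_match(
    peaks_src: Sequence[DHSPeak],
    peaks_tgt: Sequence[DHSPeak],
    chain: ChainMap,
    assembly_tgt: GenomeAssembly,
    min_frac: float,
    pad: int,
    min_mapped: float,
) -> dict[str, str]:
    """Best target peak per source peak by overlap fraction of the lifted query.

    The fraction denominator is the lifted query length; overlap is measured
    against the pad-extended target peak.  Strictly greater than ``min_frac``
    is required.  Ties break to the smallest target start, then id.
    """
    ext = {
        p.peak_id: assembly_tgt.clip(
            GenomicInterval(
                p.interval.chrom,
                max(0, p.interval.start - pad),
                p.interval.end + pad,
            )
        )
        for p in peaks_tgt
    }
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    max_len: dict[str, int] = {}
    for pid, iv in ext.items():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, pid))
        max_len[iv.chrom] = max(max_len.get(iv.chrom, 0), iv.length)
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    matches: dict[str, str] = {}
    for peak in peaks_src:
        res = lift_interval(peak.interval, chain, min_mapped)
        if res.status != "unique":
            continue
        lifted = res.target
        entry = by_chrom.get(lifted.chrom, [])
        best: tuple[float, int, str] | None = None
        starts = [s for s, _e, _p in entry]
        hi = bisect_right(starts, lifted.end)
        lo = bisect_left(starts, lifted.start - max_len.get(lifted.chrom, 0))
        for s, e, pid in entry[lo:hi]:
            ov = min(e, lifted.end) - max(s, lifted.start)
            if ov <= 0:
                continue
            frac = ov / lifted.length
            if frac > min_frac:
                key = (frac, -s, pid)
                if best is None or (key[0], key[1]) > (best[0], best[1]):
                    best = key
        if best is not None:
            matches[peak.peak_id] = best[2]
    return matches


def reciprocal_conserved_pairs(
    peaks_a: Sequence[DHSPeak],
    peaks_b: Sequence[DHSPeak],
    chain_ab: ChainMap,
    chain_ba: ChainMap,
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    assembly_a: GenomeAssembly,
    assembly_b: GenomeAssembly,
    min_frac: float = 0.5,
    pad: int = 500,
    min_mapped: float = 0.95,
    require_synteny: bool = True,
) -> list[tuple[str, str]]:
    """One-to-one conserved peak pairs via reciprocal lifted overlap + synteny."""
    fwd = _best_reciprocal_match(
        peaks_a, peaks_b, chain_ab, assembly_b, min_frac, pad, min_mapped
    )
    rev = _best_reciprocal_match(
        peaks_b, peaks_a, chain_ba, assembly_a, min_frac, pad, min_mapped
    )
    iv_a = {p.peak_id: p.interval for p in peaks_a}
    iv_b = {p.peak_id: p.interval for p in peaks_b}
    pairs = []
    for pid_a, pid_b in fwd.items():
        if rev.get(pid_b) != pid_a:
            continue
        if require_synteny and not synteny_check(
            iv_a[pid_a], iv_b[pid_b], genes_a, genes_b
        ):
            continue
        pairs.append((pid_a, pid_b))
    return sorted(pairs)


def species_specific_open(
    peaks: Sequence[DHSPeak],
    classes: Mapping[str, str],
    min_open_stages: int,
) -> set[str]:
    """Class-2 peaks open in at least ``min_open_stages`` stages."""
    return {
        p.peak_id
        for p in peaks
        if classes.get(p.peak_id) == "maps_no_overlap"
        and p.n_open_stages >= min_open_stages
    }


def newly_emerged(
    peaks: Sequence[DHSPeak],
    outgroup_chains: Mapping[str, ChainMap],
    min_mapped: float = 0.95,
) -> set[str]:
    """Peaks whose sequence cannot be lifted to any outgroup assembly."""
    if not outgroup_chains:
        raise ValueError("newly-emerged calling needs at least one outgroup chain")
    flagged = set()
    for peak in peaks:
        if all(
            lift_interval(peak.interval, chain, min_mapped).status == "unmapped"
            for chain in outgroup_chains.values()
        ):
            flagged.add(peak.peak_id)
    return flagged


def promoter_conservation(
    open_a: Mapping[str, bool], open_b: Mapping[str, bool]
) -> str:
    """Promoter openness class for an orthologous gene pair.

    ``a_specific_open``: open at every A stage and at no B stage;
    ``b_specific_open``: the mirror; ``conserved_open``: open at every stage
    in both species; anything else is ``other``.
    """
    all_a = all(open_a.values()) and len(open_a) > 0
    any_a = any(open_a.values())
    all_b = all(open_b.values()) and len(open_b) > 0
    any_b = any(open_b.values())
    if all_a and not any_b:
        return "a_specific_open"
    if all_b and not any_a:
        return "b_specific_open"
    if all_a and all_b:
        return "conserved_open"
    return "other"


def conservation_calls(
    peaks_a: Sequence[DHSPeak],
    peaks_b: Sequence[DHSPeak],
    chain_ab: ChainMap,
    chain_ba: ChainMap,
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    assembly_a: GenomeAssembly,
    assembly_b: GenomeAssembly,
    outgroup_chains: Mapping[str, ChainMap] | None = None,
    min_frac: float = 0.5,
    pad: int = 500,
    min_mapped: float = 0.95,
    min_open_stages_a: int = 2,
) -> tuple[dict[str, ConservationCall], list[str]]:
    """Full per-peak conservation categorization for species A.

    Returns (calls keyed by A peak id, ids removed for multi-chain ambiguity).
    Peaks in class 1 that fail reciprocity or synteny are sequence-conserved
    but not conserved pairs and fall into the divergent-state category, as do
    class-2 peaks.  Unmappable peaks are genome-specific.  When outgroup
    chains are given, unmappable-everywhere peaks are additionally flagged
    newly emerged.
    """
    ext_b = extend_and_merge([p.interval for p in peaks_b], assembly_b, pad)
    classes, _lifts = liftability_classes(peaks_a, chain_ab, ext_b, min_mapped)
    pairs = dict(
        reciprocal_conserved_pairs(
            peaks_a,
            peaks_b,
            chain_ab,
            chain_ba,
            genes_a,
            genes_b,
            assembly_a,
            assembly_b,
            min_frac=min_frac,
            pad=pad,
            min_mapped=min_mapped,
        )
    )
    sso = species_specific_open(peaks_a, classes, min_open_stages_a)
    emerged: set[str] = set()
    if outgroup_chains:
        emerged = newly_emerged(peaks_a, outgroup_chains, min_mapped)
    calls: dict[str, ConservationCall] = {}
    removed: list[str] = []
    for peak in peaks_a:
        pid = peak.peak_id
        cls = classes[pid]
        if cls == "multiple":
            removed.append(pid)
            continue
        if pid in pairs:
            category = "conserved_pair"
            partner = pairs[pid]
        elif cls == "unmappable":
            category = "genome_specific"
            partner = None
        else:
            category = "sequence_conserved_divergent_state"
            partner = None
        calls[pid] = ConservationCall(
            peak_id_a=pid,
            peak_id_b=partner,
            category=category,
            lift_class=cls,
            species_specific_open=pid in sso,
            newly_emerged=pid in emerged,
        )
    return calls, removed
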