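"""Seeded two-species synthetic dataset with planted ground truth.

The generator emits everything the pipeline consumes — two assemblies related
by a block map, stage-resolved peaks and FPKM matrices for a 6-stage and a
3-stage species, SNPs, CpG/methylation tables, GO terms and interaction
anchors — together with a :class:`PlantedTruth` record of what was planted.

Genome B is derived from genome A by a fixed per-chromosome rearrangement
layout: two deleted segments (one also absent from all outgroup genomes, the
other only from B), an inverted segment, a segment translocated to another
chromosome, a segmentally duplicated region that lifts ambiguously, and a
B-specific insertion.  Planted element classes follow from where an element
sits:

* ``conserved``       - normal territory; a B partner peak at the lifted locus;
* ``state_divergent`` - normal territory; lifts, but B has no peak there;
* ``genome_specific`` - inside the B-only deletion (mappable to outgroups);
* ``newly_emerged``   - inside the everywhere-deleted segment;
* ``translocated``    - lifts to another chromosome with a B partner, so the
  reciprocal overlap passes but the flanking-ortholog synteny check fails;
* ``multi_hit``       - inside the duplicated segment (two qualifying chains).

Dynamic expression archetypes over the 6 A stages are cyclic high-blocks:
high at k consecutive stages (mod 6) for k = 1, 2, 3, with equal gene counts
in every rotation, plus uniform-high, low-flat and silent genes.  The
rotation that wraps around the series end (high at the first and last stage,
low between) is the bimodally expressed class driven by distinct early- and
late-acting element sets.  Per-gene log-normal signatures keep co-archetype
genes from being identical.  The rotational balance makes the per-stage
value distributions (and hence the quantile-normalization reference)
essentially stage-invariant, so planted correlations survive normalization.

The 3-stage species B uses exact two-valued stage patterns assigned so that
every stage column of both the expression and the accessibility matrix holds
the identical value multiset; quantile normalization is then exactly the
identity in the noise-free regime, which matters because a 3-point Pearson
test at p < 0.05 requires r > 0.9969.

Planted regulatory elements copy their target gene's stage profile (scaled
by the coupling); measurement noise of standard deviation ``noise_sd`` is
added on the log2 scale when matrices are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .crossmap import ChainBlock, ChainMap, lift_interval, synteny_check
from .enrichment import GoTerm, SnpCatalog
from .genome import (
    CpGSite,
    DHSPeak,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    derive_promoter,
)
from .pairing import InteractionRecord

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedDataset",
    "simulate",
    "write_dataset",
    "small_config",
]

STAGES_A = ("GW11", "GW13", "GW16", "GW19", "GW23", "GW26")
STAGES_B = ("E50", "E90", "E120")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-genome dataset.

    The default scale is two 10-Mb chromosomes, 300 genes and about 2,000
    regulatory elements — large enough for stable statistics, small enough
    for seconds-scale runs.  Archetype counts are constrained (equal
    per-rotation counts, ``n_block2 == n_block3``) to keep stage columns
    distribution-balanced; see the module docstring.
    """

    n_chroms: int = 2
    chrom_length: int = 10_000_000
    genes_per_chrom: int = 150
    stages_a: tuple[str, ...] = STAGES_A
    stages_b: tuple[str, ...] = STAGES_B

    # gene archetype counts (whole genome)
    n_block1: int = 36
    n_block2: int = 60
    n_block3: int = 60
    n_uniform: int = 60
    n_lowflat: int = 48
    n_silent: int = 36

    # element class counts (whole genome)
    n_conserved: int = 1100
    n_state_divergent: int = 310
    n_genome_specific: int = 280
    n_newly_emerged: int = 200
    n_translocated: int = 30
    n_multi_hit: int = 20
    n_conserved_open_prom: int = 40
    n_a_specific_prom: int = 20
    n_b_specific_prom: int = 20
    n_b_specific_distal: int = 150

    # planted pairing
    n_divergent_paired: int = 40
    n_gspec_paired: int = 20
    n_newly_paired: int = 10
    n_transloc_paired: int = 10

    # signal levels (FPKM) and variation (log2 scale)
    hi_fpkm: float = 30.0
    lo_fpkm: float = 0.3
    uniform_fpkm: float = 7.0
    lowflat_fpkm: float = 0.5
    baseline_fpkm: float = 1.0
    promoter_fpkm: float = 7.0
    signature_sd: float = 0.6
    noise_sd: float = 0.0
    coupling: float = 1.0

    element_length: int = 300
    promoter_peak_length: int = 600
    gene_body_length: int = 10_000

    # variants / methylation
    snp_per_kb: float = 1.0
    snp_enriched_fold: float = 3.0
    cpg_rich_per_100bp: float = 8.0
    cpg_poor_per_100bp: float = 1.0
    meth_rich_beta: tuple[float, float] = (2.0, 8.0)
    meth_poor_beta: tuple[float, float] = (8.0, 2.0)
    coverage_mean: float = 20.0

    hic_fraction: float = 0.6
    n_hic_noise: int = 200
    n_go_terms: int = 30
    n_outgroups: int = 3
    n_no_ortholog: int = 10
    identity_genomes: bool = False

    @property
    def n_dynamic(self) -> int:
        return self.n_block1 + self.n_block2 + self.n_block3

    def validate(self) -> None:
        n_stages = len(self.stages_a)
        total = self.n_dynamic + self.n_uniform + self.n_lowflat + self.n_silent
        if total != self.n_chroms * self.genes_per_chrom:
            raise ValueError("archetype counts must sum to the gene count")
        for n in (self.n_block1, self.n_block2, self.n_block3):
            if n % n_stages != 0:
                raise ValueError("block archetype counts must divide over rotations")
        if self.n_block2 != self.n_block3:
            raise ValueError("stage balance requires n_block2 == n_block3")
        strata = (
            self.n_conserved_open_prom + self.n_a_specific_prom + self.n_b_specific_prom
        )
        quiet = self.n_uniform + self.n_lowflat + self.n_silent
        if strata + self.n_no_ortholog > quiet:
            raise ValueError("promoter strata plus ortholog-free genes exceed quiet genes")


def small_config(**overrides) -> SimulationConfig:
    """A reduced, balance-preserving configuration for fast unit tests."""
    cfg = SimulationConfig(
        n_chroms=2,
        chrom_length=2_000_000,
        genes_per_chrom=30,
        n_block1=6, n_block2=12, n_block3=12,
        n_uniform=12, n_lowflat=10, n_silent=8,
        n_conserved=120, n_state_divergent=34, n_genome_specific=16,
        n_newly_emerged=16, n_translocated=6, n_multi_hit=4,
        n_conserved_open_prom=8, n_a_specific_prom=4, n_b_specific_prom=4,
        n_b_specific_distal=20,
        n_divergent_paired=6, n_gspec_paired=4, n_newly_paired=2,
        n_transloc_paired=2,
        n_hic_noise=40, n_go_terms=10, n_no_ortholog=4,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@dataclass
class PlantedTruth:
    """Ground truth for everything the generator planted."""

    element_class: dict[str, str] = field(default_factory=dict)
    conserved_partners: dict[str, str] = field(default_factory=dict)
    pairs_a: list[tuple[str, str, str]] = field(default_factory=list)  # gene, peak, phase
    pairs_b: list[tuple[str, str, str]] = field(default_factory=list)
    gene_archetype: dict[str, str] = field(default_factory=dict)
    gene_archetype_b: dict[str, str] = field(default_factory=dict)
    species_specific_open_a: list[str] = field(default_factory=list)
    promoter_class: dict[str, str] = field(default_factory=dict)
    cpg_rich_genes: list[str] = field(default_factory=list)
    cpg_poor_genes: list[str] = field(default_factory=list)
    hic_pairs: list[tuple[str, str]] = field(default_factory=list)
    removed_multi: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "PlantedTruth":
        truth = cls(**obj)
        truth.pairs_a = [tuple(x) for x in truth.pairs_a]
        truth.pairs_b = [tuple(x) for x in truth.pairs_b]
        truth.hic_pairs = [tuple(x) for x in truth.hic_pairs]
        return truth


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    assembly_a: GenomeAssembly
    assembly_b: GenomeAssembly
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    peaks_a: list[DHSPeak]
    peaks_b: list[DHSPeak]
    chain_ab: ChainMap
    chain_ba: ChainMap
    outgroup_chains: dict[str, ChainMap]
    expr_a: pd.DataFrame  # FPKM, genes x stages
    expr_b: pd.DataFrame
    acc_a: pd.DataFrame  # FPKM, peaks x stages
    acc_b: pd.DataFrame
    snps: SnpCatalog
    cpg_sites: list[CpGSite]
    go_terms: list[GoTerm]
    interactions: list[InteractionRecord]
    truth: PlantedTruth


@dataclass
class _Zones:
    newly: tuple[int, int]
    gspec: tuple[int, int]
    inversion: tuple[int, int]
    trans: tuple[int, int]
    dup: tuple[int, int]
    b_insert_pos: int
    b_insert_len: int

    def deleted_or_moved(self) -> list[tuple[int, int]]:
        return [self.newly, self.gspec, self.trans, self.dup]

    def all_zones(self) -> list[tuple[int, int]]:
        return [self.newly, self.gspec, self.inversion, self.trans, self.dup]


def _zones_for(cfg: SimulationConfig) -> _Zones:
    L = cfg.chrom_length
    return _Zones(
        newly=(int(0.200 * L), int(0.210 * L)),
        gspec=(int(0.230 * L), int(0.240 * L)),
        inversion=(int(0.400 * L), int(0.450 * L)),
        trans=(int(0.600 * L), int(0.606 * L)),
        dup=(int(0.800 * L), int(0.802 * L)),
        b_insert_pos=int(0.900 * L),
        b_insert_len=int(0.005 * L),
    )


def _build_genomes(cfg: SimulationConfig):
    """Derive assembly B and all chain maps from the rearrangement layout."""
    chroms_a = {f"chrA{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    assembly_a = GenomeAssembly("speciesA", chroms_a)
    zones = _zones_for(cfg)
    blocks: list[ChainBlock] = []
    b_lengths: dict[str, int] = {}
    if cfg.identity_genomes:
        for i in range(cfg.n_chroms):
            ca, cb = f"chrA{i + 1}", f"chrB{i + 1}"
            blocks.append(
                ChainBlock(ca, 0, cfg.chrom_length, cb, 0, cfg.chrom_length, "+", 100 + i)
            )
            b_lengths[cb] = cfg.chrom_length
        assembly_b = GenomeAssembly("speciesB", b_lengths)
        chain_ab = ChainMap(blocks, "speciesA", "speciesB")
        og_chains = {}
        for k in range(cfg.n_outgroups):
            og_blocks = [
                ChainBlock(f"chrA{i + 1}", 0, cfg.chrom_length,
                           f"og{k + 1}_chr{i + 1}", 0, cfg.chrom_length, "+", i)
                for i in range(cfg.n_chroms)
            ]
            og_chains[f"og{k + 1}"] = ChainMap(og_blocks, "speciesA", f"og{k + 1}")
        return assembly_a, assembly_b, chain_ab, og_chains, zones

    L = cfg.chrom_length
    # segments translocated out of chromosome i land in chromosome (i+1) % n
    trans_src = {i: (f"chrA{i + 1}",) + zones.trans for i in range(cfg.n_chroms)}
    incoming = {(i + 1) % cfg.n_chroms: (i,) + trans_src[i] for i in range(cfg.n_chroms)}

    for i in range(cfg.n_chroms):
        ca, cb = f"chrA{i + 1}", f"chrB{i + 1}"
        main, inv_id, dup_id = 100 + i, 200 + i, 400 + i
        off = 0

        def match(s: int, e: int, chain_id: int = main, strand: str = "+"):
            nonlocal off
            if e > s:
                blocks.append(ChainBlock(ca, s, e, cb, off, off + (e - s), strand, chain_id))
                off += e - s

        match(0, zones.newly[0])
        # newly zone: deleted everywhere
        match(zones.newly[1], zones.gspec[0])
        # gspec zone: deleted in B only
        match(zones.gspec[1], zones.inversion[0])
        match(*zones.inversion, chain_id=inv_id, strand="-")
        match(zones.inversion[1], zones.trans[0])
        # translocated zone leaves this chromosome
        match(zones.trans[1], zones.b_insert_pos)
        off += zones.b_insert_len  # B-specific insertion
        src_idx, src_chrom_in, s_in, e_in = incoming[i]
        blocks.append(
            ChainBlock(src_chrom_in, s_in, e_in, cb, off, off + (e_in - s_in), "+", 300 + src_idx)
        )
        off += e_in - s_in
        # extra copy of the duplicated segment (second qualifying chain)
        blocks.append(
            ChainBlock(ca, zones.dup[0], zones.dup[1], cb, off,
                       off + (zones.dup[1] - zones.dup[0]), "+", dup_id)
        )
        off += zones.dup[1] - zones.dup[0]
        match(zones.b_insert_pos, L)
        b_lengths[cb] = off

    assembly_b = GenomeAssembly("speciesB", b_lengths)
    chain_ab = ChainMap(blocks, "speciesA", "speciesB")
    og_chains = {}
    for k in range(cfg.n_outgroups):
        og_blocks = []
        for i in range(cfg.n_chroms):
            ca, co = f"chrA{i + 1}", f"og{k + 1}_chr{i + 1}"
            n0, n1 = zones.newly
            og_blocks.append(ChainBlock(ca, 0, n0, co, 0, n0, "+", i))
            og_blocks.append(ChainBlock(ca, n1, L, co, n0, n0 + L - n1, "+", i))
        og_chains[f"og{k + 1}"] = ChainMap(og_blocks, "speciesA", f"og{k + 1}")
    return assembly_a, assembly_b, chain_ab, og_chains, zones


def _near_any(pos: int, zones: Sequence[tuple[int, int]], margin: int) -> bool:
    return any(z0 - margin <= pos < z1 + margin for z0, z1 in zones)


def _place_genes(cfg: SimulationConfig, zones: _Zones, chain_ab, rng):
    """Evenly spaced genes avoiding rearrangement zones; lifted B counterparts."""
    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    body_len = cfg.gene_body_length
    idx = 0
    # genes stay clear of deleted/translocated/duplicated segments and of the
    # inversion boundaries and insertion point, but may live inside the
    # inversion itself (their B copies simply flip strand)
    avoid = zones.deleted_or_moved() + [
        (zones.inversion[0], zones.inversion[0]),
        (zones.inversion[1], zones.inversion[1]),
        (zones.b_insert_pos, zones.b_insert_pos),
    ]
    for i in range(cfg.n_chroms):
        ca = f"chrA{i + 1}"
        spacing = max(1, cfg.chrom_length // (cfg.genes_per_chrom * 3))
        candidates = []
        for j in range(1, cfg.genes_per_chrom * 3):
            tss = j * spacing
            lo, hi = tss - body_len, tss + body_len
            if lo < 20_000 or hi > cfg.chrom_length - 20_000:
                continue
            if not cfg.identity_genomes and (
                _near_any(lo, avoid, 12_000) or _near_any(hi, avoid, 12_000)
            ):
                continue
            candidates.append(tss)
        if len(candidates) < cfg.genes_per_chrom:
            raise RuntimeError("gene placement failed; layout too crowded")
        chosen = [
            candidates[k]
            for k in np.linspace(0, len(candidates) - 1, cfg.genes_per_chrom).astype(int)
        ]
        for tss in chosen:
            strand = "+" if idx % 2 == 0 else "-"
            lo = tss - body_len if strand == "-" else tss
            hi = tss if strand == "-" else tss + body_len
            gid_a, gid_b = f"gA{idx:04d}", f"gB{idx:04d}"
            body = GenomicInterval(ca, lo, hi)
            genes_a.append(GeneModel(gid_a, ca, strand, tss, body, ortholog_id=gid_b))
            res = lift_interval(body, chain_ab)
            tss_res = lift_interval(
                GenomicInterval(ca, max(0, tss - 1), tss + 1), chain_ab
            )
            if res.status != "unique" or tss_res.status != "unique":
                raise RuntimeError(f"gene {gid_a} does not lift uniquely")
            inverted = (
                zones.inversion[0] <= tss < zones.inversion[1]
                and not cfg.identity_genomes
            )
            strand_b = ({"+": "-", "-": "+"}[strand]) if inverted else strand
            tss_b = tss_res.target.start if inverted else tss_res.target.end - 1
            tss_b = min(max(tss_b, res.target.start), res.target.end)
            genes_b.append(
                GeneModel(gid_b, res.target.chrom, strand_b, tss_b, res.target,
                          ortholog_id=gid_a)
            )
            idx += 1
    return genes_a, genes_b


def _assign_archetypes(cfg: SimulationConfig, genes_a, rng) -> dict[str, str]:
    """Shuffle archetype labels over genes.

    Dynamic labels are ``b{k}r{p}``: high at the k consecutive stages
    starting at rotation p (cyclic over the stage series), with exactly equal
    counts in every rotation.
    """
    n_stages = len(cfg.stages_a)
    counts: dict[str, int] = {}
    for k, count in ((1, cfg.n_block1), (2, cfg.n_block2), (3, cfg.n_block3)):
        per_rot = count // n_stages
        for p in range(n_stages):
            counts[f"b{k}r{p}"] = per_rot
    counts["uniform"] = cfg.n_uniform
    counts["lowflat"] = cfg.n_lowflat
    counts["silent"] = cfg.n_silent
    # interleave labels evenly along the gene order (with a random per-label
    # phase) so genes sharing an archetype sit far apart on the chromosome
    # and rarely fall into each other's candidate windows
    placed: list[tuple[float, str]] = []
    for lab, c in counts.items():
        phase = float(rng.random())
        placed += [((i + phase) / c, lab) for i in range(c)]
    placed.sort()
    labels = [lab for _pos, lab in placed]
    return {g.gene_id: lab for g, lab in zip(genes_a, labels)}


def _hi_stages(label: str, n_stages: int) -> list[int]:
    """Stage indices where a dynamic archetype is high."""
    if not label.startswith("b"):
        return []
    k, p = int(label[1]), int(label[3:])
    return sorted((p + j) % n_stages for j in range(k))


def _is_flank_bimodal(label: str, n_stages: int) -> bool:
    """High at exactly the first and last stage: the masked-pairing class."""
    return _hi_stages(label, n_stages) == [0, n_stages - 1]


def _wraps(label: str, n_stages: int) -> bool:
    hi = _hi_stages(label, n_stages)
    return bool(hi) and 0 in hi and (n_stages - 1) in hi


_B_PATTERN_BY_ROTATION = {
    # (family k, rotation p) -> 3-stage class; chosen so that, with equal
    # per-rotation counts and n_block2 == n_block3, every B stage column
    # carries the same number of high, low and zero values.
    (2, 0): "bimodal", (2, 1): "early", (2, 2): "middle", (2, 3): "middle",
    (2, 4): "late", (2, 5): "bimodal",
    (3, 0): "early", (3, 1): "middle", (3, 2): "middle", (3, 3): "middle",
    (3, 4): "late", (3, 5): "bimodal",
}


def _b_label(label_a: str, n_stages: int) -> str:
    """Species-B expression class for a gene given its A archetype."""
    if not label_a.startswith("b"):
        return label_a
    k, p = int(label_a[1]), int(label_a[3:])
    if k == 1:
        return f"onestage{p // 2}"
    return _B_PATTERN_BY_ROTATION[(k, p)]


def _b_pattern(label_b: str, cfg: SimulationConfig) -> np.ndarray:
    """Exact two-valued 3-stage expression pattern (log2 FPKM scale)."""
    h = np.log2(cfg.hi_fpkm + 1)
    l = np.log2(cfg.lo_fpkm + 1)
    patterns = {
        "early": [h, l, l],
        "middle": [l, h, l],
        "late": [l, l, h],
        "bimodal": [h, l, h],
        "uniform": [np.log2(cfg.uniform_fpkm + 1)] * 3,
        "lowflat": [np.log2(cfg.lowflat_fpkm + 1)] * 3,
        "silent": [0.0] * 3,
    }
    if label_b.startswith("onestage"):
        out = np.zeros(3)
        out[int(label_b[len("onestage"):])] = h
        return out
    return np.array(patterns[label_b])


def _gene_profile_a(label: str, cfg: SimulationConfig, rng) -> np.ndarray:
    """Log2 FPKM profile over the A stages with a per-gene signature."""
    n = len(cfg.stages_a)
    if label == "uniform":
        return np.full(n, np.log2(cfg.uniform_fpkm + 1))
    if label == "lowflat":
        return np.full(n, np.log2(cfg.lowflat_fpkm + 1))
    if label == "silent":
        return np.zeros(n)
    hi = set(_hi_stages(label, n))
    one_stage_family = label.startswith("b1")
    # the flank-bimodal class is defined by comparable activation at the
    # earliest and latest stage: both flanks share one amplitude draw
    shared_hi = (
        cfg.hi_fpkm * 2 ** rng.normal(0, cfg.signature_sd)
        if _is_flank_bimodal(label, n) else None
    )
    prof = np.zeros(n)
    for s in range(n):
        if s in hi:
            fpkm = shared_hi if shared_hi is not None \
                else cfg.hi_fpkm * 2 ** rng.normal(0, cfg.signature_sd)
        elif one_stage_family:
            fpkm = 0.0
        else:
            fpkm = cfg.lo_fpkm * 2 ** rng.normal(0, cfg.signature_sd)
        prof[s] = np.log2(fpkm + 1)
    return prof


class _SlotPool:
    """Grid of available element start positions per chromosome.

    Elements keep at least 1 kb spacing in normal territory (500 bp inside
    rearrangement zones) and stay clear of zone boundaries, the B-insertion
    point and promoter windows, so that lifted elements never graze a
    neighbouring extended peak.
    """

    def __init__(self, cfg: SimulationConfig, zones: _Zones, genes_a, rng):
        self.cfg = cfg
        self.zones = zones
        self.rng = rng
        self.used: set[tuple[str, int]] = set()
        self.tss_by_chrom: dict[str, np.ndarray] = {}
        for i in range(cfg.n_chroms):
            ca = f"chrA{i + 1}"
            self.tss_by_chrom[ca] = np.array(
                sorted(g.tss for g in genes_a if g.chrom == ca), dtype=np.int64
            )

    def _ok(self, chrom: str, pos: int) -> bool:
        cfg, zones = self.cfg, self.zones
        if pos < 10_000 or pos + cfg.element_length > cfg.chrom_length - 10_000:
            return False
        if (chrom, pos) in self.used:
            return False
        if not cfg.identity_genomes:
            if _near_any(pos, zones.deleted_or_moved(), 3_000):
                return False
            inv0, inv1 = zones.inversion
            if abs(pos - inv0) < 3_000 or abs(pos - inv1) < 3_000:
                return False
            if abs(pos - zones.b_insert_pos) < 3_000:
                return False
        tss = self.tss_by_chrom[chrom]
        k = int(np.searchsorted(tss, pos))
        for t in tss[max(0, k - 1): k + 1]:
            if abs(pos - int(t)) < 3_500:
                return False
        return True

    def near(self, chrom: str, center: int, max_dist: int) -> int:
        for _ in range(500):
            pos = (center + int(self.rng.integers(-max_dist, max_dist))) // 1000 * 1000
            if self._ok(chrom, pos):
                self.used.add((chrom, pos))
                return pos
        raise RuntimeError("could not place element near gene")

    def anywhere(self, chrom: str) -> int:
        for _ in range(800):
            pos = int(self.rng.integers(10_000, self.cfg.chrom_length - 10_000))
            pos = pos // 1000 * 1000
            if self._ok(chrom, pos):
                self.used.add((chrom, pos))
                return pos
        raise RuntimeError("could not place element")

    def in_zone(self, chrom: str, zone: tuple[int, int]) -> int:
        lo = zone[0] + 200
        hi = zone[1] - self.cfg.element_length - 200
        for _ in range(800):
            pos = int(self.rng.integers(lo, hi)) // 500 * 500
            if (chrom, pos) not in self.used and lo <= pos <= hi:
                self.used.add((chrom, pos))
                return pos
        raise RuntimeError("could not place element in zone")

    def release(self, chrom: str, pos: int) -> None:
        self.used.discard((chrom, pos))


def simulate(cfg: SimulationConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate the full two-species dataset with planted truth."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_stages = len(cfg.stages_a)
    assembly_a, assembly_b, chain_ab, og_chains, zones = _build_genomes(cfg)
    chain_ba = chain_ab.invert()
    genes_a, genes_b = _place_genes(cfg, zones, chain_ab, rng)
    archetypes = _assign_archetypes(cfg, genes_a, rng)
    truth = PlantedTruth(gene_archetype=dict(archetypes))
    genes_by_id = {g.gene_id: g for g in genes_a}
    genes_b_by_id = {g.gene_id: g for g in genes_b}

    # ---- quiet-gene strata: promoter classes and ortholog-free genes -----
    # strata genes stay away from the inversion: its internal coordinate
    # reversal legitimately changes a promoter's nearest flanking orthologs,
    # which would defeat the synteny half of a planted conserved promoter
    inv_margin = 2 * cfg.chrom_length // cfg.genes_per_chrom
    inv_lo = zones.inversion[0] - inv_margin
    inv_hi = zones.inversion[1] + inv_margin
    quiet = [
        g.gene_id for g in genes_a
        if archetypes[g.gene_id] in ("uniform", "lowflat", "silent")
        and (cfg.identity_genomes or not inv_lo <= g.tss < inv_hi)
    ]
    quiet = [str(x) for x in rng.permutation(quiet)]
    i0 = 0
    prom_conserved = quiet[i0: i0 + cfg.n_conserved_open_prom]
    i0 += cfg.n_conserved_open_prom
    prom_a_spec = quiet[i0: i0 + cfg.n_a_specific_prom]
    i0 += cfg.n_a_specific_prom
    prom_b_spec = quiet[i0: i0 + cfg.n_b_specific_prom]
    i0 += cfg.n_b_specific_prom
    no_ortholog = set(quiet[i0: i0 + cfg.n_no_ortholog])
    if len(quiet) < i0 + cfg.n_no_ortholog:
        raise ValueError("not enough quiet genes outside the inversion for the strata")
    for g in prom_conserved:
        truth.promoter_class[g] = "conserved_open"
    for g in prom_a_spec:
        truth.promoter_class[g] = "a_specific_open"
    for g in prom_b_spec:
        truth.promoter_class[g] = "b_specific_open"
    if no_ortholog:
        dropped_b = {genes_by_id[g].ortholog_id for g in no_ortholog}
        genes_a = [
            GeneModel(g.gene_id, g.chrom, g.strand, g.tss, g.body, None)
            if g.gene_id in no_ortholog else g
            for g in genes_a
        ]
        genes_b = [
            GeneModel(g.gene_id, g.chrom, g.strand, g.tss, g.body, None)
            if g.gene_id in dropped_b else g
            for g in genes_b
        ]
        genes_by_id = {g.gene_id: g for g in genes_a}
        genes_b_by_id = {g.gene_id: g for g in genes_b}

    # ---- expression profiles ---------------------------------------------
    expr_a_log2 = pd.DataFrame(
        {g.gene_id: _gene_profile_a(archetypes[g.gene_id], cfg, rng) for g in genes_a},
        index=list(cfg.stages_a),
    ).T
    b_labels = {
        "gB" + g.gene_id[2:]: _b_label(archetypes[g.gene_id], n_stages)
        for g in genes_a
    }
    expr_b_log2 = pd.DataFrame.from_dict(
        {gid: _b_pattern(lab, cfg) for gid, lab in b_labels.items()},
        orient="index", columns=list(cfg.stages_b),
    )
    truth.gene_archetype_b = dict(b_labels)

    # ---- element placement ------------------------------------------------
    pool = _SlotPool(cfg, zones, genes_a, rng)
    peaks_a: list[DHSPeak] = []
    peaks_b: list[DHSPeak] = []
    acc_a_rows: dict[str, np.ndarray] = {}
    acc_b_rows: dict[str, np.ndarray] = {}
    open_thr = 1.0  # log2 FPKM openness threshold for profile-driven flags
    next_id = [0]

    def new_peak_a(chrom, start, length, cls, signal, open_flags) -> DHSPeak:
        pid = f"pA{next_id[0]:05d}"
        next_id[0] += 1
        peak = DHSPeak(
            GenomicInterval(chrom, start, start + length), pid,
            {s: bool(f) for s, f in zip(cfg.stages_a, open_flags)},
            {s: float(v) for s, v in zip(cfg.stages_a, signal)},
        )
        peaks_a.append(peak)
        acc_a_rows[pid] = np.asarray(signal, dtype=float)
        truth.element_class[pid] = cls
        return peak

    def add_partner(peak_a: DHSPeak, signal_b, open_b) -> str:
        res = lift_interval(peak_a.interval, chain_ab)
        if res.status != "unique":
            raise RuntimeError(f"element {peak_a.peak_id} does not lift uniquely")
        pid_b = "pB" + peak_a.peak_id[2:]
        peaks_b.append(
            DHSPeak(res.target, pid_b,
                    {s: bool(f) for s, f in zip(cfg.stages_b, open_b)},
                    {s: float(v) for s, v in zip(cfg.stages_b, signal_b)})
        )
        acc_b_rows[pid_b] = np.asarray(signal_b, dtype=float)
        truth.conserved_partners[peak_a.peak_id] = pid_b
        return pid_b

    flat_a = np.full(n_stages, np.log2(cfg.baseline_fpkm + 1))
    flat_b = np.full(3, np.log2(cfg.baseline_fpkm + 1))
    all_open_a = [True] * n_stages
    all_open_b = [True] * 3
    lo_log2 = np.log2(cfg.lo_fpkm + 1)

    def place_paired(gene: GeneModel, a_phase: str, cls: str,
                     max_dist: int = 500_000) -> DHSPeak:
        """Plant one element coupled to a gene's A profile; returns the peak."""
        prof = expr_a_log2.loc[gene.gene_id].to_numpy().copy() / cfg.coupling
        if a_phase == "early":
            prof[n_stages - 1] = np.log2(
                cfg.lo_fpkm * 2 ** rng.normal(0, cfg.signature_sd) + 1
            )
        elif a_phase == "late":
            prof[0] = np.log2(cfg.lo_fpkm * 2 ** rng.normal(0, cfg.signature_sd) + 1)
        zone_map = {
            "genome_specific": zones.gspec,
            "newly_emerged": zones.newly,
            "translocated": zones.trans,
        }
        for _ in range(300):
            if cls in zone_map:
                pos = pool.in_zone(gene.chrom, zone_map[cls])
            else:
                pos = pool.near(gene.chrom, gene.tss, max_dist)
            iv = GenomicInterval(gene.chrom, pos, pos + cfg.element_length)
            if abs(iv.midpoint - gene.tss) > 950_000:
                pool.release(gene.chrom, pos)
                continue
            if cls == "conserved" and gene.ortholog_id is not None:
                res = lift_interval(iv, chain_ab)
                gene_b = genes_b_by_id[gene.ortholog_id]
                if (
                    res.status != "unique"
                    or res.target.chrom != gene_b.chrom
                    or abs(res.target.midpoint - gene_b.tss) > 950_000
                    or not synteny_check(iv, res.target, genes_a, genes_b)
                ):
                    pool.release(gene.chrom, pos)
                    continue
            open_flags = prof >= open_thr
            peak = new_peak_a(gene.chrom, pos, cfg.element_length, cls, prof, open_flags)
            truth.pairs_a.append((gene.gene_id, peak.peak_id, a_phase))
            return peak
        raise RuntimeError("paired element placement failed")

    # ---- planted conserved paired elements --------------------------------
    dynamic_genes = [g for g in genes_a if archetypes[g.gene_id].startswith("b")]
    h_log2 = np.log2(cfg.hi_fpkm + 1)
    conserved_paired: list[tuple[DHSPeak, GeneModel, str, str]] = []  # peak, gene, a_phase, b_phase
    for gene in dynamic_genes:
        lab_a = archetypes[gene.gene_id]
        lab_b = b_labels[gene.ortholog_id]
        flank_bimodal_a = _is_flank_bimodal(lab_a, n_stages)
        n_elems = 4 if lab_b == "bimodal" else 2
        for j in range(n_elems):
            if flank_bimodal_a:
                a_phase = "early" if j < n_elems // 2 else "late"
            else:
                a_phase = "all"
            if lab_b == "bimodal":
                b_phase = "early" if j < n_elems // 2 else "late"
            else:
                b_phase = "all"
            peak = place_paired(gene, a_phase, "conserved")
            conserved_paired.append((peak, gene, a_phase, b_phase))

    for peak, gene, _a_phase, b_phase in conserved_paired:
        gid_b = gene.ortholog_id
        lab_b = b_labels[gid_b]
        if lab_b == "bimodal":
            sig_b = np.array([h_log2, lo_log2, lo_log2]) if b_phase == "early" \
                else np.array([lo_log2, lo_log2, h_log2])
        else:
            sig_b = _b_pattern(lab_b, cfg) / cfg.coupling
            # elements keep a low floor where the gene is fully silent
            sig_b = np.where(sig_b == 0, lo_log2, sig_b)
        open_b = sig_b >= open_thr
        add_partner(peak, sig_b, open_b)
        truth.pairs_b.append((gid_b, "pB" + peak.peak_id[2:], b_phase))

    # unpaired conserved elements (flat on both sides)
    n_unpaired_cons = cfg.n_conserved - len(conserved_paired)
    if n_unpaired_cons < 0:
        raise ValueError("n_conserved is smaller than the planted paired elements")
    for _ in range(n_unpaired_cons):
        chrom = f"chrA{int(rng.integers(cfg.n_chroms)) + 1}"
        pos = None
        for _attempt in range(200):
            pos = pool.anywhere(chrom)
            iv = GenomicInterval(chrom, pos, pos + cfg.element_length)
            res = lift_interval(iv, chain_ab)
            if res.status == "unique" and synteny_check(iv, res.target, genes_a, genes_b):
                break
            pool.release(chrom, pos)
        peak = new_peak_a(chrom, pos, cfg.element_length, "conserved", flat_a, all_open_a)
        add_partner(peak, flat_b, all_open_b)

    # promoter peaks: conserved-open and A-specific strata
    prom_sig_a = np.full(n_stages, np.log2(cfg.promoter_fpkm + 1))
    prom_sig_b = np.full(3, np.log2(cfg.promoter_fpkm + 1))
    for gid, cls, with_partner in (
        [(g, "promoter_conserved", True) for g in prom_conserved]
        + [(g, "promoter_a_specific", False) for g in prom_a_spec]
    ):
        gene = genes_by_id[gid]
        start = gene.tss - cfg.promoter_peak_length // 2
        peak = new_peak_a(gene.chrom, start, cfg.promoter_peak_length, cls,
                          prom_sig_a, all_open_a)
        if with_partner:
            add_partner(peak, prom_sig_b, all_open_b)

    # state-divergent elements: lift fine, B stays closed
    eligible_div = [
        g for g in dynamic_genes
        if len(_hi_stages(archetypes[g.gene_id], n_stages)) >= 2
        and not _wraps(archetypes[g.gene_id], n_stages)
    ]
    div_gene_ids = [str(x) for x in rng.permutation([g.gene_id for g in eligible_div])]
    n_div_open1 = max(0, cfg.n_state_divergent - cfg.n_divergent_paired) // 5
    placed_div = 0
    for j in range(cfg.n_divergent_paired):
        gene = genes_by_id[div_gene_ids[j % len(div_gene_ids)]]
        place_paired(gene, "all", "state_divergent")
        placed_div += 1
    while placed_div < cfg.n_state_divergent:
        chrom = f"chrA{int(rng.integers(cfg.n_chroms)) + 1}"
        pos = pool.anywhere(chrom)
        iv = GenomicInterval(chrom, pos, pos + cfg.element_length)
        if lift_interval(iv, chain_ab).status != "unique":
            pool.release(chrom, pos)
            continue
        if placed_div < cfg.n_state_divergent - n_div_open1:
            n_open = int(rng.integers(2, n_stages + 1))
        else:
            n_open = 1
        flags = np.zeros(n_stages, dtype=bool)
        flags[rng.choice(n_stages, size=n_open, replace=False)] = True
        new_peak_a(chrom, pos, cfg.element_length, "state_divergent", flat_a, flags)
        placed_div += 1

    # ---- zone-bound classes ----------------------------------------------
    plain_dynamic = [
        g for g in dynamic_genes if not _wraps(archetypes[g.gene_id], n_stages)
    ]

    def nearest_plain_gene(chrom: str, center: int) -> GeneModel:
        cands = sorted(
            (g for g in plain_dynamic if g.chrom == chrom),
            key=lambda g: abs(g.tss - center),
        )
        for g in cands:
            if abs(g.tss - center) < 900_000:
                return g
        raise RuntimeError("no dynamic gene near zone")

    def fill_zone(cls: str, zone: tuple[int, int], total: int, paired: int):
        per_chrom = np.diff(np.linspace(0, total, cfg.n_chroms + 1).astype(int))
        k = 0
        for i in range(cfg.n_chroms):
            chrom = f"chrA{i + 1}"
            for _ in range(int(per_chrom[i])):
                if k < paired:
                    gene = nearest_plain_gene(chrom, (zone[0] + zone[1]) // 2)
                    place_paired(gene, "all", cls)
                else:
                    pos = pool.in_zone(chrom, zone)
                    new_peak_a(chrom, pos, cfg.element_length, cls, flat_a, all_open_a)
                k += 1

    if not cfg.identity_genomes:
        fill_zone("newly_emerged", zones.newly, cfg.n_newly_emerged, cfg.n_newly_paired)
        fill_zone("genome_specific", zones.gspec, cfg.n_genome_specific, cfg.n_gspec_paired)
        fill_zone("translocated", zones.trans, cfg.n_translocated, cfg.n_transloc_paired)
        # translocated elements get B partners at the translocated locus so
        # reciprocal overlap passes and only synteny rejects them
        for peak in list(peaks_a):
            if truth.element_class[peak.peak_id] == "translocated":
                add_partner(peak, flat_b, all_open_b)
                del truth.conserved_partners[peak.peak_id]
        for i in range(cfg.n_chroms):
            chrom = f"chrA{i + 1}"
            for _ in range(cfg.n_multi_hit // cfg.n_chroms):
                pos = pool.in_zone(chrom, zones.dup)
                peak = new_peak_a(chrom, pos, cfg.element_length, "multi_hit",
                                  flat_a, all_open_a)
                truth.removed_multi.append(peak.peak_id)

    # ---- B-only peaks ------------------------------------------------------
    bid = [0]

    def new_peak_b(chrom, start, length, signal, open_flags):
        pid = f"pBs{bid[0]:04d}"
        bid[0] += 1
        peaks_b.append(
            DHSPeak(GenomicInterval(chrom, start, start + length), pid,
                    {s: bool(f) for s, f in zip(cfg.stages_b, open_flags)},
                    {s: float(v) for s, v in zip(cfg.stages_b, signal)})
        )
        acc_b_rows[pid] = np.asarray(signal, dtype=float)

    for gid in prom_b_spec:
        gene_b = genes_b_by_id["gB" + gid[2:]]
        start = gene_b.tss - cfg.promoter_peak_length // 2
        new_peak_b(gene_b.chrom, start, cfg.promoter_peak_length, prom_sig_b, all_open_b)
    if not cfg.identity_genomes and cfg.n_b_specific_distal:
        per_chrom = np.diff(
            np.linspace(0, cfg.n_b_specific_distal, cfg.n_chroms + 1).astype(int)
        )
        for i in range(cfg.n_chroms):
            cb = f"chrB{i + 1}"
            ins_start = None
            for blk in chain_ab.blocks:
                if blk.tgt_chrom == cb and blk.src_end == zones.b_insert_pos \
                        and blk.strand == "+" and blk.src_start >= zones.trans[1]:
                    ins_start = blk.tgt_end  # insertion begins where this block ends
            used_b: set[int] = set()
            for _ in range(int(per_chrom[i])):
                for _a in range(400):
                    pos = ins_start + int(
                        rng.integers(200, zones.b_insert_len - cfg.element_length - 200)
                    )
                    pos = pos // 500 * 500
                    if pos not in used_b:
                        used_b.add(pos)
                        break
                new_peak_b(cb, pos, cfg.element_length, flat_b, all_open_b)

    truth.species_specific_open_a = sorted(
        p.peak_id for p in peaks_a
        if truth.element_class[p.peak_id] in ("state_divergent", "promoter_a_specific")
        and p.n_open_stages >= 2
    )

    # ---- emitted matrices (FPKM scale, optional measurement noise) -------
    def emit(log2_rows: dict[str, np.ndarray], stages) -> pd.DataFrame:
        ids = sorted(log2_rows)
        arr = np.stack([log2_rows[i] for i in ids]).astype(float)
        if cfg.noise_sd > 0:
            arr = arr + rng.normal(0, cfg.noise_sd, size=arr.shape)
        return pd.DataFrame(
            np.maximum(2.0**arr - 1.0, 0.0), index=ids, columns=list(stages)
        )

    expr_a = emit({g: expr_a_log2.loc[g].to_numpy() for g in expr_a_log2.index},
                  cfg.stages_a)
    expr_b = emit({g: expr_b_log2.loc[g].to_numpy() for g in expr_b_log2.index},
                  cfg.stages_b)
    acc_a = emit(acc_a_rows, cfg.stages_a)
    acc_b = emit(acc_b_rows, cfg.stages_b)

    # ---- SNPs --------------------------------------------------------------
    positions: set[tuple[str, int]] = set()
    for i in range(cfg.n_chroms):
        chrom = f"chrA{i + 1}"
        n = int(rng.poisson(cfg.chrom_length / 1000 * cfg.snp_per_kb))
        for pos in rng.integers(0, cfg.chrom_length, size=n):
            positions.add((chrom, int(pos)))
    extra_rate = cfg.snp_per_kb * (cfg.snp_enriched_fold - 1.0)
    for peak in peaks_a:
        if truth.element_class[peak.peak_id] == "newly_emerged":
            n = int(rng.poisson(peak.interval.length / 1000 * extra_rate))
            for pos in rng.integers(peak.interval.start, peak.interval.end, size=n):
                positions.add((peak.interval.chrom, int(pos)))
    snps = SnpCatalog(positions, source="synthetic")

    # ---- CpG sites and methylation -----------------------------------------
    cpg_sites: list[CpGSite] = []
    rich = set(sorted(g.gene_id for g in genes_a)[0::2])
    for g in genes_a:
        promoter = derive_promoter(g, assembly_a)
        is_rich = g.gene_id in rich
        dens = cfg.cpg_rich_per_100bp if is_rich else cfg.cpg_poor_per_100bp
        n_sites = int(rng.poisson(dens * promoter.length / 100))
        a, b = cfg.meth_rich_beta if is_rich else cfg.meth_poor_beta
        p_meth = rng.beta(a, b)
        site_pos = np.unique(rng.integers(promoter.start, promoter.end, size=n_sites))
        for pos in site_pos:
            cov = max(1, int(rng.poisson(cfg.coverage_mean)))
            meth = int(rng.binomial(cov, p_meth))
            cpg_sites.append(CpGSite(g.chrom, int(pos), meth, cov))
        (truth.cpg_rich_genes if is_rich else truth.cpg_poor_genes).append(g.gene_id)

    # ---- GO terms ------------------------------------------------------------
    universe = [g.gene_id for g in genes_a]
    stage0_active = sorted(
        g for g, lab in archetypes.items()
        if lab.startswith("b") and 0 in _hi_stages(lab, n_stages)
    )
    n_core = max(5, len(stage0_active) * 3 // 4)
    planted_members = set(stage0_active[:n_core])
    planted_members |= {str(x) for x in rng.choice(universe, size=5, replace=False)}
    go_terms = [GoTerm("GO:PLANTED", frozenset(planted_members))]
    for t in range(cfg.n_go_terms - 1):
        size = int(rng.integers(10, 41))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        go_terms.append(GoTerm(f"GO:{t + 1:07d}", frozenset(str(m) for m in members)))

    # ---- Hi-C interactions ----------------------------------------------------
    interactions: list[InteractionRecord] = []
    peaks_by_id = {p.peak_id: p for p in peaks_a}
    for gene_id, pid, _phase in truth.pairs_a:
        if rng.random() < cfg.hic_fraction:
            gene_m = genes_by_id[gene_id]
            peak = peaks_by_id[pid]
            anchor1 = assembly_a.clip(GenomicInterval(
                peak.interval.chrom,
                max(0, peak.interval.start - 2000),
                peak.interval.end + 2000,
            ))
            anchor2 = derive_promoter(gene_m, assembly_a)
            interactions.append(InteractionRecord(anchor1, anchor2))
            truth.hic_pairs.append((gene_id, pid))
    for _ in range(cfg.n_hic_noise):
        chrom = f"chrA{int(rng.integers(cfg.n_chroms)) + 1}"
        a = int(rng.integers(10_000, cfg.chrom_length - 60_000))
        b = a + int(rng.integers(20_000, 50_000))
        interactions.append(InteractionRecord(
            GenomicInterval(chrom, a, a + 4000), GenomicInterval(chrom, b, b + 4000)))

    return SimulatedDataset(
        config=cfg,
        assembly_a=assembly_a, assembly_b=assembly_b,
        genes_a=genes_a, genes_b=genes_b,
        peaks_a=peaks_a, peaks_b=peaks_b,
        chain_ab=chain_ab, chain_ba=chain_ba, outgroup_chains=og_chains,
        expr_a=expr_a, expr_b=expr_b, acc_a=acc_a, acc_b=acc_b,
        snps=snps, cpg_sites=cpg_sites, go_terms=go_terms,
        interactions=interactions, truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the dataset in the plain-text dialects the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_assembly(ds.assembly_a, out / "assembly_a.tsv")
    cio.write_assembly(ds.assembly_b, out / "assembly_b.tsv")
    cio.write_genes(ds.genes_a, out / "genes_a.tsv")
    cio.write_genes(ds.genes_b, out / "genes_b.tsv")
    cio.write_peaks(ds.peaks_a, out / "peaks_a.bed", out / "peaks_a_stages.tsv",
                    stages=list(ds.config.stages_a))
    cio.write_peaks(ds.peaks_b, out / "peaks_b.bed", out / "peaks_b_stages.tsv",
                    stages=list(ds.config.stages_b))
    cio.write_block_map(ds.chain_ab, out / "chain_a_to_b.tsv")
    cio.write_block_map(ds.chain_ba, out / "chain_b_to_a.tsv")
    for name, chain in ds.outgroup_chains.items():
        cio.write_block_map(chain, out / f"chain_a_to_{name}.tsv")
    cio.write_matrix(ds.expr_a, out / "expr_a_fpkm.tsv")
    cio.write_matrix(ds.expr_b, out / "expr_b_fpkm.tsv")
    cio.write_matrix(ds.acc_a, out / "acc_a_fpkm.tsv")
    cio.write_matrix(ds.acc_b, out / "acc_b_fpkm.tsv")
    cio.write_snps(ds.snps, out / "snps.tsv")
    cio.write_cpg_sites(ds.cpg_sites, out / "cpg_sites_a.tsv")
    cio.write_go_terms(ds.go_terms, out / "go_terms.tsv")
    cio.write_interactions(ds.interactions, out / "hic_a.tsv")
    cio.write_json(ds.truth.to_json(), out / "truth.json")
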