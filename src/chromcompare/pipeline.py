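"""End-to-end orchestration: annotate -> normalize -> dynamics -> pair ->
crossmap -> groups -> enrich.

The pipeline is a pure function of (inputs, parameters, seed): stage outputs
are written as deterministic TSVs and a re-run with the same configuration
reproduces them byte for byte.  ``analyze`` computes everything in memory;
``run_pipeline`` wraps it with file loading, stage output writing and a run
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from . import io as cio
from .crossmap import ChainMap, ConservationCall, conservation_calls, promoter_conservation
from .dynamics import DynamicsTable, compute_dynamics
from .enrichment import (
    GoTerm,
    SnpCatalog,
    enrichment_trend,
    go_enrichment,
    snp_associated_genes,
    snp_frequency,
)
from .genome import (
    CpGSite,
    DHSPeak,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    annotate_peaks,
    classify_promoter_openness,
    derive_promoter,
    promoter_cpg_density,
    promoter_methylation_level,
)
from .pairing import InteractionRecord, RegPair, hic_support, pair_elements, stage_masked_pairing
from .pair_groups import (
    classify_groups,
    compare_pair_distances,
    cross_species_signal_consistency,
)
from .quantify import StageMatrix, log2_transform, quantile_normalize

__all__ = [
    "PipelineParams",
    "PipelineInputs",
    "PipelineResults",
    "RunManifest",
    "STAGE_ORDER",
    "analyze",
    "run_pipeline",
    "inputs_from_dataset",
    "default_config",
]

STAGE_ORDER = ["annotate", "normalize", "dynamics", "pair", "crossmap", "groups", "enrich"]


@dataclass
class PipelineParams:
    """All tunable thresholds with their literature defaults."""

    promoter_flank: int = 2000
    distal_flank: int = 998_000
    pad: int = 500
    r_min: float = 0.8
    p_max: float = 0.05
    min_overlap_frac: float = 0.5
    min_mapped: float = 0.95
    min_open_stages_a: int = 2
    min_open_stages_b: int = 1
    expressed_min_fpkm: float = 1.0
    log_pseudocount: float = 1.0
    entropy_threshold_a: float | None = None  # default looked up from stage count
    entropy_threshold_b: float | None = None
    kmeans_k: int = 6
    seed: int = 0
    # species-A stage indices folded onto each species-B stage
    stage_groups: tuple[tuple[int, ...], ...] = ((0, 1), (2, 3), (4, 5))


@dataclass
class PipelineInputs:
    assembly_a: GenomeAssembly
    assembly_b: GenomeAssembly
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    peaks_a: list[DHSPeak]
    peaks_b: list[DHSPeak]
    chain_ab: ChainMap
    chain_ba: ChainMap
    outgroup_chains: dict[str, ChainMap]
    expr_a: pd.DataFrame
    expr_b: pd.DataFrame
    acc_a: pd.DataFrame
    acc_b: pd.DataFrame
    snps: SnpCatalog | None = None
    cpg_sites: list[CpGSite] = field(default_factory=list)
    go_terms: list[GoTerm] = field(default_factory=list)
    interactions: list[InteractionRecord] = field(default_factory=list)


@dataclass
class PipelineResults:
    peak_categories_a: dict[str, str]
    peak_categories_b: dict[str, str]
    promoter_openness_a: pd.DataFrame
    promoter_openness_b: pd.DataFrame
    promoter_conservation: pd.DataFrame
    promoter_cpg_meth: pd.DataFrame
    acc_a_qnorm: pd.DataFrame
    acc_b_qnorm: pd.DataFrame
    expr_a_qnorm: pd.DataFrame
    expr_b_qnorm: pd.DataFrame
    dynamics_a: DynamicsTable
    dynamics_b: DynamicsTable
    pairs_a: list[RegPair]
    pairs_b: list[RegPair]
    conservation_a: dict[str, ConservationCall]
    removed_a: list[str]
    conservation_b: dict[str, ConservationCall]
    removed_b: list[str]
    groups: pd.DataFrame
    snp_enrichment: pd.DataFrame | None
    snp_trend_slope: float | None
    snp_frequency_by_class: pd.DataFrame | None
    snp_associated: set[str]
    go_results: pd.DataFrame | None


def _overlapping_peaks(promoter: GenomicInterval, peaks_sorted, starts) -> list[DHSPeak]:
    import bisect

    hi = bisect.bisect_left(starts, promoter.end)
    out = []
    for p in peaks_sorted[max(0, hi - 64): hi]:
        if p.interval.end > promoter.start:
            out.append(p)
    return out


def _promoter_openness(
    genes: Sequence[GeneModel],
    peaks: Sequence[DHSPeak],
    assembly: GenomeAssembly,
    stages: Sequence[str],
    flank: int,
) -> pd.DataFrame:
    by_chrom: dict[str, list[DHSPeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    starts_by_chrom = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.interval.start)
        starts_by_chrom[chrom] = [p.interval.start for p in by_chrom[chrom]]
    rows = {}
    for g in genes:
        promoter = derive_promoter(g, assembly, flank)
        nearby = _overlapping_peaks(
            promoter, by_chrom.get(g.chrom, []), starts_by_chrom.get(g.chrom, [])
        )
        rows[g.gene_id] = classify_promoter_openness(promoter, nearby, stages)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(stages))
    df.index.name = "gene_id"
    return df.sort_index()


def analyze(inputs: PipelineInputs, params: PipelineParams | None = None) -> PipelineResults:
    """Run every analysis stage in memory."""
    params = params or PipelineParams()
    stages_a = list(inputs.expr_a.columns)
    stages_b = list(inputs.expr_b.columns)

    # ---- annotate ----------------------------------------------------------
    cat_a = annotate_peaks(inputs.peaks_a, inputs.genes_a, inputs.assembly_a,
                           params.promoter_flank)
    cat_b = annotate_peaks(inputs.peaks_b, inputs.genes_b, inputs.assembly_b,
                           params.promoter_flank)
    open_a = _promoter_openness(inputs.genes_a, inputs.peaks_a, inputs.assembly_a,
                                stages_a, params.promoter_flank)
    open_b = _promoter_openness(inputs.genes_b, inputs.peaks_b, inputs.assembly_b,
                                stages_b, params.promoter_flank)
    prom_rows = []
    for g in inputs.genes_a:
        if g.ortholog_id is None or g.ortholog_id not in open_b.index:
            continue
        label = promoter_conservation(
            open_a.loc[g.gene_id].to_dict(), open_b.loc[g.ortholog_id].to_dict()
        )
        prom_rows.append((g.gene_id, g.ortholog_id, label))
    prom_cons = pd.DataFrame(prom_rows, columns=["gene_id_a", "gene_id_b", "promoter_class"])

    cpg_by_chrom: dict[str, list[CpGSite]] = {}
    for s in inputs.cpg_sites:
        cpg_by_chrom.setdefault(s.chrom, []).append(s)
    cpg_rows = []
    for g in inputs.genes_a:
        promoter = derive_promoter(g, inputs.assembly_a, params.promoter_flank)
        sites = [s for s in cpg_by_chrom.get(g.chrom, [])
                 if promoter.start <= s.position < promoter.end]
        dens = promoter_cpg_density(promoter, [s.position for s in sites])
        ml = promoter_methylation_level(promoter, sites)
        cpg_rows.append((g.gene_id, dens, np.nan if ml is None else ml))
    cpg_df = pd.DataFrame(cpg_rows, columns=["gene_id", "cpg_per_100bp", "methylation"])

    # ---- normalize ---------------------------------------------------------
    def qn(df: pd.DataFrame) -> pd.DataFrame:
        m = StageMatrix(df, scale="fpkm")
        return quantile_normalize(log2_transform(m, params.log_pseudocount)).values

    acc_a_q, acc_b_q = qn(inputs.acc_a), qn(inputs.acc_b)
    expr_a_q, expr_b_q = qn(inputs.expr_a), qn(inputs.expr_b)

    # ---- dynamics ----------------------------------------------------------
    dyn_a = compute_dynamics(expr_a_q, params.entropy_threshold_a,
                             k=params.kmeans_k, seed=params.seed)
    dyn_b = compute_dynamics(expr_b_q, params.entropy_threshold_b,
                             k=params.kmeans_k, seed=params.seed)

    # ---- pair --------------------------------------------------------------
    def run_pairing(genes, peaks, acc_q, expr_q, assembly, dyn: DynamicsTable):
        gene_by_id = {g.gene_id: g for g in genes}
        specific = [gene_by_id[g] for g in dyn.stage_specific_genes if g in gene_by_id]
        pairs = pair_elements(
            specific, peaks, acc_q, expr_q, assembly,
            distal_flank=params.distal_flank, r_min=params.r_min, p_max=params.p_max,
        )
        for gid in dyn.bimodal_genes():
            gene = gene_by_id.get(gid)
            if gene is None:
                continue
            try:
                early, late = stage_masked_pairing(
                    gene, peaks, acc_q, expr_q, assembly,
                    distal_flank=params.distal_flank,
                    r_min=params.r_min, p_max=params.p_max,
                )
            except ValueError:
                continue
            pairs.extend(early)
            pairs.extend(late)
        return pairs

    pairs_a = run_pairing(inputs.genes_a, inputs.peaks_a, acc_a_q, expr_a_q,
                          inputs.assembly_a, dyn_a)
    pairs_b = run_pairing(inputs.genes_b, inputs.peaks_b, acc_b_q, expr_b_q,
                          inputs.assembly_b, dyn_b)
    if inputs.interactions:
        peaks_a_by_id = {p.peak_id: p for p in inputs.peaks_a}
        genes_a_by_id = {g.gene_id: g for g in inputs.genes_a}
        pairs_a = [
            RegPair(
                p.peak_id, p.gene_id, p.pearson_r, p.p_value, p.phase,
                hic_support(
                    peaks_a_by_id[p.peak_id].interval,
                    derive_promoter(genes_a_by_id[p.gene_id], inputs.assembly_a,
                                    params.promoter_flank),
                    inputs.interactions,
                ),
            )
            for p in pairs_a
        ]

    # ---- crossmap ----------------------------------------------------------
    outgroups_for_a = {"speciesB": inputs.chain_ab, **inputs.outgroup_chains}
    cons_a, removed_a = conservation_calls(
        inputs.peaks_a, inputs.peaks_b, inputs.chain_ab, inputs.chain_ba,
        inputs.genes_a, inputs.genes_b, inputs.assembly_a, inputs.assembly_b,
        outgroup_chains=outgroups_for_a,
        min_frac=params.min_overlap_frac, pad=params.pad,
        min_mapped=params.min_mapped, min_open_stages_a=params.min_open_stages_a,
    )
    cons_b, removed_b = conservation_calls(
        inputs.peaks_b, inputs.peaks_a, inputs.chain_ba, inputs.chain_ab,
        inputs.genes_b, inputs.genes_a, inputs.assembly_b, inputs.assembly_a,
        outgroup_chains=None,
        min_frac=params.min_overlap_frac, pad=params.pad,
        min_mapped=params.min_mapped, min_open_stages_a=params.min_open_stages_b,
    )

    # ---- groups ------------------------------------------------------------
    ortholog_map = {g.gene_id: g.ortholog_id for g in inputs.genes_a
                    if g.ortholog_id is not None}
    consistency = {}
    for pid, call in cons_a.items():
        if call.peak_id_b and pid in acc_a_q.index and call.peak_id_b in acc_b_q.index:
            consistency[pid] = cross_species_signal_consistency(
                acc_a_q.loc[pid].to_numpy(), acc_b_q.loc[call.peak_id_b].to_numpy(),
                params.stage_groups,
            )
    grouped = classify_groups(pairs_a, pairs_b, cons_a, ortholog_map,
                              signal_consistency=consistency, r_min=params.r_min)
    peaks_a_by_id = {p.peak_id: p for p in inputs.peaks_a}
    genes_a_by_id = {g.gene_id: g for g in inputs.genes_a}
    tss_b = {g.gene_id: g.tss for g in inputs.genes_b}
    group_rows = []
    for gp in grouped:
        element = peaks_a_by_id[gp.peak_id].interval
        gene = genes_a_by_id[gp.gene_id]
        ortholog = ortholog_map.get(gp.gene_id)
        d_native, d_lifted = compare_pair_distances(
            element, gene.tss, inputs.chain_ab, tss_b.get(ortholog),
            min_mapped=params.min_mapped,
        )
        group_rows.append((
            gp.peak_id, gp.gene_id, gp.group, gp.subcategory or "NA",
            d_native, np.nan if d_lifted is None else d_lifted,
        ))
    groups_df = pd.DataFrame(
        group_rows,
        columns=["peak_id", "gene_id", "group", "subcategory",
                 "distance_native", "distance_lifted"],
    ).sort_values(["peak_id", "gene_id"], kind="stable").reset_index(drop=True)

    # ---- enrich ------------------------------------------------------------
    snp_df = trend_slope = freq_df = go_df = None
    snp_assoc: set[str] = set()
    if inputs.snps is not None and inputs.snps.total > 0:
        stage_sets = {
            s: [p.interval for p in inputs.peaks_a if p.open_by_stage.get(s, False)]
            for s in stages_a
        }
        stage_sets = {s: ivs for s, ivs in stage_sets.items() if ivs}
        if len(stage_sets) >= 2:
            trend = enrichment_trend(stage_sets, inputs.snps, inputs.assembly_a)
            trend_slope = trend.slope
            snp_df = pd.DataFrame(
                [(s, trend.es_by_stage[s]) for s in stage_sets],
                columns=["stage", "es"],
            )
            snp_df["enriched"] = snp_df["es"] >= 1.5

        freq_rows = [
            (p.peak_id, cons_a[p.peak_id].category,
             cons_a[p.peak_id].newly_emerged,
             snp_frequency(p.interval, inputs.snps))
            for p in inputs.peaks_a if p.peak_id in cons_a
        ]
        freq_df = pd.DataFrame(
            freq_rows, columns=["peak_id", "category", "newly_emerged", "snp_per_kb"]
        )

        expressed = {
            g.gene_id: bool(inputs.expr_a.loc[g.gene_id].max() >= params.expressed_min_fpkm)
            for g in inputs.genes_a if g.gene_id in inputs.expr_a.index
        }
        promoter_open_any = {g: bool(open_a.loc[g].any()) for g in open_a.index}
        pairs_by_gene: dict[str, list[str]] = {}
        for p in pairs_a:
            pairs_by_gene.setdefault(p.gene_id, []).append(p.peak_id)
        snp_assoc = snp_associated_genes(
            inputs.genes_a, expressed, promoter_open_any, pairs_by_gene,
            peaks_a_by_id, inputs.snps, inputs.assembly_a, params.promoter_flank,
        )
        if inputs.go_terms and snp_assoc:
            universe = {g.gene_id for g in inputs.genes_a}
            res = go_enrichment(snp_assoc & universe, inputs.go_terms, universe)
            go_df = pd.DataFrame(
                [(r.label, r.es, r.p_value, r.q_value) for r in res],
                columns=["term_id", "es", "p", "q"],
            ).sort_values("p", kind="stable").reset_index(drop=True)

    return PipelineResults(
        peak_categories_a=cat_a, peak_categories_b=cat_b,
        promoter_openness_a=open_a, promoter_openness_b=open_b,
        promoter_conservation=prom_cons, promoter_cpg_meth=cpg_df,
        acc_a_qnorm=acc_a_q, acc_b_qnorm=acc_b_q,
        expr_a_qnorm=expr_a_q, expr_b_qnorm=expr_b_q,
        dynamics_a=dyn_a, dynamics_b=dyn_b,
        pairs_a=pairs_a, pairs_b=pairs_b,
        conservation_a=cons_a, removed_a=removed_a,
        conservation_b=cons_b, removed_b=removed_b,
        groups=groups_df,
        snp_enrichment=snp_df, snp_trend_slope=trend_slope,
        snp_frequency_by_class=freq_df,
        snp_associated=snp_assoc, go_results=go_df,
    )


# --------------------------------------------------------------------------
# file-based run


def default_config(data_dir: str | Path, out_dir: str | Path, seed: int = 0) -> dict:
    """Configuration dictionary pointing at a dataset directory's dialects."""
    d = Path(data_dir)
    cfg: dict = {
        "seed": seed,
        "out_dir": str(out_dir),
        "species_a": {
            "assembly": str(d / "assembly_a.tsv"),
            "genes": str(d / "genes_a.tsv"),
            "peaks_bed": str(d / "peaks_a.bed"),
            "peaks_stages": str(d / "peaks_a_stages.tsv"),
            "expr": str(d / "expr_a_fpkm.tsv"),
            "acc": str(d / "acc_a_fpkm.tsv"),
        },
        "species_b": {
            "assembly": str(d / "assembly_b.tsv"),
            "genes": str(d / "genes_b.tsv"),
            "peaks_bed": str(d / "peaks_b.bed"),
            "peaks_stages": str(d / "peaks_b_stages.tsv"),
            "expr": str(d / "expr_b_fpkm.tsv"),
            "acc": str(d / "acc_b_fpkm.tsv"),
        },
        "chain_ab": str(d / "chain_a_to_b.tsv"),
        "chain_ba": str(d / "chain_b_to_a.tsv"),
        "outgroup_chains": {
            p.stem.replace("chain_a_to_", ""): str(p)
            for p in sorted(d.glob("chain_a_to_og*.tsv"))
        },
        "snps": str(d / "snps.tsv"),
        "cpg_sites": str(d / "cpg_sites_a.tsv"),
        "go_terms": str(d / "go_terms.tsv"),
        "interactions": str(d / "hic_a.tsv"),
        "params": {},
    }
    return cfg


def load_inputs(config: Mapping) -> PipelineInputs:
    a, b = config["species_a"], config["species_b"]
    for key in ("assembly", "genes", "peaks_bed", "peaks_stages", "expr", "acc"):
        for side in (a, b):
            if not Path(side[key]).exists():
                raise FileNotFoundError(f"missing input file: {side[key]}")
    chain_ab = cio.read_block_map(config["chain_ab"])
    chain_ba = (
        cio.read_block_map(config["chain_ba"])
        if config.get("chain_ba") and Path(config["chain_ba"]).exists()
        else chain_ab.invert()
    )
    outgroups = {
        name: cio.read_block_map(path)
        for name, path in config.get("outgroup_chains", {}).items()
    }
    snps = None
    if config.get("snps") and Path(config["snps"]).exists():
        snps = cio.read_snps(config["snps"])
    cpg = (cio.read_cpg_sites(config["cpg_sites"])
           if config.get("cpg_sites") and Path(config["cpg_sites"]).exists() else [])
    go = (cio.read_go_terms(config["go_terms"])
          if config.get("go_terms") and Path(config["go_terms"]).exists() else [])
    hic = (cio.read_interactions(config["interactions"])
           if config.get("interactions") and Path(config["interactions"]).exists() else [])
    return PipelineInputs(
        assembly_a=cio.read_assembly(a["assembly"], "speciesA"),
        assembly_b=cio.read_assembly(b["assembly"], "speciesB"),
        genes_a=cio.read_genes(a["genes"]),
        genes_b=cio.read_genes(b["genes"]),
        peaks_a=cio.read_peaks(a["peaks_bed"], a["peaks_stages"]),
        peaks_b=cio.read_peaks(b["peaks_bed"], b["peaks_stages"]),
        chain_ab=chain_ab, chain_ba=chain_ba, outgroup_chains=outgroups,
        expr_a=cio.read_matrix(a["expr"]), expr_b=cio.read_matrix(b["expr"]),
        acc_a=cio.read_matrix(a["acc"]), acc_b=cio.read_matrix(b["acc"]),
        snps=snps, cpg_sites=cpg, go_terms=go, interactions=hic,
    )


def inputs_from_dataset(ds) -> PipelineInputs:
    """Adapter from a :class:`chromcompare.simulate.SimulatedDataset`."""
    return PipelineInputs(
        assembly_a=ds.assembly_a, assembly_b=ds.assembly_b,
        genes_a=ds.genes_a, genes_b=ds.genes_b,
        peaks_a=ds.peaks_a, peaks_b=ds.peaks_b,
        chain_ab=ds.chain_ab, chain_ba=ds.chain_ba,
        outgroup_chains=ds.outgroup_chains,
        expr_a=ds.expr_a, expr_b=ds.expr_b, acc_a=ds.acc_a, acc_b=ds.acc_b,
        snps=ds.snps, cpg_sites=ds.cpg_sites, go_terms=ds.go_terms,
        interactions=ds.interactions,
    )


@dataclass
class RunManifest:
    config_hash: str
    input_hashes: dict[str, str]
    counts: dict[str, int]
    package_version: str
    timestamp: str

    def to_json(self) -> dict:
        return asdict_manifest(self)


def asdict_manifest(m: RunManifest) -> dict:
    return {
        "config_hash": m.config_hash,
        "input_hashes": m.input_hashes,
        "counts": m.counts,
        "package_version": m.package_version,
        "timestamp": m.timestamp,
    }


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _bool_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.astype(int)


def write_results(results: PipelineResults, out: Path,
                  start_index: int = 0) -> dict[str, int]:
    """Write per-stage outputs; returns row counts.  ``start_index`` skips
    writing outputs of stages earlier in :data:`STAGE_ORDER`."""
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage_on(name: str) -> bool:
        return STAGE_ORDER.index(name) >= start_index

    if stage_on("annotate"):
        for species, cats in (("a", results.peak_categories_a),
                              ("b", results.peak_categories_b)):
            df = pd.DataFrame(sorted(cats.items()), columns=["peak_id", "category"])
            df.to_csv(out / f"peak_categories_{species}.tsv", sep="\t", index=False)
            counts[f"peak_categories_{species}"] = len(df)
        _bool_frame(results.promoter_openness_a).to_csv(
            out / "promoter_openness_a.tsv", sep="\t")
        _bool_frame(results.promoter_openness_b).to_csv(
            out / "promoter_openness_b.tsv", sep="\t")
        results.promoter_conservation.to_csv(
            out / "promoter_conservation.tsv", sep="\t", index=False)
        results.promoter_cpg_meth.to_csv(
            out / "promoter_cpg_meth_a.tsv", sep="\t", index=False,
            float_format="%.6g")
        counts["promoter_conservation"] = len(results.promoter_conservation)
    if stage_on("normalize"):
        for name, df in (
            ("acc_a_qnorm", results.acc_a_qnorm), ("acc_b_qnorm", results.acc_b_qnorm),
            ("expr_a_qnorm", results.expr_a_qnorm), ("expr_b_qnorm", results.expr_b_qnorm),
        ):
            cio.write_matrix(df, out / f"{name}.tsv")
            counts[name] = len(df)
    if stage_on("dynamics"):
        for species, dyn in (("a", results.dynamics_a), ("b", results.dynamics_b)):
            table = dyn.table.copy()
            table.to_csv(out / f"dynamics_{species}.tsv", sep="\t", float_format="%.6g")
            dyn.scaled.to_csv(out / f"dynamics_scaled_{species}.tsv", sep="\t",
                              float_format="%.6g")
            counts[f"dynamics_{species}_stage_specific"] = len(dyn.stage_specific_genes)
    if stage_on("pair"):
        for species, pairs in (("a", results.pairs_a), ("b", results.pairs_b)):
            rows = [
                (p.peak_id, p.gene_id, p.pearson_r, p.p_value, p.phase,
                 "NA" if p.hic_supported is None else int(p.hic_supported))
                for p in pairs
            ]
            df = pd.DataFrame(rows, columns=["peak_id", "gene_id", "r", "p",
                                             "phase", "hic_supported"])
            df = df.sort_values(["gene_id", "peak_id", "phase"], kind="stable")
            df.to_csv(out / f"pairs_{species}.tsv", sep="\t", index=False,
                      float_format="%.6g")
            counts[f"pairs_{species}"] = len(df)
    if stage_on("crossmap"):
        for species, calls, removed in (
            ("a", results.conservation_a, results.removed_a),
            ("b", results.conservation_b, results.removed_b),
        ):
            rows = [
                (c.peak_id_a, c.peak_id_b or "NA", c.category, c.lift_class,
                 int(c.species_specific_open), int(c.newly_emerged))
                for c in sorted(calls.values(), key=lambda c: c.peak_id_a)
            ]
            df = pd.DataFrame(rows, columns=[
                "peak_id", "partner_id", "category", "lift_class",
                "species_specific_open", "newly_emerged"])
            df.to_csv(out / f"conservation_{species}.tsv", sep="\t", index=False)
            with open(out / f"removed_multi_{species}.txt", "w") as fh:
                fh.write("".join(f"{pid}\n" for pid in sorted(removed)))
            counts[f"conserved_pairs_{species}"] = sum(
                1 for c in calls.values() if c.category == "conserved_pair")
            counts[f"removed_multi_{species}"] = len(removed)
    if stage_on("groups"):
        results.groups.to_csv(out / "groups_a.tsv", sep="\t", index=False,
                              float_format="%.6g")
        for label in ("I", "II", "III"):
            counts[f"group_{label}"] = int((results.groups["group"] == label).sum())
    if stage_on("enrich"):
        if results.snp_enrichment is not None:
            results.snp_enrichment.to_csv(out / "snp_enrichment_by_stage_a.tsv",
                                          sep="\t", index=False, float_format="%.6g")
        if results.snp_frequency_by_class is not None:
            results.snp_frequency_by_class.to_csv(
                out / "snp_frequency_by_class_a.tsv", sep="\t", index=False,
                float_format="%.6g")
        with open(out / "snp_associated_genes_a.txt", "w") as fh:
            fh.write("".join(f"{g}\n" for g in sorted(results.snp_associated)))
        if results.go_results is not None:
            results.go_results.to_csv(out / "go_enrichment.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        counts["snp_associated_genes"] = len(results.snp_associated)
    return counts


def run_pipeline(
    config: Mapping | str | Path,
    from_stage: str | None = None,
) -> RunManifest:
    """Load inputs, run every stage and write outputs plus a manifest.

    ``from_stage`` recomputes everything but rewrites only outputs from the
    named stage onward (earlier stage files are left untouched), which
    yields downstream outputs identical to a full run.
    """
    if not isinstance(config, Mapping):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    params = PipelineParams(**config.get("params", {}))
    params.seed = int(config.get("seed", params.seed))
    inputs = load_inputs(config)
    results = analyze(inputs, params)
    out = Path(config["out_dir"])
    start = STAGE_ORDER.index(from_stage) if from_stage else 0
    counts = write_results(results, out, start_index=start)

    input_files: dict[str, str] = {}
    for side in ("species_a", "species_b"):
        for key, path in config[side].items():
            input_files[f"{side}.{key}"] = _hash_file(path)
    for key in ("chain_ab", "chain_ba", "snps", "cpg_sites", "go_terms", "interactions"):
        path = config.get(key)
        if path and Path(path).exists():
            input_files[key] = _hash_file(path)
    cfg_hash = hashlib.sha256(
        json.dumps({k: v for k, v in config.items() if k != "out_dir"},
                   sort_keys=True).encode()
    ).hexdigest()
    try:
        from importlib.metadata import version

        pkg_version = version("chromcompare")
    except Exception:
        pkg_version = "unknown"
    manifest = RunManifest(
        config_hash=cfg_hash,
        input_hashes=input_files,
        counts=counts,
        package_version=pkg_version,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    cio.write_json(manifest.to_json(), out / "manifest.json")
    return manifest
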