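"""Readers and writers for the plain-text dialects the pipeline exchanges.

Coordinates are 0-based half-open on disk and in memory (BED-native); the
GTF reader converts from 1-based closed coordinates on the way in.

Dialects:

* assembly: two-column TSV ``chrom<TAB>length`` (UCSC chrom.sizes);
* genes: TSV ``gene_id chrom strand tss body_start body_end ortholog_id``
  with ``NA`` for absent orthologs;
* peaks: BED4 (chrom, start, end, peak_id) plus a wide sidecar TSV keyed by
  peak_id with ``open_<stage>`` / ``signal_<stage>`` columns;
* stage matrices: TSV with ``row_id`` first column and stage columns;
* block map: TSV ``src_chrom src_start src_end tgt_chrom tgt_start tgt_end
  strand chain_id`` (the native chain dialect); UCSC chain files are also
  read and written;
* SNPs: TSV/BED ``chrom pos`` or ``chrom start end`` with end = start + 1;
* CpG sites: TSV ``chrom position methylated total``;
* GO: two-column TSV ``term_id gene_id``;
* interactions: BEDPE-like TSV (first six columns).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .crossmap import ChainBlock, ChainMap
from .enrichment import GoTerm, SnpCatalog
from .genome import (
    CpGSite,
    DHSPeak,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
)
from .pairing import InteractionRecord

__all__ = [
    "read_assembly",
    "write_assembly",
    "read_genes",
    "write_genes",
    "read_genes_gtf",
    "read_peaks",
    "write_peaks",
    "read_matrix",
    "write_matrix",
    "read_block_map",
    "write_block_map",
    "read_ucsc_chain",
    "write_ucsc_chain",
    "read_snps",
    "write_snps",
    "read_cpg_sites",
    "write_cpg_sites",
    "read_go_terms",
    "write_go_terms",
    "read_interactions",
    "write_interactions",
    "read_json",
    "write_json",
]


def read_assembly(path: str | Path, name: str | None = None) -> GenomeAssembly:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeAssembly(
        name or Path(path).stem,
        dict(zip(df["chrom"].astype(str), df["length"].astype(int))),
    )


def write_assembly(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in assembly.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "body_start", "body_end", "ortholog_id"]


def read_genes(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        ortholog = None if pd.isna(row.ortholog_id) or row.ortholog_id == "NA" else str(row.ortholog_id)
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                body=GenomicInterval(str(row.chrom), int(row.body_start), int(row.body_end)),
                ortholog_id=ortholog,
            )
        )
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = [
        (
            g.gene_id,
            g.chrom,
            g.strand,
            g.tss,
            g.body.start,
            g.body.end,
            g.ortholog_id if g.ortholog_id is not None else "NA",
        )
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader: one gene per ``gene`` feature, TSS from strand.

    GTF is 1-based closed; coordinates are converted to 0-based half-open.
    Orthologs are not represented in GTF and come back as None.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            chrom, _src, _feat, start, end, _score, strand, _frame, attrs = fields[:9]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('" ')
            if gene_id is None:
                continue
            body = GenomicInterval(chrom, int(start) - 1, int(end))
            tss = body.start if strand == "+" else body.end
            genes.append(GeneModel(gene_id, chrom, strand, tss, body))
    return genes


def read_peaks(
    bed_path: str | Path, sidecar_path: str | Path | None = None
) -> list[DHSPeak]:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id"], dtype={"chrom": str, "peak_id": str},
    )
    peaks = [
        DHSPeak(GenomicInterval(r.chrom, int(r.start), int(r.end)), r.peak_id)
        for r in bed.itertuples(index=False)
    ]
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t", dtype={"peak_id": str}).set_index("peak_id")
        open_cols = [c for c in side.columns if c.startswith("open_")]
        sig_cols = [c for c in side.columns if c.startswith("signal_")]
        for peak in peaks:
            row = side.loc[peak.peak_id]
            peak.open_by_stage = {c[len("open_"):]: bool(row[c]) for c in open_cols}
            peak.signal_by_stage = {c[len("signal_"):]: float(row[c]) for c in sig_cols}
    return peaks


def write_peaks(
    peaks: Sequence[DHSPeak],
    bed_path: str | Path,
    sidecar_path: str | Path | None = None,
    stages: Sequence[str] | None = None,
) -> None:
    with open(bed_path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.peak_id}\n")
    if sidecar_path is not None:
        if stages is None:
            stages = list(peaks[0].open_by_stage) if peaks else []
        rows = []
        for p in peaks:
            row: dict[str, object] = {"peak_id": p.peak_id}
            for s in stages:
                row[f"open_{s}"] = int(bool(p.open_by_stage.get(s, False)))
            for s in stages:
                row[f"signal_{s}"] = round(float(p.signal_by_stage.get(s, 0.0)), 6)
            rows.append(row)
        pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"row_id": str}).set_index("row_id")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "row_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


BLOCK_COLUMNS = [
    "src_chrom", "src_start", "src_end",
    "tgt_chrom", "tgt_start", "tgt_end", "strand", "chain_id",
]


def read_block_map(
    path: str | Path, source_assembly: str = "", target_assembly: str = ""
) -> ChainMap:
    df = pd.read_csv(path, sep="\t", dtype={"src_chrom": str, "tgt_chrom": str})
    blocks = [
        ChainBlock(
            r.src_chrom, int(r.src_start), int(r.src_end),
            r.tgt_chrom, int(r.tgt_start), int(r.tgt_end),
            str(r.strand), int(getattr(r, "chain_id", 0)),
        )
        for r in df.itertuples(index=False)
    ]
    return ChainMap(blocks, source_assembly, target_assembly)


def write_block_map(chain: ChainMap, path: str | Path) -> None:
    rows = [
        (b.src_chrom, b.src_start, b.src_end, b.tgt_chrom, b.tgt_start, b.tgt_end, b.strand, b.chain_id)
        for b in chain.blocks
    ]
    pd.DataFrame(rows, columns=BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ucsc_chain(
    path: str | Path,
    src_sizes: Mapping[str, int] | None = None,
    tgt_sizes: Mapping[str, int] | None = None,
) -> ChainMap:
    """Parse a UCSC chain file into ungapped blocks.

    Chain alignment coordinates on a ``-`` strand side count from the end of
    the chromosome; converting them to forward-strand coordinates requires
    the chromosome size carried in the header line.
    """
    blocks: list[ChainBlock] = []
    with open(path) as fh:
        header = None
        t_pos = q_pos = 0
        for raw in fh:
            line = raw.strip()
            if not line:
                header = None
                continue
            if line.startswith("chain"):
                parts = line.split()
                # chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
                header = {
                    "t_name": parts[2], "t_size": int(parts[3]), "t_strand": parts[4],
                    "t_start": int(parts[5]), "t_end": int(parts[6]),
                    "q_name": parts[7], "q_size": int(parts[8]), "q_strand": parts[9],
                    "q_start": int(parts[10]), "q_end": int(parts[11]),
                    "chain_id": int(parts[12]) if len(parts) > 12 else len(blocks),
                }
                t_pos, q_pos = header["t_start"], header["q_start"]
                continue
            if header is None:
                continue
            nums = [int(x) for x in line.split()]
            size = nums[0]
            dt = nums[1] if len(nums) > 1 else 0
            dq = nums[2] if len(nums) > 2 else 0
            src_start, src_end = t_pos, t_pos + size
            if header["q_strand"] == "+":
                tgt_start, tgt_end = q_pos, q_pos + size
                strand = "+"
            else:
                tgt_start = header["q_size"] - (q_pos + size)
                tgt_end = header["q_size"] - q_pos
                strand = "-"
            blocks.append(
                ChainBlock(
                    header["t_name"], src_start, src_end,
                    header["q_name"], tgt_start, tgt_end,
                    strand, header["chain_id"],
                )
            )
            t_pos += size + dt
            q_pos += size + dq
            if len(nums) == 1:
                header = None
    return ChainMap(blocks)


def write_ucsc_chain(
    chain: ChainMap,
    path: str | Path,
    src_sizes: Mapping[str, int],
    tgt_sizes: Mapping[str, int],
) -> None:
    """Serialize a ChainMap as a UCSC chain file (one chain per chain_id run)."""
    by_chain: dict[int, list[ChainBlock]] = {}
    for b in chain.blocks:
        by_chain.setdefault(b.chain_id, []).append(b)
    with open(path, "w") as fh:
        for cid in sorted(by_chain):
            blist = sorted(by_chain[cid], key=lambda b: b.src_start)
            strand = blist[0].strand
            t_name, q_name = blist[0].src_chrom, blist[0].tgt_chrom
            t_start, t_end = blist[0].src_start, blist[-1].src_end
            if strand == "+":
                q_start = blist[0].tgt_start
                q_end = blist[-1].tgt_end
            else:
                q_size = tgt_sizes[q_name]
                q_start = q_size - blist[0].tgt_end
                q_end = q_size - blist[-1].tgt_start
            fh.write(
                f"chain 1000 {t_name} {src_sizes[t_name]} + {t_start} {t_end} "
                f"{q_name} {tgt_sizes[q_name]} {strand} {q_start} {q_end} {cid}\n"
            )
            for i, b in enumerate(blist):
                size = b.src_end - b.src_start
                if i == len(blist) - 1:
                    fh.write(f"{size}\n")
                else:
                    nxt = blist[i + 1]
                    dt = nxt.src_start - b.src_end
                    if strand == "+":
                        dq = nxt.tgt_start - b.tgt_end
                    else:
                        dq = b.tgt_start - nxt.tgt_end
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


def read_snps(path: str | Path, source: str = "") -> SnpCatalog:
    """Read SNP positions from a two-column TSV or a BED (start column used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df[0] = df[0].astype(str)
    return SnpCatalog(zip(df[0], df[1].astype(int)),
                      source=source or Path(path).stem)


def write_snps(snps: SnpCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in snps.positions():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def read_cpg_sites(path: str | Path) -> list[CpGSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CpGSite(r.chrom, int(r.position), int(r.methylated), int(r.total))
        for r in df.itertuples(index=False)
    ]


def write_cpg_sites(sites: Sequence[CpGSite], path: str | Path) -> None:
    rows = [(s.chrom, s.position, s.methylated_reads, s.total_reads) for s in sites]
    pd.DataFrame(rows, columns=["chrom", "position", "methylated", "total"]).to_csv(
        path, sep="\t", index=False
    )


def read_go_terms(path: str | Path) -> list[GoTerm]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms = []
    for term_id, group in df.groupby("term_id", sort=True):
        terms.append(GoTerm(term_id, frozenset(group["gene_id"])))
    return terms


def write_go_terms(terms: Sequence[GoTerm], path: str | Path) -> None:
    rows = [
        (t.term_id, g) for t in terms for g in sorted(t.member_genes)
    ]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        InteractionRecord(
            GenomicInterval(str(r[0]), int(r[1]), int(r[2])),
            GenomicInterval(str(r[3]), int(r[4]), int(r[5])),
        )
        for r in df.itertuples(index=False)
    ]


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.anchor1.chrom}\t{r.anchor1.start}\t{r.anchor1.end}\t"
                f"{r.anchor2.chrom}\t{r.anchor2.start}\t{r.anchor2.end}\n"
            )


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
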