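"""Correlation-based pairing of regulatory elements with genes.

A DHS within the promoter or the +-998 kb distal region of a gene (so within
about 1 Mb of the TSS) is a candidate element.  The candidate becomes a
paired regulatory element when the Pearson correlation between its
quantile-normalized per-stage accessibility and the gene's quantile-normalized
per-stage expression exceeds 0.8 with a two-sided p-value below 0.05 (the
p-value is the standard t test with n - 2 degrees of freedom).

Genes expressed at both the earliest and the latest stage but not in between
are assumed to be driven by two distinct element sets; for those the pairing
is re-run twice with one flank stage masked (accessibility signal set to 0
and the expression floored) to separate early- from late-acting elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import DHSPeak, GeneModel, GenomicInterval, GenomeAssembly, derive_promoter

__all__ = [
    "PairCandidate",
    "RegPair",
    "InteractionRecord",
    "enumerate_candidates",
    "correlate_pair",
    "pair_elements",
    "stage_masked_pairing",
    "hic_support",
]

R_MIN_DEFAULT = 0.8
P_MAX_DEFAULT = 0.05
DISTAL_FLANK_DEFAULT = 998_000


@dataclass(frozen=True)
class PairCandidate:
    peak_id: str
    gene_id: str
    pearson_r: float
    p_value: float
    n_stages: int
    passed: bool


@dataclass(frozen=True)
class RegPair:
    peak_id: str
    gene_id: str
    pearson_r: float
    p_value: float
    phase: str = "all"  # all | early | late
    hic_supported: bool | None = None


@dataclass(frozen=True)
class InteractionRecord:
    anchor1: GenomicInterval
    anchor2: GenomicInterval


def enumerate_candidates(
    gene: GeneModel,
    peaks: Sequence[DHSPeak],
    assembly: GenomeAssembly,
    distal_flank: int = DISTAL_FLANK_DEFAULT,
    promoter_flank: int = 2000,
) -> list[DHSPeak]:
    """Peaks overlapping the promoter or its +-``distal_flank`` neighbourhood."""
    promoter = derive_promoter(gene, assembly, promoter_flank)
    window = assembly.clip(
        GenomicInterval(
            promoter.chrom,
            max(0, promoter.start - distal_flank),
            promoter.end + distal_flank,
        )
    )
    return [p for p in peaks if p.interval.overlaps(window)]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value (df = n - 2)."""
    n = x.size
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((sx * sy).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_pair(
    signal,
    expr,
    peak_id: str = "",
    gene_id: str = "",
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
) -> PairCandidate:
    """Correlate one element's stage signal with one gene's stage expression."""
    x = np.asarray(signal, dtype=float)
    y = np.asarray(expr, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("stage vectors must align and contain >=3 stages")
    r, p = _pearson_with_p(x, y)
    passed = bool(not np.isnan(r) and r > r_min and p < p_max)
    return PairCandidate(peak_id, gene_id, r, p, x.size, passed)


def _correlate_many(
    signals: np.ndarray, expr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and p of each signal row against one expression vector."""
    n = expr.size
    sy = expr - expr.mean()
    ss_y = (sy**2).sum()
    sx = signals - signals.mean(axis=1, keepdims=True)
    ss_x = (sx**2).sum(axis=1)
    denom = np.sqrt(ss_x * ss_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((sx @ sy) / denom, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return r, p


def pair_elements(
    genes: Sequence[GeneModel],
    peaks: Sequence[DHSPeak],
    acc_qnorm: pd.DataFrame,
    expr_qnorm: pd.DataFrame,
    assembly: GenomeAssembly,
    distal_flank: int = DISTAL_FLANK_DEFAULT,
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
) -> list[RegPair]:
    """All passing element-gene pairs for a (dynamic) gene set.

    ``acc_qnorm`` (peaks x stages) and ``expr_qnorm`` (genes x stages) are the
    quantile-normalized matrices.  A gene may gain many elements and an
    element may serve many genes; no exclusivity is applied.
    """
    pairs: list[RegPair] = []
    acc_ids = {pid: i for i, pid in enumerate(acc_qnorm.index)}
    acc_arr = acc_qnorm.to_numpy(dtype=float)
    for gene in genes:
        if gene.gene_id not in expr_qnorm.index:
            continue
        candidates = enumerate_candidates(gene, peaks, assembly, distal_flank)
        cand_ids = [p.peak_id for p in candidates if p.peak_id in acc_ids]
        if not cand_ids:
            continue
        rows = acc_arr[[acc_ids[pid] for pid in cand_ids]]
        expr = expr_qnorm.loc[gene.gene_id].to_numpy(dtype=float)
        r, p = _correlate_many(rows, expr)
        keep = ~np.isnan(r) & (r > r_min) & (p < p_max)
        for idx in np.nonzero(keep)[0]:
            pairs.append(
                RegPair(cand_ids[idx], gene.gene_id, float(r[idx]), float(p[idx]))
            )
    return pairs


def _flank_high_stages(scaled: np.ndarray, high: float = 0.7, low: float = 0.3):
    """Indices of the earliest/latest high stages of a bimodal scaled profile."""
    if scaled.size < 3 or not (
        scaled[0] >= high and scaled[-1] >= high and scaled[1:-1].min() <= low
    ):
        raise ValueError("stage-masked pairing requires a bimodal profile")
    return 0, scaled.size - 1


def stage_masked_pairing(
    gene: GeneModel,
    peaks: Sequence[DHSPeak],
    acc_qnorm: pd.DataFrame,
    expr_qnorm: pd.DataFrame,
    assembly: GenomeAssembly,
    distal_flank: int = DISTAL_FLANK_DEFAULT,
    r_min: float = R_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
    masked_floor: float = 0.0,
) -> tuple[list[RegPair], list[RegPair]]:
    """Early- and late-acting element sets for a bimodal gene.

    The gene must be expressed at the earliest and latest stages with a low
    interior (the precondition is checked on the min-max scaled profile).
    Masking the latest high stage (signal -> 0, expression -> floor) isolates
    early-acting elements; masking the earliest isolates late-acting ones.
    """
    expr = expr_qnorm.loc[gene.gene_id].to_numpy(dtype=float)
    rng = expr.max() - expr.min()
    if rng == 0:
        raise ValueError("flat expression profile")
    scaled = (expr - expr.min()) / rng
    early_idx, late_idx = _flank_high_stages(scaled)

    candidates = enumerate_candidates(gene, peaks, assembly, distal_flank)
    cand_ids = [p.peak_id for p in candidates if p.peak_id in acc_qnorm.index]
    if not cand_ids:
        return [], []
    rows = acc_qnorm.loc[cand_ids].to_numpy(dtype=float)

    def run(mask_stage: int, phase: str) -> list[RegPair]:
        sig = rows.copy()
        sig[:, mask_stage] = 0.0
        e = expr.copy()
        e[mask_stage] = masked_floor
        r, p = _correlate_many(sig, e)
        keep = ~np.isnan(r) & (r > r_min) & (p < p_max)
        return [
            RegPair(cand_ids[i], gene.gene_id, float(r[i]), float(p[i]), phase=phase)
            for i in np.nonzero(keep)[0]
        ]

    early_set = run(late_idx, "early")
    late_set = run(early_idx, "late")
    return early_set, late_set


def hic_support(
    element: GenomicInterval,
    promoter: GenomicInterval,
    interactions: Iterable[InteractionRecord],
) -> bool:
    """Supported iff element and promoter fall in opposite anchors of a record."""
    for rec in interactions:
        if (
            element.overlaps(rec.anchor1)
            and promoter.overlaps(rec.anchor2)
            or element.overlaps(rec.anchor2)
            and promoter.overlaps(rec.anchor1)
        ):
            return True
    return False
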