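"""Cross-species classification of element-gene pairs.

Pairs on genes with 1-to-1 orthologs fall into three groups:

* Group I   - the element is half of a conserved cross-species peak pair and
  both halves pair with the same orthologous gene in their own species;
* Group II  - the element's sequence is conserved (a conserved peak pair or a
  lift-but-no-peak element) but the pairing is not mirrored: the element is
  species-specifically open, or its accessibility dynamics disagree between
  species, or the partner simply does not pair with the ortholog;
* Group III - the element's sequence is specific to its genome.

The Group II "inconsistent dynamics" call reuses the pairing threshold: a
conserved element whose per-stage signals, after matching stage frames
between species, correlate at r <= 0.8 is considered dynamically
inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .crossmap import ChainMap, ConservationCall, lift_interval
from .genome import GenomicInterval
from .pairing import RegPair

__all__ = [
    "GroupedPair",
    "OrthoComparison",
    "classify_groups",
    "matched_cluster_orthologs",
    "compare_pair_distances",
    "cross_species_signal_consistency",
]


@dataclass(frozen=True)
class GroupedPair:
    peak_id: str
    gene_id: str
    group: str  # I | II | III | unassigned
    subcategory: str | None = None


@dataclass(frozen=True)
class OrthoComparison:
    shared: frozenset[str]
    a_specific: frozenset[str]
    b_specific: frozenset[str]


def cross_species_signal_consistency(
    signal_a,
    signal_b,
    stage_groups: Sequence[Sequence[int]],
) -> float:
    """Pearson r between species' signals in matched stage frames.

    ``stage_groups`` maps each species-B stage to the species-A stage indices
    it corresponds to; species-A values are averaged within each group before
    correlating (e.g. a 6-stage series folds onto a 3-stage one as
    ``[(0, 1), (2, 3), (4, 5)]``).
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if len(stage_groups) != b.size:
        raise ValueError("stage correspondence must cover every species-B stage")
    folded = np.array([a[list(g)].mean() for g in stage_groups])
    if np.ptp(folded) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(folded, b)[0, 1])


def classify_groups(
    pairs_a: Sequence[RegPair],
    pairs_b: Sequence[RegPair],
    calls_a: Mapping[str, ConservationCall],
    ortholog_map: Mapping[str, str],
    signal_consistency: Mapping[str, float] | None = None,
    r_min: float = 0.8,
) -> list[GroupedPair]:
    """Assign Groups I/II/III to species-A pairs.

    ``ortholog_map`` maps A gene ids to B gene ids; pairs on genes without an
    entry are unassigned, as are pairs on elements removed for multi-chain
    ambiguity.  ``signal_consistency`` optionally carries per-element
    cross-species signal correlations used to subcategorize Group II.
    """
    b_pairs = {(p.peak_id, p.gene_id) for p in pairs_b}
    grouped: list[GroupedPair] = []
    for pair in pairs_a:
        ortholog = ortholog_map.get(pair.gene_id)
        call = calls_a.get(pair.peak_id)
        if ortholog is None or call is None:
            grouped.append(GroupedPair(pair.peak_id, pair.gene_id, "unassigned"))
            continue
        if call.category == "genome_specific":
            grouped.append(GroupedPair(pair.peak_id, pair.gene_id, "III"))
            continue
        if (
            call.category == "conserved_pair"
            and (call.peak_id_b, ortholog) in b_pairs
        ):
            grouped.append(GroupedPair(pair.peak_id, pair.gene_id, "I"))
            continue
        if call.species_specific_open:
            sub = "species_specific_open"
        elif (
            call.category == "conserved_pair"
            and signal_consistency is not None
            and not np.isnan(signal_consistency.get(pair.peak_id, np.nan))
            and signal_consistency[pair.peak_id] <= r_min
        ):
            sub = "inconsistent_dynamics"
        else:
            sub = "unmirrored"
        grouped.append(GroupedPair(pair.peak_id, pair.gene_id, "II", sub))
    return grouped


def matched_cluster_orthologs(
    cluster_a_genes: set[str],
    cluster_b_genes: set[str],
    ortholog_map: Mapping[str, str],
) -> OrthoComparison:
    """Compare ortholog membership of two matched expression clusters.

    Sets are expressed in species-B gene ids: ``shared`` holds orthologs
    present in both clusters, the specific sets those present in only one.
    Genes without 1-to-1 orthologs are ignored.
    """
    mapped_a = {
        ortholog_map[g] for g in cluster_a_genes if g in ortholog_map
    }
    mapped_b = {
        g
        for g in cluster_b_genes
        if g in set(ortholog_map.values())
    }
    return OrthoComparison(
        shared=frozenset(mapped_a & mapped_b),
        a_specific=frozenset(mapped_a - mapped_b),
        b_specific=frozenset(mapped_b - mapped_a),
    )


def compare_pair_distances(
    element: GenomicInterval,
    tss_a: int,
    chain_ab: ChainMap,
    tss_b: int | None,
    min_mapped: float = 0.95,
) -> tuple[float, float | None]:
    """Element-TSS distance in the home species and after lifting.

    Distances are measured from the element midpoint.  The lifted distance is
    None when the element does not lift uniquely or the ortholog TSS is
    unknown.
    """
    native = abs(element.midpoint - tss_a)
    if tss_b is None:
        return native, None
    res = lift_interval(element, chain_ab, min_mapped)
    if res.status != "unique":
        return native, None
    return native, abs(res.target.midpoint - tss_b)
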