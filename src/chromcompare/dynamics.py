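"""Stage-specificity scoring and expression-profile clustering.

A gene's developmental dynamics are summarized by the Shannon entropy of its
stage-proportion vector: after quantile normalization the (non-negative)
per-stage expression values are turned into proportions and

    H = -sum_s p_s log2 p_s,     p_s = v_s / sum(v)

so a uniformly expressed gene scores log2(S) bits over S stages and a gene
expressed at a single stage scores 0.  Genes below a species-specific
threshold (defaults 2.55 bits for a 6-stage series, 1.56 for a 3-stage
series; both sit just below the respective maxima log2 6 and log2 3) are
called stage-specific.  Stage-specific genes are min-max scaled to [0, 1] and
clustered with K-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "DEFAULT_ENTROPY_THRESHOLDS",
    "entropy_score",
    "classify_stage_specific",
    "minmax_scale",
    "cluster_profiles",
    "choose_k_by_elbow",
    "is_bimodal_profile",
    "compute_dynamics",
    "DynamicsTable",
]

# Entropy thresholds (bits) keyed by number of stages, as used for the
# 6-stage and 3-stage developmental series.
DEFAULT_ENTROPY_THRESHOLDS = {6: 2.55, 3: 1.56}


def entropy_score(values) -> float | None:
    """Shannon entropy (bits) of the stage-proportion vector.

    Negative inputs (possible after normalization) are floored at zero before
    forming proportions; 0*log(0) is taken as 0.  All-zero profiles have no
    defined proportions and return None.
    """
    v = np.clip(np.asarray(values, dtype=float), 0.0, None)
    total = v.sum()
    if total <= 0:
        return None
    p = v / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def classify_stage_specific(entropy: float, threshold: float) -> bool:
    """Stage-specific iff entropy is strictly below the threshold."""
    return entropy < threshold


def minmax_scale(values) -> np.ndarray | None:
    """Scale a profile to [0, 1] via (x - min) / (max - min); None if flat."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return None
    return (v - lo) / (hi - lo)


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int | str = 6,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[pd.Series, dict[int, float]]:
    """K-means partition of scaled profiles.

    With ``k="auto"`` the cluster count is chosen by scanning k in [2, 10]
    and taking the elbow of the SSE curve (maximum second difference).
    Returns (assignments indexed like ``profiles``, SSE per evaluated k).
    """
    X = profiles.to_numpy(dtype=float)
    sse: dict[int, float] = {}
    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"unknown k mode {k!r}")
        kmax = min(10, len(profiles) - 1)
        for kk in range(2, kmax + 1):
            km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
            km.fit(X)
            sse[kk] = float(km.inertia_)
        k = choose_k_by_elbow(sse)
    if len(profiles) < k:
        raise ValueError(f"{len(profiles)} profiles cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    sse[k] = float(km.inertia_)
    return pd.Series(labels, index=profiles.index, name="cluster"), sse


def choose_k_by_elbow(sse: dict[int, float]) -> int:
    """Elbow = k with the maximum second difference of the SSE curve."""
    ks = sorted(sse)
    if len(ks) < 3:
        return ks[0]
    best_k, best_curv = ks[1], -np.inf
    for i in range(1, len(ks) - 1):
        curv = sse[ks[i - 1]] - 2 * sse[ks[i]] + sse[ks[i + 1]]
        if curv > best_curv:
            best_k, best_curv = ks[i], curv
    return best_k


def is_bimodal_profile(
    scaled, high: float = 0.7, low: float = 0.3
) -> bool:
    """True for profiles high at the first and last stage with a low interior.

    This is the shape of genes regulated by distinct early- and late-acting
    element sets, the input to stage-masked pairing.
    """
    s = np.asarray(scaled, dtype=float)
    if s.size < 3:
        return False
    return bool(s[0] >= high and s[-1] >= high and s[1:-1].min() <= low)


@dataclass
class DynamicsTable:
    """Per-gene dynamics: entropy, stage-specific flag, scaled profile, cluster."""

    table: pd.DataFrame          # entropy, stage_specific, cluster columns
    scaled: pd.DataFrame         # scaled profiles for stage-specific genes
    sse: dict[int, float]

    @property
    def stage_specific_genes(self) -> list[str]:
        flags = self.table["stage_specific"]
        return [g for g, f in flags.items() if f is True]

    def bimodal_genes(self) -> list[str]:
        return [g for g in self.scaled.index if is_bimodal_profile(self.scaled.loc[g])]


def compute_dynamics(
    expr_qnorm: pd.DataFrame,
    entropy_threshold: float | None = None,
    k: int | str = 6,
    seed: int = 0,
) -> DynamicsTable:
    """Entropy scoring, stage-specific calling, scaling and clustering.

    ``expr_qnorm`` is the quantile-normalized log2 expression matrix
    (genes x stages).  Genes with all-zero or flat profiles are excluded from
    scaling/clustering; the default entropy threshold is looked up from the
    stage count.
    """
    n_stages = expr_qnorm.shape[1]
    if entropy_threshold is None:
        try:
            entropy_threshold = DEFAULT_ENTROPY_THRESHOLDS[n_stages]
        except KeyError:
            raise ValueError(
                f"no default entropy threshold for {n_stages} stages; pass one"
            ) from None
    records = {}
    scaled_rows = {}
    for gene, row in expr_qnorm.iterrows():
        h = entropy_score(row.to_numpy())
        specific = classify_stage_specific(h, entropy_threshold) if h is not None else None
        records[gene] = {"entropy": h, "stage_specific": specific}
        if specific:
            scaled = minmax_scale(row.to_numpy())
            if scaled is not None:
                scaled_rows[gene] = scaled
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "gene_id"
    scaled_df = pd.DataFrame.from_dict(
        scaled_rows, orient="index", columns=list(expr_qnorm.columns)
    )
    sse: dict[int, float] = {}
    table["cluster"] = pd.Series(dtype="Int64")
    if len(scaled_df) >= 2:
        n_distinct = len(np.unique(scaled_df.to_numpy(), axis=0))
        k_eff = k if isinstance(k, str) else min(k, n_distinct)
        clusters, sse = cluster_profiles(scaled_df, k=k_eff, seed=seed)
        table.loc[clusters.index, "cluster"] = clusters.astype("Int64")
    return DynamicsTable(table=table, scaled=scaled_df, sse=sse)
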