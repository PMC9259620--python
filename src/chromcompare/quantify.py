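"""Tag densities, replicate concordance, log transform and quantile normalization.

Accessibility and expression both live on the FPKM scale; downstream
correlation analysis uses ``log2(FPKM + 1)`` normalized across developmental
stages by quantile normalization.  The pseudocount keeps zero FPKM at zero and
is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StageMatrix",
    "window_tag_density",
    "replicate_correlation",
    "log2_transform",
    "quantile_normalize",
    "flag_expressed",
]

VALID_SCALES = ("fpkm", "log2fpkm", "qnorm")


@dataclass
class StageMatrix:
    """Rows = regions or genes, columns = ordered developmental stages."""

    values: pd.DataFrame
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("stage matrix contains missing cells")

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)


def window_tag_density(
    fragments: int | np.ndarray,
    window_length: int | np.ndarray,
    library_total: int,
) -> float | np.ndarray:
    """FPKM tag density: fragments / (kb of window x millions of fragments)."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return np.asarray(fragments, dtype=float) / (
        (np.asarray(window_length, dtype=float) / 1000.0)
        * (library_total / 1e6)
    )


def replicate_correlation(a, b) -> float | None:
    """Pearson r between two replicate vectors; None when variance vanishes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicates need identical shape and >=3 entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def log2_transform(matrix: StageMatrix, pseudocount: float = 1.0) -> StageMatrix:
    """log2(FPKM + pseudocount); with the default pseudocount zeros stay zero."""
    if matrix.scale != "fpkm":
        raise ValueError("log transform expects an FPKM-scale matrix")
    return StageMatrix(np.log2(matrix.values + pseudocount), scale="log2fpkm")


def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a DataFrame.

    Every column is mapped onto the reference distribution given by the
    row-wise mean of the column-sorted input.  Tied values within a column
    receive the mean of the reference values their ranks span.
    """
    arr = df.to_numpy(dtype=float)
    n, m = arr.shape
    if m == 1:
        return df.astype(float).copy()
    ref = np.sort(arr, axis=0).mean(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(ref)))
    out = np.empty_like(arr)
    for j in range(m):
        uniq, inverse, counts = np.unique(
            arr[:, j], return_inverse=True, return_counts=True
        )
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        block_means = (csum[starts + counts] - csum[starts]) / counts
        out[:, j] = block_means[inverse]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: StageMatrix) -> StageMatrix:
    if matrix.scale != "log2fpkm":
        raise ValueError("quantile normalization expects log2 FPKM input")
    return StageMatrix(quantile_normalize_frame(matrix.values), scale="qnorm")


def flag_expressed(fpkm, threshold: float = 1.0):
    """Expressed iff FPKM >= threshold (values below 1 count as not expressed)."""
    arr = np.asarray(fpkm, dtype=float)
    flags = arr >= threshold
    return bool(flags) if np.isscalar(fpkm) or arr.ndim == 0 else flags
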