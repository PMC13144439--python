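"""Cells × genes expression matrices and their normalizations.

The container is a thin wrapper over a pandas DataFrame (cells in rows,
genes in columns) carrying a ``scale`` tag that records what the values
mean: ``raw`` simulator output, ``log`` (log2(x+1)) or ``zscore``
(per-gene standardized). Downstream correlation inference uses the matrix
as supplied and never transforms it silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "normalize_log",
    "zscore",
    "apply_dropout",
]

_SCALES = ("raw", "log", "zscore")


@dataclass
class ExpressionMatrix:
    """Expression values with named cells (rows) and genes (columns).

    Invariants: finite values, unique gene names, non-negative values when
    ``scale == "raw"``.
    """

    data: pd.DataFrame
    scale: str = "raw"
    converged: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.data.columns.duplicated().any():
            raise ValueError("gene names must be unique")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if self.scale == "raw" and vals.size and vals.min() < 0:
            raise ValueError("raw expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def cells(self) -> list[str]:
        return [str(c) for c in self.data.index]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes absent from the matrix: {', '.join(missing)}")
        return ExpressionMatrix(self.data[genes].copy(), scale=self.scale)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column cell id, header row of gene names."""
        self.data.to_csv(Path(path), sep="\t", index_label="cell")

    def to_mtx(self, path: str | Path) -> None:
        """Matrix Market triplet export (useful for sparse post-dropout data)."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(self.values()))


def read_expression(path: str | Path, scale: str = "log") -> ExpressionMatrix:
    """Read a dense TSV/CSV (first column cell id, header of gene names).

    The delimiter is inferred from the extension (``.csv`` → comma,
    otherwise tab). ``scale`` tags how the stored values were normalized.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    return ExpressionMatrix(df, scale=scale)


def normalize_log(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a raw matrix (pseudocount of 1)."""
    if matrix.scale != "raw":
        raise ValueError(f"expected a raw matrix, got scale {matrix.scale!r}")
    out = np.log2(matrix.values() + 1.0)
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(df, scale="log", converged=matrix.converged)


def zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization to mean 0, SD 1 (ddof=1).

    Zero-variance genes cannot be standardized and are dropped with a
    warning; a single-cell matrix is rejected.
    """
    if matrix.n_cells < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    vals = matrix.values()
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(matrix.genes, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s): {', '.join(dropped)}"
        )
    vals = vals[:, keep]
    out = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    cols = [g for g, k in zip(matrix.genes, keep) if k]
    df = pd.DataFrame(out, index=matrix.data.index, columns=cols)
    return ExpressionMatrix(df, scale="zscore", converged=matrix.converged)


def apply_dropout(
    matrix: ExpressionMatrix,
    drop_prob: float,
    drop_quantile: float = 0.2,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Technical-noise model: zero out low values at random, per gene.

    For each gene the empirical ``drop_quantile`` of its values is computed
    (linear-interpolation quantile); every entry strictly below that
    threshold is independently set to zero with probability ``drop_prob``.
    Entries at or above the threshold are untouched.
    """
    if not (0 <= drop_prob <= 1 and 0 <= drop_quantile <= 1):
        raise ValueError("drop_prob and drop_quantile must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    vals = matrix.values().copy()
    thresholds = np.quantile(vals, drop_quantile, axis=0)  # type-7 linear
    below = vals < thresholds[None, :]
    hit = rng.random(vals.shape) < drop_prob
    vals[below & hit] = 0.0
    df = pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(df, scale=matrix.scale, converged=matrix.converged)
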