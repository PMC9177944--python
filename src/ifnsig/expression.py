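"""Count-matrix containers, I/O, filtering, normalization and z-scoring.

The transcriptomic input is a gene x sample matrix of non-negative integer
read counts with a two-level group label per sample (``CTL`` healthy
controls, ``FM`` fibromyalgia patients).  Normalization uses the
median-of-ratios size-factor estimator: size factors are per-sample medians
of counts divided by per-gene geometric means, computed over the reference
set of genes that are positive in every sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

VALID_GROUPS = ("CTL", "FM")

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "load_counts",
    "write_matrix",
    "filter_low_expressed",
    "size_factors",
    "normalize",
    "zscore_rows",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus per-sample group labels.

    ``counts`` is a pandas DataFrame indexed by unique gene ids with unique
    sample-id columns; ``groups`` maps each sample id to ``CTL`` or ``FM``.
    """

    counts: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(cols)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()].tolist()
                raise ValueError(f"samples without group label: {missing[:5]}")
            bad = set(self.groups.unique()) - set(VALID_GROUPS)
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("count matrix has no group labels")
        return self.groups.index[self.groups == group].tolist()


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression, on a linear or log2 scale."""

    values: pd.DataFrame
    size_factors: pd.Series
    scale: Literal["linear", "log2"]
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")


def load_counts(path: str | Path, fmt: str = "tsv", groups: pd.Series | None = None) -> CountMatrix:
    """Read a count matrix from TSV (genes in rows, sample-id header) or
    MatrixMarket (``.mtx`` with ``<stem>.rownames.txt`` / ``.colnames.txt``
    sidecar files).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count file not found: {path}")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.map(lambda v: not _is_integral(v))
        if bad.to_numpy().any():
            row = df.index[bad.any(axis=1)][0]
            # +2: header line plus 1-based numbering
            lineno = df.index.get_loc(row) + 2
            raise ValueError(f"non-integer count at gene {row!r} (line {lineno})")
        df = df.astype(np.int64)
    elif fmt == "mtx":
        raw = mmread(path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        rownames = _read_names(path.parent / (path.stem + ".rownames.txt"))
        colnames = _read_names(path.parent / (path.stem + ".colnames.txt"))
        df = pd.DataFrame(np.asarray(mat, dtype=np.int64), index=rownames, columns=colnames)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")
    return CountMatrix(df, groups)


def write_matrix(matrix: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write counts as TSV or MatrixMarket plus row/column-name sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        matrix.counts.to_csv(path, sep="\t")
    elif fmt == "mtx":
        sparse = coo_matrix(matrix.counts.to_numpy())
        mmwrite(str(path), sparse)
        _write_names(path.parent / (path.stem + ".rownames.txt"), matrix.gene_ids)
        _write_names(path.parent / (path.stem + ".colnames.txt"), matrix.sample_ids)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def filter_low_expressed(matrix: CountMatrix, max_zero_samples: int = 5) -> CountMatrix:
    """Drop genes with zero counts in more than ``max_zero_samples`` samples.

    A gene with zeros in exactly ``max_zero_samples`` samples is retained;
    gene order is preserved.  Idempotent.
    """
    if max_zero_samples < 0:
        raise ValueError("max_zero_samples must be >= 0")
    n_zero = (matrix.counts == 0).sum(axis=1)
    keep = n_zero <= max_zero_samples
    return CountMatrix(matrix.counts.loc[keep], matrix.groups)


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors s_j.

    For each reference gene g (nonzero in all samples) compute the ratio of
    its count in sample j to its geometric mean across samples; s_j is the
    median of those ratios.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; relax filtering "
            "before estimating size factors"
        )
    logc = np.log(counts[ref])
    log_geomean = logc.mean(axis=1)
    ratios = np.exp(logc - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=matrix.sample_ids, name="size_factor")


def normalize(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    scale: Literal["linear", "log2"] = "linear",
) -> NormalizedMatrix:
    """Divide counts by size factors; optionally log2(x + 1)-transform."""
    if factors is None:
        factors = size_factors(matrix)
    factors = pd.Series(factors)
    if set(factors.index) != set(matrix.sample_ids):
        raise ValueError("size-factor index does not match sample ids")
    factors = factors.reindex(matrix.sample_ids)
    values = matrix.counts.div(factors, axis=1)
    if scale == "log2":
        values = np.log2(values + 1.0)
    return NormalizedMatrix(values, factors, scale, groups=matrix.groups)


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores (mean 0, sample SD 1 with ddof=1).

    Constant rows carry no clustering information and would corrupt
    Euclidean distances, so they are dropped with a warning.
    """
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = values.index[constant].tolist()
        warnings.warn(
            f"dropping {len(dropped)} constant row(s) from z-scoring: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    kept = values.loc[~constant]
    return kept.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)


def _is_integral(v: object) -> bool:
    try:
        return float(v) == int(float(v))
    except (TypeError, ValueError):
        return False


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"sidecar name file not found: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _write_names(path: Path, names: Sequence[str]) -> None:
    path.write_text("\n".join(names) + "\n")
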