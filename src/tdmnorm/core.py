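"""Expression-matrix data model and plumbing.

Matrices are genes-in-rows, samples-in-columns, the convention of delimited
expression files (TSV and the PCL dialect with its NAME/GWEIGHT columns).
Every matrix carries a declared value space -- ``linear`` for RNA-seq style
estimated abundances/counts, ``log2`` for microarray-style intensities --
because the cross-platform transforms care about which one they receive.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabeledDataset",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "align_genes",
    "filter_by_mad",
    "log2_transform",
]

LINEAR = "linear"
LOG2 = "log2"
_SPACES = (LINEAR, LOG2)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a declared value space.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique row/column identifiers.
    values
        Numeric array of shape ``(len(gene_ids), len(sample_ids))``; all
        entries finite, and non-negative when ``space == "linear"``.
    space
        ``"linear"`` or ``"log2"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    space: str = LOG2

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}, got {self.space!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise ValueError("empty matrix: need at least one gene and one sample")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.space == LINEAR and np.any(self.values < 0):
            raise ValueError("linear-space values must be non-negative")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, space: str) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            space=space,
        )

    def with_values(self, values: np.ndarray, space: str | None = None) -> "ExpressionMatrix":
        return replace(
            self, values=np.asarray(values, dtype=float),
            space=self.space if space is None else space,
        )


@dataclass
class LabeledDataset:
    """An :class:`ExpressionMatrix` plus one class label per sample."""

    matrix: ExpressionMatrix
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.matrix.n_samples:
            raise ValueError(
                f"{len(self.labels)} labels for {self.matrix.n_samples} samples"
            )

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))


# -- I/O -------------------------------------------------------------------

def read_matrix(path: str | os.PathLike, dialect: str = "tsv", space: str = LOG2) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    ``dialect="tsv"``: first column gene ids, header row sample ids.
    ``dialect="pcl"``: GENE, NAME, GWEIGHT columns precede the samples and an
    optional EWEIGHT row follows the header; both are skipped.
    """
    if dialect not in ("tsv", "pcl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                      keep_default_na=False, na_filter=False)
    if dialect == "pcl":
        drop = [c for c in raw.columns[:2] if c.upper() in ("NAME", "GWEIGHT")]
        raw = raw.drop(columns=drop)
        if len(raw.index) and str(raw.index[0]).upper() == "EWEIGHT":
            raw = raw.iloc[1:]
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    values = np.empty(raw.shape, dtype=float)
    cols = list(raw.columns)
    for j, col in enumerate(cols):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-numeric value {raw[col].iloc[i]!r} at gene {raw.index[i]!r}, "
                f"sample {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=[str(i) for i in raw.index],
        sample_ids=[str(c) for c in cols],
        values=values,
        space=space,
    )


def write_matrix(m: ExpressionMatrix, path: str | os.PathLike, dialect: str = "tsv") -> None:
    """Write a matrix readably by :func:`read_matrix`, atomically.

    Values are written with 10 significant digits.
    """
    if dialect not in ("tsv", "pcl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = m.to_frame()
    if dialect == "pcl":
        out = df.copy()
        out.insert(0, "GWEIGHT", 1)
        out.insert(0, "NAME", list(m.gene_ids))
        out.index.name = "GENE"
        df = out
    else:
        df.index.name = "GENE"
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, sep="\t", float_format="%.10g")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (sample_id, class) TSV; a header line is tolerated."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two tab-separated columns")
    first = str(df.iloc[0, 0]).lower()
    if first in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# -- gene-level operations -------------------------------------------------

def align_genes(train: ExpressionMatrix, test: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in the training order.

    Cross-platform work routinely loses genes to platform differences;
    models trained on the aligned training matrix keep their coefficient
    order valid on the aligned test matrix.
    """
    test_set = set(test.gene_ids)
    shared = [g for g in train.gene_ids if g in test_set]
    if not shared:
        raise ValueError("no genes shared between matrices")
    tr_pos = {g: i for i, g in enumerate(train.gene_ids)}
    tr_idx = [tr_pos[g] for g in shared] if len(shared) < train.n_genes else None
    te_pos = {g: i for i, g in enumerate(test.gene_ids)}
    te_idx = [te_pos[g] for g in shared]
    if tr_idx is None:
        train_out = train
    else:
        train_out = ExpressionMatrix(shared, list(train.sample_ids),
                                     train.values[tr_idx, :], train.space)
    test_out = ExpressionMatrix(shared, list(test.sample_ids),
                                test.values[te_idx, :], test.space)
    return train_out, test_out


def filter_by_mad(m: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the ``k`` genes with the largest median absolute deviation.

    MAD per gene is ``median(|x - median(x)|)`` across samples, with no
    consistency constant (ranking is invariant to it).  Original gene order
    is preserved; ties at the cutoff are broken in favour of earlier genes.
    """
    if not (0 < k <= m.n_genes):
        raise ValueError(f"k={k} out of range for {m.n_genes} genes")
    med = np.median(m.values, axis=1, keepdims=True)
    mad = np.median(np.abs(m.values - med), axis=1)
    # stable sort on -mad keeps original order within ties
    top = np.sort(np.argsort(-mad, kind="stable")[:k])
    return ExpressionMatrix([m.gene_ids[i] for i in top], list(m.sample_ids),
                            m.values[top, :], m.space)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``log2(x + pseudocount)`` on a linear-space matrix."""
    if m.space != LINEAR:
        raise ValueError("log2_transform expects a linear-space matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(m.values == 0):
        raise ValueError("zero values require a positive pseudocount")
    return m.with_values(np.log2(m.values + pseudocount), space=LOG2)
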