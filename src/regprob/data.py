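"""Expression-matrix container and delimited-text readers.

The central object is :class:`ExpressionDataset`: a genes x samples matrix of
real-valued expression levels (microarray intensities or RNA-seq counts both
work, because every downstream statistic is comparison-based) together with a
binary class assignment of the samples (tumor vs normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("regprob")

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "read_labels",
    "read_probe_map",
    "write_matrix",
]


class DataError(ValueError):
    """Raised when an input matrix or label file violates the data contract."""


@dataclass
class ExpressionDataset:
    """A labelled genes x samples expression matrix with a two-class design.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); the index holds unique gene
        identifiers, the columns unique sample identifiers.
    classes
        Mapping (or Series) from every sample identifier to one of exactly
        two class labels.
    tumor_label
        Which of the two labels is the "tumor" (case) class.  Defaults to
        ``"tumor"`` when that label is present, otherwise it must be given
        explicitly.
    """

    values: pd.DataFrame
    classes: pd.Series
    tumor_label: str = "tumor"
    normal_label: str = field(init=False)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if isinstance(self.classes, Mapping):
            self.classes = pd.Series(self.classes)
        self.classes = self.classes.reindex(self.values.columns)
        if self.classes.isna().any():
            missing = list(self.classes.index[self.classes.isna()])
            raise DataError(f"samples missing from the label file: {missing[:5]}")
        labels = sorted(set(self.classes))
        if len(labels) != 2:
            raise DataError(
                f"exactly two class labels are required, found {labels!r}"
            )
        if self.tumor_label not in labels:
            raise DataError(
                f"tumor label {self.tumor_label!r} not among class labels {labels!r}"
            )
        self.normal_label = next(l for l in labels if l != self.tumor_label)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5]
            raise DataError(f"duplicate gene identifiers: {list(dup)}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:5]
            raise DataError(f"duplicate sample identifiers: {list(dup)}")
        if self.values.isna().any().any():
            row, col = next(
                (r, c)
                for r in self.values.index
                for c in self.values.columns
                if pd.isna(self.values.at[r, c])
            )
            raise DataError(f"missing value at gene {row!r}, sample {col!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tumor_mask(self) -> np.ndarray:
        return (self.classes == self.tumor_label).to_numpy()

    @property
    def n(self) -> int:
        """Number of tumor samples."""
        return int(self.tumor_mask.sum())

    @property
    def m(self) -> int:
        """Number of normal samples."""
        return int((~self.tumor_mask).sum())

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def tumor_values(self) -> np.ndarray:
        """(genes, n) array of tumor-class expression values."""
        return self.values.to_numpy(dtype=float)[:, self.tumor_mask]

    def normal_values(self) -> np.ndarray:
        """(genes, m) array of normal-class expression values."""
        return self.values.to_numpy(dtype=float)[:, ~self.tumor_mask]

    def require_two_per_class(self) -> None:
        if self.n < 2 or self.m < 2:
            raise DataError(
                f"need at least two samples per class, got n={self.n}, m={self.m}"
            )

    def with_classes_swapped(self) -> "ExpressionDataset":
        """Return a copy with the tumor/normal assignment exchanged."""
        return ExpressionDataset(
            self.values.copy(), self.classes.copy(), tumor_label=self.normal_label
        )

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[gene_ids], self.classes, tumor_label=self.tumor_label
        )


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_labels(path, tumor_label: str | None = None) -> pd.Series:
    """Read a two-column sample/class file into a Series."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"label file {path} must have two columns (sample, class)")
    # tolerate an optional header line
    if str(df.iloc[0, 0]).lower() in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    labels = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise DataError(
            f"label file {path} must define exactly two classes, found {classes!r}"
        )
    return labels


def read_expression(
    matrix_path, labels_path, tumor_label: str = "tumor"
) -> ExpressionDataset:
    """Load a delimited genes x samples matrix plus its sample-class file.

    The delimiter (tab or comma) is auto-detected from the first line.  The
    matrix must carry gene identifiers in the first column and sample
    identifiers in the header row; every sample column must appear in the
    label file with one of exactly two class labels.
    """
    matrix_path = Path(matrix_path)
    sep = _detect_sep(matrix_path)
    df = pd.read_csv(
        matrix_path, sep=sep, index_col=0, comment="#", float_precision="round_trip"
    )
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        col = bad[0]
        nonnum = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise DataError(
            f"non-numeric value {nonnum.iloc[0]!r} in column {col!r}, "
            f"row {nonnum.index[0]!r} of {matrix_path}"
        )
    labels = read_labels(labels_path)
    missing = [c for c in df.columns if c not in labels.index]
    if missing:
        raise DataError(
            f"samples present in matrix but absent from labels: {missing[:5]}"
        )
    labels = labels.reindex(df.columns)
    if tumor_label not in set(labels):
        raise DataError(
            f"tumor label {tumor_label!r} not found in {labels_path}; "
            f"classes are {sorted(set(labels))!r}"
        )
    ds = ExpressionDataset(df, labels, tumor_label=tumor_label)
    logger.info(
        "loaded %d genes x %d samples (n=%d tumor, m=%d normal)",
        ds.n_genes, len(ds.sample_ids), ds.n, ds.m,
    )
    return ds


def write_matrix(values: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a genes x samples matrix with round-trip-exact float formatting."""
    values.rename_axis("gene_id").to_csv(path, sep=sep, float_format="%.17g")


def read_probe_map(path) -> dict:
    """Read a two-column probe/gene mapping file (many probes per gene allowed)."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"probe map {path} must have two columns (probe, gene)")
    if str(df.iloc[0, 0]).lower() in {"probe", "probe_id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
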