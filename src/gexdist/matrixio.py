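"""Expression-matrix container, delimited-text I/O, and the low-expression filter.

Matrices are gene-by-sample tables of non-negative normalized expression
(TPM or similar) with a header row of sample IDs and a first column of
gene IDs.  Synthetic matrices from families with real support may contain
negatives; this is flagged in ``meta`` rather than rejected.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "filter_low_expression",
]


class MatrixParseError(ValueError):
    """An expression-matrix file failed validation."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with identifiers.

    ``values`` is a DataFrame indexed by gene ID with sample-ID columns.
    ``labels``, when present, maps sample ID to class label.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise MatrixParseError(f"duplicated gene id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise MatrixParseError(f"duplicated sample id: {dup!r}")
        if not np.issubdtype(v.to_numpy().dtype, np.number):
            raise MatrixParseError("non-numeric expression values")
        if np.isnan(v.to_numpy()).any():
            gene = v.index[np.isnan(v.to_numpy()).any(axis=1)][0]
            raise MatrixParseError(f"missing value in gene {gene!r}")
        if self.labels is not None:
            self.labels = self.labels.reindex(v.columns)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()][0]
                raise MatrixParseError(f"no class label for sample {missing!r}")
        if (v.to_numpy() < 0).any():
            self.meta.setdefault("has_negative_values", True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        lab = self.labels.loc[sample_ids] if self.labels is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], labels=lab)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], labels=self.labels)


_SEPS = {"tsv": "\t", "csv": ","}


def read_expression_matrix(path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a genes-in-rows expression matrix.

    ``fmt`` is ``tsv``, ``csv``, or ``mtx-triplet`` (Matrix Market
    coordinate file plus sibling ``<path>.rows`` / ``<path>.cols`` ID
    lists, one per line).
    """
    path = Path(path)
    if fmt == "mtx-triplet":
        from scipy.io import mmread

        m = mmread(str(path))
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        arr = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
        if arr.shape != (len(rows), len(cols)):
            raise MatrixParseError(
                f"mtx shape {arr.shape} does not match id lists "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        return ExpressionMatrix(pd.DataFrame(arr, index=rows, columns=cols))
    if fmt not in _SEPS:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        df = pd.read_csv(
            path, sep=_SEPS[fmt], index_col=0, comment="#",
            float_precision="round_trip",
        )
    except pd.errors.ParserError as e:
        raise MatrixParseError(f"{path}: {e}") from e
    bad = df.columns[
        [not np.issubdtype(df[c].dtype, np.number) for c in df.columns]
    ]
    for c in bad:
        col = pd.to_numeric(df[c], errors="coerce")
        row = col.index[col.isna() & df[c].notna()]
        if len(row):
            line = df.index.get_loc(row[0]) + 2  # header + 1-based
            raise MatrixParseError(
                f"{path}: non-numeric value {df.loc[row[0], c]!r} "
                f"(gene {row[0]!r}, sample {c!r}, line {line})"
            )
        df[c] = col
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    """Write a matrix at full float precision (value-exact round trip)."""
    path = Path(path)
    if fmt == "mtx-triplet":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(matrix.values.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(matrix.sample_ids) + "\n")
        return
    if fmt not in _SEPS:
        raise ValueError(f"unknown format {fmt!r}")
    buf = io.StringIO()
    matrix.values.to_csv(buf, sep=_SEPS[fmt], float_format=None, lineterminator="\n")
    path.write_text(buf.getvalue())


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, label) TSV; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise MatrixParseError(f"{path}: expected two tab-separated columns")
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise MatrixParseError(f"{path}: duplicated sample id {dup!r}")
    return s


def write_labels(labels: pd.Series, path) -> None:
    Path(path).write_text(
        "".join(f"{sid}\t{lab}\n" for sid, lab in labels.items())
    )


def filter_low_expression(
    matrix: ExpressionMatrix,
    zero_fraction: float = 0.95,
    drop_all_zero: bool = False,
) -> ExpressionMatrix:
    """Remove genes whose fraction of exactly-zero entries exceeds the cutoff.

    A gene is removed when ``#zeros / n_samples`` is *strictly* greater
    than ``zero_fraction``.  ``drop_all_zero`` additionally removes genes
    with zero expression across all samples (fraction exactly 1.0, which
    the strict comparison otherwise keeps at ``zero_fraction=1.0``).
    """
    if not 0 <= zero_fraction <= 1:
        raise ValueError("zero_fraction must be in [0, 1]")
    frac = (matrix.values == 0).mean(axis=1)
    keep = ~(frac > zero_fraction)
    if drop_all_zero:
        keep &= frac < 1.0
    removed = list(matrix.values.index[~keep])
    if not keep.any():
        warnings.warn("all genes removed by the zero-expression filter")
    out = ExpressionMatrix(matrix.values.loc[keep], labels=matrix.labels)
    out.meta["removed_genes"] = removed
    return out
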