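"""Gene-by-sample expression container and its tab-separated on-disk format.

The whole pipeline operates on non-negative abundance matrices (TPM-like
values or raw counts) with genes in rows and samples in columns, plus a
per-sample cohort/batch label. ``ExpressionMatrix`` is a thin, validated
wrapper around a :class:`pandas.DataFrame` in that orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
]

VALID_UNITS = ("TPM-like", "counts")


class FormatError(ValueError):
    """A file or in-memory table violates the expected schema."""


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples abundance matrix with batch metadata.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns. All
        entries must be finite and >= 0.
    unit
        Either ``"TPM-like"`` (within-sample normalized abundances) or
        ``"counts"``.
    batch
        Mapping sample id -> cohort/batch label. Every sample must have a
        label; samples without a meaningful cohort get a shared default.
    """

    values: pd.DataFrame
    unit: str = "TPM-like"
    batch: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        neg = arr < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise FormatError(
                f"negative value {arr[g, s]} at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if not self.batch:
            self.batch = {s: "batch0" for s in self.values.columns}
        missing = [s for s in self.values.columns if s not in self.batch]
        if missing:
            raise FormatError(f"samples missing batch labels: {missing[:5]}")
        # drop labels for samples not present (keeps subsetting painless)
        self.batch = {s: self.batch[s] for s in self.values.columns}

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit, dict(self.batch))

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples], self.unit, {s: self.batch[s] for s in samples}
        )

    def sample(self, sample_id: str) -> pd.Series:
        """Expression column of one sample, indexed by gene id."""
        return self.values[sample_id]


def read_expression_tsv(path, unit: str = "TPM-like",
                        batch: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV (gzip transparently supported).

    Layout: header row of sample ids, first column gene ids, numeric body.
    Row and column order are preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    nonnum = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    for col in nonnum:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[np.argmax(bad.to_numpy())]
            raise FormatError(
                f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    return ExpressionMatrix(df, unit=unit, batch=batch or {})


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_labels_tsv(path) -> dict[str, str]:
    """Read a two-column (sample_id, label) TSV with header into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs two columns (sample_id, label)")
    sid, lab = df.columns[:2]
    if df[sid].duplicated().any():
        raise FormatError("duplicate sample ids in label file")
    return dict(zip(df[sid], df[lab]))


def write_labels_tsv(labels: dict[str, str], path, label_name: str = "label") -> None:
    pd.DataFrame(
        {"sample_id": list(labels), label_name: [labels[s] for s in labels]}
    ).to_csv(path, sep="\t", index=False)
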