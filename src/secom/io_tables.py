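"""Reading, writing and validating taxon-by-sample count tables.

The contract formats are delimited text (TSV/CSV). A count table is stored
with taxa as rows and samples as columns (the usual OTU-table convention);
an ``orientation`` flag handles transposed files. Per-sample metadata
(ecosystem / body-site label, subject identifier) travels on the
:class:`CountTable` itself and can be attached from a separate metadata
table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "read_count_table",
    "write_count_table",
    "attach_sample_metadata",
    "filter_prevalence",
    "read_correlation",
    "write_correlation",
]


class CountTableError(ValueError):
    """Raised for malformed or inconsistent count-table input."""


@dataclass
class CountTable:
    """Observed taxon x sample counts O_ij with optional sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_taxa, n_samples)``.
    taxon_ids, sample_ids
        Unique string identifiers matching the matrix dimensions.
    ecosystem
        Optional per-sample ecosystem / body-site label.
    subject
        Optional per-sample subject identifier, used to pair samples of the
        same individual across ecosystems.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    ecosystem: list[str] | None = None
    subject: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountTableError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                raise CountTableError("counts must be integers")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise CountTableError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        d, n = self.counts.shape
        if len(self.taxon_ids) != d:
            raise CountTableError(f"{len(self.taxon_ids)} taxon ids for {d} rows")
        if len(self.sample_ids) != n:
            raise CountTableError(f"{len(self.sample_ids)} sample ids for {n} columns")
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise CountTableError(f"duplicate {name} ids: {dupes}")
        for name, meta in (("ecosystem", self.ecosystem), ("subject", self.subject)):
            if meta is not None:
                meta = [str(m) for m in meta]
                if len(meta) != n:
                    raise CountTableError(f"{name} labels do not match sample count")
                setattr(self, name, meta)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, idx: Sequence[int]) -> "CountTable":
        idx = list(idx)
        return CountTable(
            counts=self.counts[:, idx],
            taxon_ids=list(self.taxon_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            ecosystem=None if self.ecosystem is None else [self.ecosystem[i] for i in idx],
            subject=None if self.subject is None else [self.subject[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and self.ecosystem == other.ecosystem
            and self.subject == other.subject
        )


def _delimiter(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_count_table(
    path: str | os.PathLike,
    orientation: Literal["taxa_by_samples", "samples_by_taxa"] = "taxa_by_samples",
    delimiter: str | None = None,
) -> CountTable:
    """Read a delimited count table.

    The file must have a header row and a leading identifier column. The
    returned table is always in taxa x samples orientation.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise CountTableError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=_delimiter(path, delimiter), index_col=0)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountTableError(f"could not parse {path}: {exc}") from exc
    if orientation == "samples_by_taxa":
        df = df.T
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            try:
                pd.to_numeric(df[col])
            except Exception as exc:
                raise CountTableError(
                    f"non-numeric entry in column {col!r} of {path}"
                ) from exc
        values = df.apply(pd.to_numeric).to_numpy()
    return CountTable(
        counts=values,
        taxon_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def write_count_table(
    table: CountTable,
    path: str | os.PathLike,
    delimiter: str | None = None,
    metadata_path: str | os.PathLike | None = None,
) -> None:
    """Write counts as a labeled TSV/CSV; metadata to an optional sidecar."""
    df = table.to_frame()
    df.index.name = "taxon_id"
    df.to_csv(path, sep=_delimiter(path, delimiter))
    if metadata_path is not None:
        meta = pd.DataFrame({"sample_id": table.sample_ids})
        if table.ecosystem is not None:
            meta["ecosystem"] = table.ecosystem
        if table.subject is not None:
            meta["subject"] = table.subject
        meta.to_csv(metadata_path, sep=_delimiter(metadata_path, delimiter), index=False)


def attach_sample_metadata(
    table: CountTable,
    metadata: pd.DataFrame | str | os.PathLike,
    sample_col: str = "sample_id",
    ecosystem_col: str | None = None,
    subject_col: str | None = None,
    delimiter: str | None = None,
) -> CountTable:
    """Attach ecosystem / subject labels from a sample metadata table."""
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep=_delimiter(metadata, delimiter), dtype=str)
    if sample_col not in metadata.columns:
        raise CountTableError(f"metadata lacks sample column {sample_col!r}")
    meta = metadata.set_index(metadata[sample_col].astype(str))
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise CountTableError(f"metadata missing samples: {missing[:5]}")
    kwargs: dict = {}
    for attr, col in (("ecosystem", ecosystem_col), ("subject", subject_col)):
        if col is not None:
            if col not in meta.columns:
                raise CountTableError(f"metadata lacks column {col!r}")
            kwargs[attr] = [str(meta.loc[s, col]) for s in table.sample_ids]
    return replace(table, **kwargs)


def filter_prevalence(table: CountTable, min_prevalence: float = 0.10) -> CountTable:
    """Drop taxa observed (count > 0) in fewer than ``min_prevalence`` of samples.

    The sample set is unchanged. ``min_prevalence = 0`` disables filtering.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise CountTableError("min_prevalence must lie in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise CountTableError(
            f"prevalence filter at {min_prevalence} removed every taxon"
        )
    return CountTable(
        counts=table.counts[keep],
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        sample_ids=list(table.sample_ids),
        ecosystem=None if table.ecosystem is None else list(table.ecosystem),
        subject=None if table.subject is None else list(table.subject),
    )


def write_correlation(
    matrix: np.ndarray | pd.DataFrame,
    path: str | os.PathLike,
    format: Literal["matrix_tsv", "edge_list"] = "matrix_tsv",
    taxon_ids: Sequence[str] | None = None,
    measure: str = "pearson",
    p_values: np.ndarray | None = None,
    overlap: np.ndarray | None = None,
    delimiter: str | None = None,
) -> None:
    """Write a square correlation matrix as a labeled table or an edge list.

    The edge list emits one row per unordered off-diagonal pair with a
    nonzero estimate: ``taxon_a, taxon_b, measure, estimate, p_value,
    n_overlap``.
    """
    if isinstance(matrix, pd.DataFrame):
        taxon_ids = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise CountTableError(f"correlation matrix must be square, got {matrix.shape}")
    d = matrix.shape[0]
    if taxon_ids is None:
        taxon_ids = [f"T{k + 1}" for k in range(d)]
    if len(taxon_ids) != d:
        raise CountTableError("taxon labels do not match matrix dimension")
    sep = _delimiter(path, delimiter)
    if format == "matrix_tsv":
        df = pd.DataFrame(matrix, index=taxon_ids, columns=taxon_ids)
        df.index.name = "taxon_id"
        df.to_csv(path, sep=sep, float_format="%.15g")
    elif format == "edge_list":
        rows = []
        for l in range(d):
            for m in range(l + 1, d):
                if matrix[l, m] != 0:
                    rows.append(
                        {
                            "taxon_a": taxon_ids[l],
                            "taxon_b": taxon_ids[m],
                            "measure": measure,
                            "estimate": matrix[l, m],
                            "p_value": np.nan if p_values is None else p_values[l, m],
                            "n_overlap": -1 if overlap is None else int(overlap[l, m]),
                        }
                    )
        cols = ["taxon_a", "taxon_b", "measure", "estimate", "p_value", "n_overlap"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False, float_format="%.15g")
    else:
        raise CountTableError(f"unknown correlation format {format!r}")


def read_correlation(path: str | os.PathLike, delimiter: str | None = None) -> pd.DataFrame:
    """Read a labeled square correlation matrix written by :func:`write_correlation`."""
    df = pd.read_csv(path, sep=_delimiter(path, delimiter), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise CountTableError(f"correlation matrix in {path} is not square: {df.shape}")
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df
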