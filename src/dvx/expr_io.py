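"""Expression-matrix I/O, quantile normalization and cross-dataset harmonization.

Matrices are plain tab-delimited text: first column gene identifiers (header
field ``gene_id``), remaining columns one sample each.  Values are assumed to
be log2-scale intensities; an optional ``log2(x + offset)`` transform is
available at read time for raw-scale inputs.  Missing values are rejected,
never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_annotation",
    "write_sample_annotation",
    "quantile_normalize",
    "intersect_features",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of normalized log2-scale intensities.

    Attributes
    ----------
    gene_ids : tuple of str
        Row identifiers, unique, order preserved.
    sample_ids : tuple of str
        Column identifiers, unique, order preserved.
    values : numpy.ndarray
        Float matrix of shape ``(len(gene_ids), len(sample_ids))``; all
        entries finite.
    dataset_id : str
        Label for the cohort the matrix came from.
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray
    dataset_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.gene_ids) == 0:
            raise ValueError("expression matrix must contain at least one gene")
        if len(self.sample_ids) == 0:
            raise ValueError("expression matrix must contain at least one sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame view (genes as index, samples as columns)."""
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_samples(self, sample_ids) -> np.ndarray:
        """Return the value sub-matrix for the given sample columns."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix {self.dataset_id!r}: {missing}")
        idx = [pos[s] for s in sample_ids]
        return self.values[:, idx]


@dataclass(frozen=True)
class SampleAnnotation:
    """Mapping of sample id to (group label, dataset id)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        table = self.table
        required = {"sample_id", "group_label", "dataset_id"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"annotation missing required column(s): {sorted(missing)}")
        table = table.astype({c: str for c in required})
        if table["sample_id"].duplicated().any():
            dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample identifier in annotation: {dup!r}")
        if (table["group_label"].str.len() == 0).any():
            raise ValueError("empty group label in annotation")
        object.__setattr__(self, "table", table.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.table["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample: {sample_id!r}")
        return row["group_label"].iloc[0]

    def samples_in_group(self, group_label: str, dataset_id: str | None = None):
        """Sample ids annotated with ``group_label`` (optionally one dataset)."""
        t = self.table
        mask = t["group_label"] == group_label
        if dataset_id is not None:
            mask &= t["dataset_id"] == dataset_id
        return list(t.loc[mask, "sample_id"])


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_matrix(
    path, dataset_id: str = "", log2_transform: bool = False, log2_offset: float = 1.0
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First column holds gene identifiers, first row the sample identifiers.
    Duplicate gene ids and non-numeric cells raise ``ValueError`` naming the
    offending location.  When ``log2_transform`` is set the values are
    transformed as ``log2(x + log2_offset)`` (for raw-scale inputs).
    """
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise ValueError(f"empty or sample-less expression matrix: {path}")
    gene_ids = list(raw.iloc[:, 0])
    sample_ids = list(raw.columns[1:])
    cells = raw.iloc[:, 1:]
    values = np.empty(cells.shape, dtype=float)
    for j, col in enumerate(cells.columns):
        bad = pd.to_numeric(cells[col], errors="coerce").isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {cells[col].iloc[i]!r} at gene "
                f"{gene_ids[i]!r}, sample {col!r}"
            )
        # exact (correctly rounded) parse so write -> read round-trips
        values[:, j] = [float(v) for v in cells[col]]
    if log2_transform:
        shifted = values + log2_offset
        if np.any(shifted <= 0):
            raise ValueError("log2 transform undefined: values + offset must be > 0")
        values = np.log2(shifted)
    return ExpressionMatrix(gene_ids, sample_ids, values, dataset_id=dataset_id)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV at full precision (round-trips bit-identically)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_annotation(path) -> SampleAnnotation:
    """Read a TSV annotation with columns sample_id, group_label, dataset_id."""
    table = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    return SampleAnnotation(table)


def write_sample_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize sample columns to a common distribution.

    After normalization every column holds the identical sorted value multiset:
    the per-rank means across samples.  Tied values within a column receive
    the mean of the rank-means their positions span, so the result is
    deterministic and invariant to input row order.  Idempotent.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    values = matrix.values
    # Per-rank means of the column-sorted matrix define the target distribution.
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = rank_means
        # Average over each tie group (equal input values share one output).
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return replace(matrix, values=out)


def intersect_features(matrices) -> list:
    """Restrict matrices to their common genes, rows sorted lexicographically.

    Mirrors cross-platform harmonization where only probes present on every
    array are retained.  Raises on an empty intersection.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no genes common to all matrices")
    ordered = sorted(common)
    out = []
    for m in matrices:
        pos = {g: i for i, g in enumerate(m.gene_ids)}
        idx = [pos[g] for g in ordered]
        out.append(replace(m, gene_ids=tuple(ordered), values=m.values[idx, :]))
    return out
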