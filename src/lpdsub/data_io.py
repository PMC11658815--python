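"""Input/output and preprocessing for count matrices, clinical tables and manifests.

Matrices are stored gene x sample (genes in rows), mirroring the usual layout
of bulk RNA-seq count files.  The containers are thin wrappers around pandas
DataFrames that enforce the invariants the downstream model relies on
(non-negative integer counts, finite log-expression, unique labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class DataError(ValueError):
    """Raised when an input file or matrix violates a format contract."""


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what} ids: {dup[:5]}")


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes x samples."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DataError("count matrix must be 2-dimensional")
        g, d = self.values.shape
        if g != len(self.gene_ids) or d != len(self.sample_ids):
            raise DataError(
                f"label counts ({len(self.gene_ids)} genes, {len(self.sample_ids)} "
                f"samples) do not match matrix shape {self.values.shape}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            bad = ~np.isclose(self.values, rounded)
            if bad.any():
                gi, di = np.argwhere(bad)[0]
                raise DataError(
                    f"non-integer count {self.values[gi, di]!r} at gene "
                    f"{self.gene_ids[gi]!r}, sample {self.sample_ids[di]!r}"
                )
            self.values = rounded.astype(np.int64)
        if (self.values < 0).any():
            gi, di = np.argwhere(self.values < 0)[0]
            raise DataError(
                f"negative count {self.values[gi, di]} at gene "
                f"{self.gene_ids[gi]!r}, sample {self.sample_ids[di]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Real-valued log-scale expression, genes x samples."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression matrix must be 2-dimensional")
        g, d = self.values.shape
        if g != len(self.gene_ids) or d != len(self.sample_ids):
            raise DataError(
                f"label counts do not match matrix shape {self.values.shape}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise DataError("expression matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(sample_ids))


SAMPLE_TYPES = {"primary", "metastatic", "cell_line", "ctc", "normal"}


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates keyed to expression-matrix columns.

    Only ``sample_id`` is mandatory; survival fields (``time``, ``event``)
    travel together.  Missing values are permitted and excluded pairwise by
    each downstream test.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise DataError("clinical table requires a sample_id column")
        _check_unique(self.table["sample_id"], "sample")
        if "time" in self.table.columns:
            t = self.table["time"].dropna()
            if (t < 0).any():
                raise DataError("survival times must be non-negative")
            if "event" not in self.table.columns:
                raise DataError("event column required when time is present")
            has_time = self.table["time"].notna()
            if self.table.loc[has_time, "event"].isna().any():
                raise DataError("event must be present wherever time is")
        if "event" in self.table.columns:
            ev = self.table["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise DataError("event flags must be 0 or 1")
        if "sample_type" in self.table.columns:
            st = self.table["sample_type"].dropna()
            bad = set(st) - SAMPLE_TYPES
            if bad:
                raise DataError(f"unknown sample types: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def survival(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        """Return (sample_id, time, event) rows with complete survival data."""
        df = self.table
        if sample_ids is not None:
            df = df[df["sample_id"].isin(sample_ids)]
        if "time" not in df.columns:
            return pd.DataFrame(columns=["sample_id", "time", "event"])
        df = df.dropna(subset=["time", "event"])
        return df[["sample_id", "time", "event"]].reset_index(drop=True)


@dataclass
class DatasetManifest:
    """Per-dataset sample counts per sample type (a cohort overview table)."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ds, row in self.counts.items():
            for st, n in row.items():
                if n < 0:
                    raise DataError(f"negative count for {ds}/{st}")


def read_count_matrix(path: str | Path, delimiter: str = "\t") -> CountMatrix:
    """Read a genes-x-samples integer count matrix.

    The first row holds sample ids, the first column gene ids.  Non-integer
    or negative entries raise :class:`DataError` naming the offending cell.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return CountMatrix(
        df.to_numpy(),
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
    )


def write_count_matrix(counts: CountMatrix, path: str | Path, delimiter: str = "\t") -> None:
    counts.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def read_clinical_table(
    path: str | Path,
    delimiter: str = "\t",
    column_map: dict[str, str] | None = None,
) -> ClinicalTable:
    """Read a clinical covariate table; ``column_map`` renames file columns
    to the canonical names (sample_id, sample_type, age, sex, ethnicity,
    vital_status, time, event)."""
    df = pd.read_csv(path, sep=delimiter)
    if column_map:
        df = df.rename(columns=column_map)
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path: str | Path, delimiter: str = "\t") -> None:
    clinical.table.to_csv(path, sep=delimiter, index=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a YAML manifest mapping dataset name -> {sample_type: count}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DatasetManifest({ds: dict(row) for ds, row in raw.items()})


def log_normalize(counts: CountMatrix, size_factors: np.ndarray) -> ExpressionMatrix:
    """log2(count / size_factor + 1) per gene and sample.

    Size factors must be strictly positive, one per sample; the +1 pseudocount
    keeps zero counts at exactly zero log-expression.
    """
    sf = np.asarray(size_factors, dtype=float)
    if sf.shape != (len(counts.sample_ids),):
        raise DataError(
            f"expected {len(counts.sample_ids)} size factors, got {sf.shape}"
        )
    if (sf <= 0).any() or not np.isfinite(sf).all():
        raise DataError("size factors must be strictly positive and finite")
    vals = np.log2(counts.values / sf[None, :] + 1.0)
    return ExpressionMatrix(vals, list(counts.gene_ids), list(counts.sample_ids))


def select_top_variance(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the n genes with the largest per-gene sample variance.

    Original gene order is preserved; exact variance ties are broken by gene
    id lexicographic order so the selection is deterministic.
    """
    g = len(expr.gene_ids)
    if n > g:
        raise DataError(f"requested {n} genes but matrix has only {g}")
    if n < 1:
        raise DataError("n must be positive")
    var = expr.values.var(axis=1, ddof=1) if expr.values.shape[1] > 1 else np.zeros(g)
    # sort by (-variance, gene id) then keep the first n, reported in input order
    order = sorted(range(g), key=lambda i: (-var[i], expr.gene_ids[i]))
    keep = sorted(order[:n])
    return ExpressionMatrix(
        expr.values[keep, :],
        [expr.gene_ids[i] for i in keep],
        list(expr.sample_ids),
    )


def summarize_manifest(manifest: DatasetManifest) -> dict:
    """Total sample count plus per-type and per-dataset totals."""
    if not manifest.counts:
        raise DataError("empty manifest")
    per_type: dict[str, int] = {}
    per_dataset: dict[str, int] = {}
    for ds, row in manifest.counts.items():
        per_dataset[ds] = sum(row.values())
        for st, n in row.items():
            per_type[st] = per_type.get(st, 0) + n
    return {
        "total": sum(per_dataset.values()),
        "per_type": per_type,
        "per_dataset": per_dataset,
    }
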