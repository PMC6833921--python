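"""Expression-matrix container, table I/O and per-gene min–max normalization.

The pipeline consumes a nonnegative gene × sample matrix. Tables are
delimited text (CSV/TSV) or a single-sheet spreadsheet, with gene IDs in the
first column and sample names in the header row. Before factorization each
gene row is rescaled to [0, 1] by its own range (min–max normalization), so
that genes with large absolute counts do not dominate the Frobenius
objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdentifierError,
    MalformedInputError,
    StateError,
)

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "write_expression_table",
    "normalize_rows",
    "write_outputs",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A nonnegative gene × sample expression matrix.

    Attributes
    ----------
    values
        float array of shape (n_genes, n_samples); nonnegative, finite.
    gene_ids, sample_ids
        Unique row and column identifiers, in file order.
    group_of_sample
        Optional map sample name -> replicate-group label.
    normalized
        True after per-gene min–max normalization.
    row_min, row_max
        Per-gene range retained by :func:`normalize_rows` for reporting;
        None on raw matrices.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    group_of_sample: Mapping[str, str] | None = None
    normalized: bool = False
    row_min: np.ndarray | None = field(default=None, repr=False)
    row_max: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n, m = vals.shape
        if n < 1 or m < 2:
            raise MalformedInputError(
                f"need at least 1 gene and 2 samples, got {n} x {m}"
            )
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise MalformedInputError("identifier counts do not match matrix shape")
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if list(ids).count(x) > 1})
                raise DuplicateIdentifierError(f"duplicate {kind} IDs: {dupes[:5]}")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise MalformedInputError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise MalformedInputError(
                f"negative value {vals[i, j]} at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def read_expression_table(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a gene × sample table from CSV, TSV or XLSX.

    First column = gene IDs, header row = sample names, all data cells
    numeric and nonnegative. ``format`` is inferred from the file suffix
    when omitted. XLSX ingestion reads the first worksheet only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "xlsx":
        df = pd.read_excel(path, sheet_name=0, index_col=0)
    elif format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
    else:
        raise ValueError(f"unknown format {format!r}")

    gene_ids = tuple(str(g) for g in df.index)
    sample_ids = tuple(str(s) for s in df.columns)
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        # locate the offending cell for the error message
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise MalformedInputError(
                    f"non-numeric cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from exc
        raise MalformedInputError(str(exc)) from exc
    if np.any(pd.isna(vals)):
        i, j = np.argwhere(pd.isna(vals))[0]
        raise MalformedInputError(
            f"missing cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(values=vals, gene_ids=gene_ids, sample_ids=sample_ids)


def write_expression_table(x: ExpressionMatrix, path: str | Path) -> Path:
    """Write the matrix in the same dialect ``read_expression_table`` reads."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    x.to_frame().to_csv(path, sep=sep)
    return path


def normalize_rows(x: ExpressionMatrix) -> ExpressionMatrix:
    """Min–max normalize each gene row to [0, 1].

    For gene row ``i`` with max ``b_i`` and min ``a_i`` the output row is
    ``(row - a_i) / (b_i - a_i)``. Constant rows (``b_i == a_i``) carry no
    class signal and are mapped to all zeros; their count is retained in
    the model report downstream.
    """
    if x.normalized:
        raise StateError("matrix is already normalized")
    vals = x.values
    b = vals.max(axis=1)
    a = vals.min(axis=1)
    span = b - a
    const = span == 0
    safe = np.where(const, 1.0, span)
    out = (vals - a[:, None]) / safe[:, None]
    out[const, :] = 0.0
    return replace(x, values=out, normalized=True, row_min=a, row_max=b)


def write_outputs(model, r_matrix, dir: str | Path) -> dict[str, Path]:
    """Persist a factorization and its membership matrix.

    Writes ``W.csv`` (gene × class), ``H.csv`` (class × sample),
    ``R.csv`` (class × sample membership degrees) and ``report.txt``
    (objective trace, KKT ratios, seed, solver configuration).
    Returns a name -> path map of everything written.
    """
    from dataclasses import asdict

    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    r = model.r
    class_labels = [f"class_{i + 1}" for i in range(r)]
    gene_ids = list(model.gene_ids) if model.gene_ids is not None else [
        f"g{i + 1}" for i in range(model.W.shape[0])
    ]
    sample_ids = list(model.sample_ids) if model.sample_ids is not None else [
        f"s{j + 1}" for j in range(model.H.shape[1])
    ]

    paths: dict[str, Path] = {}
    wdf = pd.DataFrame(model.W, index=gene_ids, columns=class_labels)
    paths["W"] = dir / "W.csv"
    wdf.to_csv(paths["W"])
    hdf = pd.DataFrame(model.H, index=class_labels, columns=sample_ids)
    paths["H"] = dir / "H.csv"
    hdf.to_csv(paths["H"])
    rdf = pd.DataFrame(r_matrix.R, index=class_labels, columns=sample_ids)
    paths["R"] = dir / "R.csv"
    rdf.to_csv(paths["R"])

    report = {
        "rank": r,
        "seed": model.seed,
        "converged": model.converged,
        "outer_iters": model.outer_iters,
        "objective_trace": [float(v) for v in model.objective_trace],
        "kkt_ratio_trace": [float(v) for v in model.kkt_ratio_trace],
        "config": asdict(model.config) if model.config is not None else None,
    }
    paths["report"] = dir / "report.txt"
    paths["report"].write_text(json.dumps(report, indent=2) + "\n")
    return paths
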