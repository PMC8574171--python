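"""Readers and writers for count matrices, cell metadata, gene sets, reports.

External formats are deliberately plain: dense TSV (tab separator, ``.``
decimal mark, UTF-8, first row = cell ids, first column = gene symbols),
MatrixMarket ``.mtx`` with sidecar ``genes.txt`` / ``cells.txt`` name files,
two-column cell metadata TSV, and one-symbol-per-line gene-set text files
(``#`` comments allowed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CellAnnotation, CountMatrix, GeneSet
from ._utils import round_half_away


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("tsv", "mtx"):
            raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")
        return format
    return "mtx" if path.suffix == ".mtx" else "tsv"


def _read_names(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"sidecar {what} file not found: {path}")
    names = [ln.strip() for ln in path.read_text().splitlines()]
    return [n for n in names if n]


def read_count_matrix(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    stage: str = "raw",
) -> CountMatrix:
    """Read a genes x cells count matrix from dense TSV or MatrixMarket.

    For ``.mtx`` input the row (gene) and column (cell) names are read from
    ``genes.txt`` / ``cells.txt`` next to the matrix unless explicit paths
    are given; entries absent from the sparse file are zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        genes = _read_names(
            Path(genes_path) if genes_path else path.parent / "genes.txt", "gene-name"
        )
        cells = _read_names(
            Path(cells_path) if cells_path else path.parent / "cells.txt", "cell-name"
        )
        mat = scipy.io.mmread(path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecar names "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return CountMatrix(values, genes, cells, stage=stage)

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            values[:, j] = raw[col].to_numpy(dtype=float)
        except (TypeError, ValueError):
            for i, entry in enumerate(raw[col]):
                try:
                    float(entry)
                except (TypeError, ValueError):
                    # header is line 1, so data row i lives on line i + 2
                    raise ValueError(
                        f"parse error in {path} at line {i + 2}: "
                        f"non-numeric value {entry!r} for gene "
                        f"{raw.index[i]!r}, cell {col!r}"
                    ) from None
            raise
    return CountMatrix(
        values, list(raw.index.astype(str)), list(raw.columns.astype(str)), stage=stage
    )


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a count matrix as dense TSV or MatrixMarket with sidecars."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.values))
        (path.parent / "genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        matrix.to_frame().to_csv(path, sep="\t")


def read_cell_annotation(path: str | Path) -> CellAnnotation:
    """Read a cell metadata TSV with columns ``cell_id``, ``group`` [, ``donor``]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cell metadata not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (cell_id, group)")
    frame = frame.rename(
        columns={frame.columns[0]: "cell_id", frame.columns[1]: "group"}
    ).set_index("cell_id")
    return CellAnnotation(frame)


def write_cell_annotation(ann: CellAnnotation, path: str | Path) -> None:
    ann.frame.rename_axis("cell_id").to_csv(path, sep="\t")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene set (``#`` comments and blanks skipped).

    Symbols are de-duplicated case-insensitively, keeping the casing of the
    first occurrence.  An empty file (or comments only) is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set not found: {path}")
    symbols = []
    for ln in path.read_text().splitlines():
        s = ln.strip()
        if s and not s.startswith("#"):
            symbols.append(s)
    if not symbols:
        raise ValueError(f"gene set file {path} contains no symbols")
    return GeneSet(name=name or path.stem, symbols=symbols, source=str(path))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_set.symbols) + "\n")


def read_edge_table(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a scored interaction edge table (source, target, combined_score)."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: expected three columns (source, target, score)")
    return [
        (str(r.iloc[0]), str(r.iloc[1]), float(r.iloc[2]))
        for _, r in frame.iterrows()
    ]


def _record_to_mapping(record) -> Mapping:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, Mapping):
        return record
    raise TypeError(f"cannot tabulate record of type {type(record).__name__}")


def write_table(
    rows: Sequence,
    path: str | Path,
    sort: bool = True,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records (dicts or dataclasses sharing one schema) as TSV.

    Percentage columns (``*_pct``) are formatted with one decimal; rows are
    ordered deterministically by gene symbol then group when those columns
    exist.  An empty record list yields a header-only file (pass
    ``columns`` to name the header when no record carries the schema).
    """
    records = [_record_to_mapping(r) for r in rows]
    if records:
        schema = list(records[0].keys())
        for r in records[1:]:
            if list(r.keys()) != schema:
                raise ValueError(
                    f"records with mixed schemas: {schema} vs {list(r.keys())}"
                )
        frame = pd.DataFrame(records, columns=schema)
    else:
        frame = pd.DataFrame(columns=list(columns or []))
    if sort:
        keys = [c for c in ("gene", "group") if c in frame.columns]
        if keys and len(frame):
            frame = frame.sort_values(keys, kind="mergesort")
    for col in frame.columns:
        if str(col).endswith("_pct"):
            frame[col] = [
                "" if v is None or (isinstance(v, float) and np.isnan(v))
                else f"{round_half_away(v, 1):.1f}"
                for v in frame[col]
            ]
    frame.to_csv(path, sep="\t", index=False)


def packaged_amp_gene_set() -> GeneSet:
    """The packaged synthetic 186-entry AMP reference list.

    A synthetic stand-in for the external AMP database used in the original
    analysis: 100 published detected symbols plus 86 synthetic placeholders.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("equiphen") / "data" / "amp_reference_synthetic.txt"
    ) as p:
        return read_gene_set(p, name="amp_reference_synthetic")
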