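"""In-memory containers for count data, cell metadata and gene sets.

The central object is :class:`CountMatrix`, a dense genes x cells array of
non-negative copy numbers tagged with a processing ``stage`` (``raw`` ->
``prenormalized`` -> ``normalized``).  Cells are annotated with exactly one
group label each (:class:`CellAnnotation`), and reference lists of gene
symbols travel as :class:`GeneSet`.

Gene symbols are matched case-insensitively throughout the package: the
reference lists used in the original analysis are human-derived while the
count matrix is murine, and symbol case is the only difference the matching
layer attempts to bridge.  No ortholog mapping is performed; unmatched
symbols are reported, never silently dropped.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STAGES = ("raw", "prenormalized", "normalized")


def _find_duplicates(items: Sequence[str]) -> list[str]:
    counts = Counter(items)
    return sorted(k for k, v in counts.items() if v > 1)


@dataclasses.dataclass
class CountMatrix:
    """Dense genes x cells matrix of non-negative expression values.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Non-negative copy numbers; zeros are interpreted as gene OFF states.
    gene_ids : sequence of str
        Unique gene symbols, one per row.
    cell_ids : sequence of str
        Unique cell identifiers, one per column.
    stage : {"raw", "prenormalized", "normalized"}
        Processing stage tag.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                "negative value at gene "
                f"{self.gene_ids[bad[0]]!r}, cell {self.cell_ids[bad[1]]!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        dup_g = _find_duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene symbols: {dup_g}")
        dup_c = _find_duplicates(self.cell_ids)
        if dup_c:
            raise ValueError(f"duplicate cell identifiers: {dup_c}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        self._lower_index = {}
        for i, g in enumerate(self.gene_ids):
            self._lower_index.setdefault(g.lower(), i)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stage: str = "raw") -> "CountMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=list(frame.index.astype(str)),
            cell_ids=list(frame.columns.astype(str)),
            stage=stage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.cell_ids)
        )

    def with_values(self, values: np.ndarray, stage: str) -> "CountMatrix":
        """Same annotation, new values and stage."""
        return CountMatrix(values, list(self.gene_ids), list(self.cell_ids), stage)

    def gene_positions(self, symbols: Iterable[str]) -> list[int]:
        """Row indices for ``symbols`` (case-insensitive); KeyError if any missing."""
        positions, missing = [], []
        for s in symbols:
            i = self._lower_index.get(str(s).lower())
            (positions.append(i) if i is not None else missing.append(s))
        if missing:
            raise KeyError(f"gene symbols not in matrix: {sorted(map(str, missing))}")
        return positions

    def match_symbols(self, symbols: Iterable[str]) -> tuple[list[int], list[str], list[str]]:
        """Case-insensitive match of ``symbols`` against the gene annotation.

        Returns ``(positions, matched, unmatched)``; ``matched`` keeps the
        caller's spelling, order follows the input after de-duplication.
        """
        positions: list[int] = []
        matched: list[str] = []
        unmatched: list[str] = []
        seen: set[str] = set()
        for s in symbols:
            key = str(s).lower()
            if key in seen:
                continue
            seen.add(key)
            i = self._lower_index.get(key)
            if i is None:
                unmatched.append(str(s))
            else:
                positions.append(i)
                matched.append(str(s))
        return positions, matched, unmatched

    def subset_cells(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(
            self.values[:, keep],
            list(self.gene_ids),
            [self.cell_ids[i] for i in keep],
            self.stage,
        )


@dataclasses.dataclass
class CellAnnotation:
    """Maps each cell to a group label (and optional donor)."""

    frame: pd.DataFrame  # index: cell_id; columns: group [, donor]

    def __post_init__(self) -> None:
        if "group" not in self.frame.columns:
            raise ValueError("annotation requires a 'group' column")
        dup = _find_duplicates(list(self.frame.index.astype(str)))
        if dup:
            raise ValueError(f"duplicate cell identifiers in annotation: {dup}")
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)
        self.frame["group"] = self.frame["group"].astype(str)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "CellAnnotation":
        return cls(pd.DataFrame({"group": pd.Series(mapping, dtype=str)}))

    @classmethod
    def from_labels(cls, cell_ids: Sequence[str], groups: Sequence[str]) -> "CellAnnotation":
        return cls(pd.DataFrame({"group": list(groups)}, index=list(cell_ids)))

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, sorted."""
        return sorted(self.frame["group"].unique())

    def group_of(self, cell_id: str) -> str:
        return self.frame.loc[str(cell_id), "group"]

    def group_vector(self, matrix: CountMatrix) -> np.ndarray:
        """Group label per matrix column; every cell must be annotated."""
        missing = [c for c in matrix.cell_ids if c not in self.frame.index]
        if missing:
            raise ValueError(f"cells without annotation: {missing}")
        return self.frame.loc[matrix.cell_ids, "group"].to_numpy()

    def two_group_masks(self, matrix: CountMatrix) -> tuple[str, str, np.ndarray, np.ndarray]:
        """``(label_a, label_b, mask_a, mask_b)`` for a two-group comparison.

        Labels are ordered alphabetically; raises if the annotated cells of
        the matrix do not fall into exactly two groups.
        """
        vec = self.group_vector(matrix)
        labels = sorted(set(vec))
        if len(labels) != 2:
            raise ValueError(
                f"group comparison requires exactly two groups, found {labels}"
            )
        a, b = labels
        return a, b, vec == a, vec == b


@dataclasses.dataclass
class GeneSet:
    """A named list of unique gene symbols."""

    name: str
    symbols: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        deduped: list[str] = []
        seen: set[str] = set()
        for s in self.symbols:
            key = str(s).lower()
            if key not in seen:
                seen.add(key)
                deduped.append(str(s))
        if not deduped:
            raise ValueError(f"gene set {self.name!r} is empty")
        self.symbols = deduped

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)
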