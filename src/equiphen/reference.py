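"""Equi-phenotype reference-gene discovery.

Bursting transcription leaves most genes OFF (zero counts) in any given
cell, so classical size-factor or housekeeping-gene normalization performs
poorly on patch-seq data.  Instead, reference genes are discovered
empirically as the genes that are (1) among the most frequently detected,
(2) most stable across cells after a pre-normalization pass, and (3)
balanced between the two cell groups (< tenfold difference of group-wise
non-zero means).  The surviving genes — the "equi-phenotype" of the two
neuron types — carry per-gene targets (cross-cell averages of non-zero
values) against which each cell's RMSD-minimizing scale factor is fitted.

Selection steps, in order:

1. ``select_frequent_genes`` — top ``k_frequent`` genes by ON count.
2. ``prenormalize`` — RMSD-fit each cell against the frequent genes'
   non-zero averages (same fit as the final normalization).
3. ``select_stable_genes`` — ``k_stable`` genes with the lowest cross-cell
   standard deviation on the pre-normalized data.
4. ``filter_balanced_genes`` — keep genes detected in both groups whose
   group-wise non-zero means differ by strictly less than ``fold_threshold``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CellAnnotation, CountMatrix
from .normalize import scale_factors


@dataclasses.dataclass
class SelectionConfig:
    """Thresholds of the reference-selection cascade (defaults as published)."""

    k_frequent: int = 1000
    k_stable: int = 500
    fold_threshold: float = 10.0
    stability_mode: str = "nonzero"  # "nonzero" or "all"

    def __post_init__(self) -> None:
        if self.k_frequent < 1 or self.k_stable < 1:
            raise ValueError("k_frequent and k_stable must be positive")
        if self.k_stable > self.k_frequent:
            raise ValueError("k_stable must not exceed k_frequent")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be positive")
        if self.stability_mode not in ("nonzero", "all"):
            raise ValueError("stability_mode must be 'nonzero' or 'all'")


@dataclasses.dataclass
class ReferenceSet:
    """Ordered reference gene symbols with per-gene normalization targets."""

    symbols: list[str]
    targets: np.ndarray  # cross-cell averages of non-zero values, > 0
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if len(self.symbols) != len(self.targets):
            raise ValueError("symbols and targets length mismatch")
        if len(self.symbols) == 0:
            raise ValueError("reference set is empty")
        if np.any(self.targets <= 0):
            raise ValueError("all reference targets must be positive")

    def __len__(self) -> int:
        return len(self.symbols)

    def to_frame(self) -> pd.DataFrame:
        extra = {
            k: self.provenance[k]
            for k in ("on_count", "sd")
            if k in self.provenance and len(self.provenance[k]) == len(self.symbols)
        }
        return pd.DataFrame(
            {"symbol": self.symbols, "target": self.targets, **extra}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ReferenceSet":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            symbols=list(frame["symbol"].astype(str)),
            targets=frame["target"].to_numpy(dtype=float),
            provenance={"source": str(path)},
        )


def _ordered_top(
    matrix: CountMatrix, positions: np.ndarray, primary: np.ndarray, k: int
) -> list[str]:
    """Top-``k`` gene symbols by ``primary`` (already oriented ascending-is-better
    after negation), ties broken by larger total expression then symbol."""
    totals = matrix.values[positions].sum(axis=1)
    symbols = np.array([matrix.gene_ids[i] for i in positions])
    order = np.lexsort((symbols, -totals, primary))
    return [str(s) for s in symbols[order][:k]]


def nonzero_row_means(values: np.ndarray) -> np.ndarray:
    """Per-row mean of strictly positive entries (NaN for all-zero rows)."""
    on = values > 0
    counts = on.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = values.sum(axis=1) / counts
    return np.where(counts > 0, means, np.nan)


def select_frequent_genes(matrix: CountMatrix, k: int) -> list[str]:
    """The up-to-``k`` genes detected (value > 0) in the most cells.

    Genes never detected are excluded; ties are broken by larger total
    expression, then lexicographic symbol, for deterministic output.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    on_counts = (matrix.values > 0).sum(axis=1)
    expressed = np.flatnonzero(on_counts > 0)
    if expressed.size == 0:
        raise ValueError("no expressed genes: matrix is all zeros")
    return _ordered_top(matrix, expressed, -on_counts[expressed].astype(float), k)


def prenormalize(matrix: CountMatrix, frequent_genes: Sequence[str]) -> CountMatrix:
    """Scale every cell by its RMSD-minimizing factor on the frequent genes.

    Targets are the frequent genes' cross-cell non-zero averages on the
    input matrix.  A cell detecting none of the frequent genes cannot be
    fitted; it is left unscaled (factor 1) with a warning.
    """
    if len(frequent_genes) == 0:
        raise ValueError("frequent_genes must be non-empty")
    pos = matrix.gene_positions(frequent_genes)
    sub = matrix.values[pos]
    targets = nonzero_row_means(sub)
    usable = ~np.isnan(targets)
    if not usable.any():
        raise ValueError("none of the frequent genes is detected in any cell")
    factors, _, n_used = scale_factors(sub[usable], targets[usable])
    unfit = n_used == 0
    if unfit.any():
        bad = [matrix.cell_ids[i] for i in np.flatnonzero(unfit)]
        warnings.warn(
            f"{len(bad)} cell(s) detect no frequent gene and are left "
            f"unscaled: {bad[:5]}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
        factors = np.where(unfit, 1.0, factors)
    return matrix.with_values(matrix.values * factors[None, :], "prenormalized")


def _stability_sd(
    values: np.ndarray, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene SD (``mode='nonzero'``: over ON cells only) and ON counts."""
    on = values > 0
    n_on = on.sum(axis=1)
    if mode == "all":
        sd = values.std(axis=1, ddof=1)
        return sd, n_on
    n = n_on.astype(float)
    sums = values.sum(axis=1)
    sq = (values**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sq - sums**2 / n) / (n - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return np.where(n_on >= 2, sd, np.nan), n_on


def select_stable_genes(
    prenorm: CountMatrix,
    candidates: Sequence[str],
    k: int,
    mode: str = "nonzero",
) -> list[str]:
    """The ``k`` candidates with the smallest cross-cell standard deviation.

    By default the SD is computed over non-zero values only, consistent with
    the non-zero averaging used everywhere else; ``mode='all'`` includes
    zeros.  Genes ON in fewer than 3 cells are excluded (their SD estimate
    is unstable).  If fewer than ``k`` candidates are eligible, all eligible
    ones are returned with a warning.
    """
    if prenorm.stage != "prenormalized":
        warnings.warn(
            f"stability selection expects a prenormalized matrix, got stage "
            f"{prenorm.stage!r}",
            stacklevel=2,
        )
    pos = np.array(prenorm.gene_positions(candidates))
    sd, n_on = _stability_sd(prenorm.values[pos], mode)
    eligible = (n_on >= 3) & ~np.isnan(sd)
    if eligible.sum() < k:
        warnings.warn(
            f"only {int(eligible.sum())} of {len(candidates)} candidates are "
            f"eligible for stability ranking (requested {k})",
            stacklevel=2,
        )
    return _ordered_top(prenorm, pos[eligible], sd[eligible], k)


def filter_balanced_genes(
    prenorm: CountMatrix,
    ann: CellAnnotation,
    candidates: Sequence[str],
    fold_threshold: float = 10.0,
) -> ReferenceSet:
    """Keep candidates balanced between the two groups; build the reference set.

    A gene survives if it is ON in at least one cell of each group and the
    ratio of its group-wise non-zero means (larger/smaller) is strictly
    below ``fold_threshold``.  Targets are the overall non-zero averages on
    the pre-normalized matrix.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    label_a, label_b, mask_a, mask_b = ann.two_group_masks(prenorm)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    pos = np.array(prenorm.gene_positions(candidates))
    sub = prenorm.values[pos]
    mean_a = nonzero_row_means(sub[:, mask_a])
    mean_b = nonzero_row_means(sub[:, mask_b])
    with np.errstate(invalid="ignore"):
        ratio = np.maximum(mean_a, mean_b) / np.minimum(mean_a, mean_b)
    keep = ~np.isnan(mean_a) & ~np.isnan(mean_b) & (ratio < fold_threshold)
    if not keep.any():
        raise ValueError(
            "no candidate gene passed the between-group balance filter; "
            "consider relaxing fold_threshold or the earlier selection sizes"
        )
    kept_pos = pos[keep]
    kept_values = prenorm.values[kept_pos]
    symbols = [prenorm.gene_ids[i] for i in kept_pos]
    targets = nonzero_row_means(kept_values)
    sd, n_on = _stability_sd(kept_values, "nonzero")
    provenance = {
        "fold_threshold": fold_threshold,
        "n_candidates": len(candidates),
        "n_selected": int(keep.sum()),
        "groups": (label_a, label_b),
        "on_count": n_on.tolist(),
        "sd": sd.tolist(),
    }
    return ReferenceSet(symbols=symbols, targets=targets, provenance=provenance)


def select_reference_genes(
    matrix: CountMatrix,
    ann: CellAnnotation,
    config: SelectionConfig | None = None,
) -> tuple[ReferenceSet, CountMatrix]:
    """Run the full cascade; returns the reference set and the prenormalized matrix."""
    config = config or SelectionConfig()
    frequent = select_frequent_genes(matrix, config.k_frequent)
    prenorm = prenormalize(matrix, frequent)
    stable = select_stable_genes(
        prenorm, frequent, config.k_stable, mode=config.stability_mode
    )
    refs = filter_balanced_genes(prenorm, ann, stable, config.fold_threshold)
    refs.provenance.update(
        k_frequent=config.k_frequent,
        k_stable=config.k_stable,
        stability_mode=config.stability_mode,
    )
    return refs, prenorm
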