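"""ON/OFF-state expression statistics.

Under bursting transcription a zero count is read as the gene being OFF at
harvest time, so two numbers summarize a gene within a cell group: the
ON-state frequency (percentage of cells detecting the transcript) and the
non-zero mean (average copy number over ON cells only, the estimator of
expression level in the ON state).  This module computes those summaries,
bins genes by detection frequency, counts gene-set transcripts per cell,
compares per-cell counts between groups (Shapiro-Wilk normality record +
two-sample t-test), and measures the frequency / copy-number association
(Spearman).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CellAnnotation, CountMatrix, GeneSet
from ._utils import round_half_away


@dataclasses.dataclass
class GeneGroupSummary:
    """ON/OFF summary of one gene in one cell group (or ``"all"``)."""

    gene: str
    group: str
    n_cells: int
    on_count: int
    on_freq_pct: float  # rounded half away from zero, one decimal
    nonzero_mean: float | None  # defined iff on_count >= 1
    in_matrix: bool = True

    @property
    def on_freq_raw(self) -> float:
        """Unrounded frequency (percentage); use for binning and correlation."""
        return 100.0 * self.on_count / self.n_cells


def _summary(gene, group, values: np.ndarray, in_matrix=True) -> GeneGroupSummary:
    n = values.size
    on = values > 0
    on_count = int(on.sum())
    mean = float(values[on].mean()) if on_count else None
    return GeneGroupSummary(
        gene=str(gene),
        group=str(group),
        n_cells=n,
        on_count=on_count,
        on_freq_pct=round_half_away(100.0 * on_count / n, 1) if n else 0.0,
        nonzero_mean=mean,
        in_matrix=in_matrix,
    )


def summarize_gene(
    matrix: CountMatrix, ann: CellAnnotation, gene: str
) -> dict[str, GeneGroupSummary]:
    """Per-group and overall summaries of one gene (keys: group labels + ``"all"``).

    A gene absent from the matrix yields all-OFF summaries flagged
    ``in_matrix=False`` ("not detected") instead of an error.
    """
    vec = ann.group_vector(matrix)
    groups = sorted(set(vec))
    pos, _, unmatched = matrix.match_symbols([gene])
    if unmatched:
        zero = np.zeros(matrix.n_cells)
        out = {g: _summary(gene, g, zero[vec == g], in_matrix=False) for g in groups}
        out["all"] = _summary(gene, "all", zero, in_matrix=False)
        return out
    row = matrix.values[pos[0]]
    out = {g: _summary(gene, g, row[vec == g]) for g in groups}
    out["all"] = _summary(gene, "all", row)
    return out


def summarize_genes(
    matrix: CountMatrix,
    ann: CellAnnotation,
    genes: Sequence[str] | None = None,
) -> list[GeneGroupSummary]:
    """Summaries for many genes (per group and overall), vectorized.

    ``genes`` defaults to every gene in the matrix; symbols absent from the
    matrix yield all-OFF summaries flagged accordingly.
    """
    vec = ann.group_vector(matrix)
    groups = sorted(set(vec))
    if genes is None:
        genes = list(matrix.gene_ids)
    pos, matched, unmatched = matrix.match_symbols(genes)
    out: list[GeneGroupSummary] = []
    blocks: list[tuple[str, np.ndarray]] = [
        (g, vec == g) for g in groups
    ] + [("all", np.ones(matrix.n_cells, dtype=bool))]
    V = matrix.values[pos] if pos else np.zeros((0, matrix.n_cells))
    for group, mask in blocks:
        sub = V[:, mask]
        on = sub > 0
        on_counts = on.sum(axis=1)
        sums = sub.sum(axis=1)
        n = int(mask.sum())
        for i, sym in enumerate(matched):
            oc = int(on_counts[i])
            out.append(
                GeneGroupSummary(
                    gene=sym,
                    group=group,
                    n_cells=n,
                    on_count=oc,
                    on_freq_pct=round_half_away(100.0 * oc / n, 1) if n else 0.0,
                    nonzero_mean=float(sums[i] / oc) if oc else None,
                )
            )
        for sym in unmatched:
            out.append(
                GeneGroupSummary(
                    gene=sym, group=group, n_cells=n, on_count=0,
                    on_freq_pct=0.0, nonzero_mean=None, in_matrix=False,
                )
            )
    return out


def overall_summaries(summaries: Iterable[GeneGroupSummary]) -> list[GeneGroupSummary]:
    return [s for s in summaries if s.group == "all"]


def summaries_to_frame(summaries: Iterable[GeneGroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


@dataclasses.dataclass
class FrequencyBins:
    """Gene counts per detection-frequency band (plus never-detected)."""

    edges: tuple[float, ...]  # descending, e.g. (50, 10)
    counts: tuple[int, ...]  # len(edges) + 1 bands, most frequent first
    n_zero: int  # genes never detected (excluded from the bands)
    labels: tuple[str, ...]

    @property
    def n_binned(self) -> int:
        return sum(self.counts)


def bin_by_frequency(
    summaries: Sequence[GeneGroupSummary],
    edges: Sequence[float] = (50.0, 10.0),
) -> FrequencyBins:
    """Bin genes by unrounded overall detection frequency.

    With the default edges ``(50, 10)`` the bands are [50, 100], [10, 50)
    and (0, 10) — "at least half the cells", "10-49%", "under 10%" — the
    only reading under which the bands partition the detected genes.
    Never-detected genes are excluded from the bands and counted separately.
    """
    edges = tuple(float(e) for e in edges)
    if any(not (0 < e < 100) for e in edges) or any(
        a <= b for a, b in zip(edges, edges[1:])
    ):
        raise ValueError("edges must be strictly descending percentages in (0, 100)")
    freqs = np.array([s.on_freq_raw for s in summaries])
    n_zero = int((freqs == 0).sum())
    detected = freqs[freqs > 0]
    bounds = (100.0,) + edges + (0.0,)
    counts = []
    for i in range(len(bounds) - 1):
        hi, lo = bounds[i], bounds[i + 1]
        if i == 0:
            counts.append(int(((detected >= lo) & (detected <= hi)).sum()))
        else:
            counts.append(int(((detected >= lo) & (detected < hi)).sum()))
    counts[-1] = int((detected < edges[-1]).sum())  # bottom band is (0, lowest edge)
    labels = [f">={edges[0]:g}%"]
    labels += [f"{lo:g}-<{hi:g}%" for hi, lo in zip(edges, edges[1:])]
    labels.append(f"<{edges[-1]:g}%")
    return FrequencyBins(
        edges=edges, counts=tuple(counts), n_zero=n_zero, labels=tuple(labels)
    )


def per_cell_geneset_count(matrix: CountMatrix, gene_set: GeneSet) -> pd.Series:
    """Number of set genes detected (value > 0) in each cell."""
    pos, matched, _ = matrix.match_symbols(gene_set.symbols)
    if not matched:
        warnings.warn(
            f"gene set {gene_set.name!r} shares no symbols with the matrix",
            stacklevel=2,
        )
        counts = np.zeros(matrix.n_cells, dtype=int)
    else:
        counts = (matrix.values[pos] > 0).sum(axis=0)
    return pd.Series(counts, index=matrix.cell_ids, name=gene_set.name)


@dataclasses.dataclass
class GroupComparison:
    """Two-sample comparison of per-cell counts with a normality record."""

    group_stats: dict[str, tuple[int, float, float]]  # group -> (n, mean, sd)
    normality_pass: dict[str, bool]  # Shapiro-Wilk at alpha = 0.05
    statistic: float
    p_value: float
    test: str  # "pooled-t" or "welch-t"


def compare_groups(
    counts: pd.Series, ann: CellAnnotation, equal_var: bool = True
) -> GroupComparison:
    """Two-sample t-test on per-cell counts between the two groups.

    Uses the pooled-variance t-test by default (``equal_var=False`` gives
    Welch).  Each group's Shapiro-Wilk normality check (alpha = 0.05) is
    recorded but never switches the test automatically.  Identical
    zero-variance groups report statistic 0, p = 1.
    """
    groups = ann.frame.loc[counts.index.astype(str), "group"]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, found {labels}")
    samples = {g: counts[(groups == g).to_numpy()].to_numpy(float) for g in labels}
    for g, v in samples.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 cells")
    stats = {
        g: (int(v.size), float(v.mean()), float(v.std(ddof=1)))
        for g, v in samples.items()
    }
    normality = {}
    for g, v in samples.items():
        if np.ptp(v) == 0:
            normality[g] = False  # degenerate sample; Shapiro undefined
        else:
            normality[g] = bool(scipy.stats.shapiro(v).pvalue >= 0.05)
    a, b = (samples[g] for g in labels)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        res = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        group_stats=stats,
        normality_pass=normality,
        statistic=t,
        p_value=p,
        test="pooled-t" if equal_var else "welch-t",
    )


def freq_copy_correlation(
    summaries: Sequence[GeneGroupSummary],
) -> tuple[float, float]:
    """Spearman correlation of ON frequency vs non-zero mean across genes.

    Only genes with a defined non-zero mean enter; average ranks for ties;
    the two-sided p comes from the large-sample approximation.  Raises if
    fewer than 4 usable genes, or if all frequencies are tied (undefined).
    """
    pairs = [
        (s.on_freq_raw, s.nonzero_mean) for s in summaries if s.nonzero_mean is not None
    ]
    if len(pairs) < 4:
        raise ValueError("need at least 4 genes with a defined non-zero mean")
    freq, mean = map(np.array, zip(*pairs))
    if np.ptp(freq) == 0 or np.ptp(mean) == 0:
        raise ValueError("correlation undefined: a variable is constant")
    rho, p = scipy.stats.spearmanr(freq, mean)
    return float(rho), float(p)
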