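"""Gene-set coverage in the transcriptome and network annotation export.

Coverage asks what fraction of a reference list (an AMP database, an
immune-pathway protein list) is detected anywhere in the sequenced cells;
per-cell counts and a two-group comparison describe how much of a set a
single cell transcribes.  For visualization in external graph tools,
scored interaction edges are filtered at a combined-score threshold and
node attributes carry each gene's ON-state frequency.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import CellAnnotation, CountMatrix, GeneSet
from .stats import (
    FrequencyBins,
    GeneGroupSummary,
    GroupComparison,
    bin_by_frequency,
    compare_groups,
    overall_summaries,
    per_cell_geneset_count,
    summarize_genes,
)
from ._utils import pct


@dataclasses.dataclass
class CoverageReport:
    """Detection coverage of one gene set in the matrix."""

    set_name: str
    n_reference: int
    n_detected: int
    coverage_pct: float  # 100 * n_detected / n_reference, one decimal
    bins: FrequencyBins
    detected_symbols: list[str]
    unmatched_symbols: list[str]  # absent from the matrix annotation


def coverage(matrix: CountMatrix, gene_set: GeneSet) -> CoverageReport:
    """Coverage of ``gene_set``: a gene counts as detected if ON in >= 1 cell.

    Symbols absent from the matrix annotation are reported as unmatched and
    count as undetected.
    """
    pos, matched, unmatched = matrix.match_symbols(gene_set.symbols)
    on_counts = (
        (matrix.values[pos] > 0).sum(axis=1) if pos else np.zeros(0, dtype=int)
    )
    detected = [s for s, c in zip(matched, on_counts) if c > 0]
    n_cells = matrix.n_cells
    summaries = [
        GeneGroupSummary(
            gene=s,
            group="all",
            n_cells=n_cells,
            on_count=int(c),
            on_freq_pct=0.0,  # raw frequency is derived from counts for binning
            nonzero_mean=None,
        )
        for s, c in zip(matched, on_counts)
    ]
    return CoverageReport(
        set_name=gene_set.name,
        n_reference=len(gene_set),
        n_detected=len(detected),
        coverage_pct=pct(len(detected), len(gene_set)),
        bins=bin_by_frequency(summaries),
        detected_symbols=sorted(detected),
        unmatched_symbols=list(unmatched),
    )


@dataclasses.dataclass
class MultiSetReport:
    """Coverage + per-cell statistics over several gene sets."""

    reports: list[CoverageReport]
    per_cell_counts: dict[str, pd.Series]
    comparisons: dict[str, GroupComparison]
    union_detected: int  # de-duplicated detected total across sets
    union_symbols: list[str]
    mean_coverage_pct: float


def multi_set_report(
    matrix: CountMatrix, sets: Sequence[GeneSet], ann: CellAnnotation
) -> MultiSetReport:
    """Per-set coverage, per-cell counts, group comparisons and the union total.

    The union counts each detected gene once even when it appears in several
    sets (case-insensitive).
    """
    if not sets:
        raise ValueError("at least one gene set is required")
    reports, counts, comparisons = [], {}, {}
    union: dict[str, str] = {}
    for gs in sets:
        rep = coverage(matrix, gs)
        reports.append(rep)
        for s in rep.detected_symbols:
            union.setdefault(s.lower(), s)
        counts[gs.name] = per_cell_geneset_count(matrix, gs)
        try:
            comparisons[gs.name] = compare_groups(counts[gs.name], ann)
        except ValueError as exc:
            warnings.warn(
                f"group comparison skipped for set {gs.name!r}: {exc}", stacklevel=2
            )
    mean_cov = float(np.mean([r.coverage_pct for r in reports]))
    return MultiSetReport(
        reports=reports,
        per_cell_counts=counts,
        comparisons=comparisons,
        union_detected=len(union),
        union_symbols=sorted(union.values()),
        mean_coverage_pct=mean_cov,
    )


@dataclasses.dataclass
class AnnotatedNetwork:
    """Score-filtered interaction edges with ON-frequency node attributes."""

    nodes: list[tuple[str, float, bool]]  # (symbol, on_freq_pct, detected)
    edges: list[tuple[str, str, float]]
    threshold: float

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for sym, freq, detected in self.nodes:
            g.add_node(sym, on_freq_pct=freq, detected=detected)
        for u, v, score in self.edges:
            g.add_edge(u, v, combined_score=score)
        return g

    def write_tables(self, nodes_path, edges_path) -> None:
        pd.DataFrame(
            self.nodes, columns=["symbol", "on_freq_pct", "detected"]
        ).to_csv(nodes_path, sep="\t", index=False)
        pd.DataFrame(
            self.edges, columns=["source", "target", "combined_score"]
        ).to_csv(edges_path, sep="\t", index=False)


def annotate_network(
    edges: Iterable[tuple[str, str, float]],
    summaries: Sequence[GeneGroupSummary],
    threshold: float = 0.7,
) -> AnnotatedNetwork:
    """Filter scored edges and attach ON-state frequencies to the nodes.

    Edges with a combined score below ``threshold`` are removed (the
    boundary is retained: "below 0.7" is excluded, 0.7 itself kept);
    self-loops are dropped with a warning.  Node attributes carry the
    overall ON-state frequency, 0.0 with ``detected=False`` for genes
    without a summary or never detected.  Scores and frequencies are never
    altered, only filtered and joined.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    freq_map = {
        s.gene.lower(): s for s in overall_summaries(summaries) or summaries
    }
    kept: list[tuple[str, str, float]] = []
    node_order: dict[str, str] = {}
    for u, v, score in edges:
        score = float(score)
        if not 0 <= score <= 1:
            raise ValueError(f"combined score {score} outside [0, 1]")
        if str(u).lower() == str(v).lower():
            warnings.warn(f"dropping self-loop on {u!r}", stacklevel=2)
            continue
        if score < threshold:
            continue
        kept.append((str(u), str(v), score))
        node_order.setdefault(str(u).lower(), str(u))
        node_order.setdefault(str(v).lower(), str(v))
    nodes = []
    for key, sym in node_order.items():
        s = freq_map.get(key)
        if s is None or s.on_count == 0:
            nodes.append((sym, 0.0, False))
        else:
            nodes.append((sym, s.on_freq_pct, True))
    return AnnotatedNetwork(nodes=nodes, edges=kept, threshold=float(threshold))


def network_summaries(
    matrix: CountMatrix, ann: CellAnnotation, symbols: Sequence[str]
) -> list[GeneGroupSummary]:
    """Convenience: overall summaries for the node symbols of a network."""
    return overall_summaries(summarize_genes(matrix, ann, symbols))
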