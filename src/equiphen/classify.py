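"""Cell-type expression classes by the tenfold rule, with a permutation check.

Each gene of an analyzed set receives exactly one label over the two cell
groups:

* ``undetected`` — ON in neither group;
* ``specific_to_<G>`` — detected exclusively in group G;
* ``enriched_in_<G>`` — detected in both, with a more-than-tenfold higher
  non-zero mean in G;
* ``even`` — detected in both with less than (or exactly) tenfold
  difference.  A ratio of exactly the threshold is classed even: "less
  than tenfold" defines even and "more than tenfold" defines enriched,
  leaving the boundary to the weaker claim.

Ratios always compare non-zero means (copy numbers in the ON state).  The
reliability of the observed label counts is assessed by a randomized group
comparison: cell group labels are shuffled preserving group sizes, the
classification is recomputed, and add-one empirical p-values are reported
against the permutation null.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .containers import CellAnnotation, CountMatrix, GeneSet
from .stats import GeneGroupSummary
from ._utils import round_half_away

LABEL_KINDS = ("even", "enriched_a", "enriched_b", "specific_a", "specific_b")


@dataclasses.dataclass
class GeneClass:
    """One gene's expression class over the two groups."""

    gene: str
    label: str  # e.g. "even", "enriched_in_Pyr", "specific_to_FS", "undetected"
    ratio: float | None  # larger/smaller non-zero mean; None unless ON in both
    support: tuple[int, int]  # ON counts (group_a, group_b)
    groups: tuple[str, str]


def label_names(group_a: str, group_b: str) -> list[str]:
    """The five class labels, in table order, for a group pair."""
    return [
        "even",
        f"enriched_in_{group_a}",
        f"enriched_in_{group_b}",
        f"specific_to_{group_a}",
        f"specific_to_{group_b}",
    ]


def classify_gene(
    summary_a: GeneGroupSummary,
    summary_b: GeneGroupSummary,
    fold_threshold: float = 10.0,
) -> GeneClass:
    """Classify one gene from its two per-group summaries."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if summary_a.gene.lower() != summary_b.gene.lower():
        raise ValueError(
            f"summaries refer to different genes: {summary_a.gene!r} vs "
            f"{summary_b.gene!r}"
        )
    if summary_a.group == summary_b.group:
        raise ValueError("summaries must come from distinct groups")
    a, b = summary_a, summary_b
    support = (a.on_count, b.on_count)
    groups = (a.group, b.group)
    if a.on_count == 0 and b.on_count == 0:
        return GeneClass(a.gene, "undetected", None, support, groups)
    if b.on_count == 0:
        return GeneClass(a.gene, f"specific_to_{a.group}", None, support, groups)
    if a.on_count == 0:
        return GeneClass(a.gene, f"specific_to_{b.group}", None, support, groups)
    hi, lo = max(a.nonzero_mean, b.nonzero_mean), min(a.nonzero_mean, b.nonzero_mean)
    ratio = hi / lo
    if ratio > fold_threshold:
        larger = a.group if a.nonzero_mean >= b.nonzero_mean else b.group
        return GeneClass(a.gene, f"enriched_in_{larger}", ratio, support, groups)
    return GeneClass(a.gene, "even", ratio, support, groups)


def _group_arrays(matrix: CountMatrix, positions: Sequence[int], mask: np.ndarray):
    sub = matrix.values[np.asarray(positions, dtype=int)][:, mask]
    on = (sub > 0).sum(axis=1)
    sums = sub.sum(axis=1)
    return on, sums


def classify_genes(
    matrix: CountMatrix,
    ann: CellAnnotation,
    gene_set: GeneSet | Sequence[str],
    fold_threshold: float = 10.0,
) -> list[GeneClass]:
    """Classify every gene of ``gene_set`` (vectorized over genes).

    Set symbols absent from the matrix are classed ``undetected``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    symbols = list(gene_set)
    label_a, label_b, mask_a, mask_b = ann.two_group_masks(matrix)
    pos, matched, unmatched = matrix.match_symbols(symbols)
    on_a, sum_a = _group_arrays(matrix, pos, mask_a)
    on_b, sum_b = _group_arrays(matrix, pos, mask_b)
    out: list[GeneClass] = []
    for i, sym in enumerate(matched):
        oa, ob = int(on_a[i]), int(on_b[i])
        support, groups = (oa, ob), (label_a, label_b)
        if oa == 0 and ob == 0:
            out.append(GeneClass(sym, "undetected", None, support, groups))
        elif ob == 0:
            out.append(GeneClass(sym, f"specific_to_{label_a}", None, support, groups))
        elif oa == 0:
            out.append(GeneClass(sym, f"specific_to_{label_b}", None, support, groups))
        else:
            ma, mb = sum_a[i] / oa, sum_b[i] / ob
            ratio = max(ma, mb) / min(ma, mb)
            if ratio > fold_threshold:
                larger = label_a if ma >= mb else label_b
                out.append(
                    GeneClass(sym, f"enriched_in_{larger}", ratio, support, groups)
                )
            else:
                out.append(GeneClass(sym, "even", ratio, support, groups))
    for sym in unmatched:
        out.append(GeneClass(sym, "undetected", None, (0, 0), (label_a, label_b)))
    return out


@dataclasses.dataclass
class ClassificationTable:
    """Per-label gene lists, counts and percentages of the detected total."""

    groups: tuple[str, str]
    labels: list[str]  # table order: even, enriched A, enriched B, specific A, specific B
    genes: dict[str, list[str]]  # label -> alphabetically sorted genes
    counts: dict[str, int]
    percentages: dict[str, float]  # of detected total, one decimal
    n_detected: int
    undetected: list[str]

    @property
    def even_pct(self) -> float:
        return self.percentages[self.labels[0]]

    @property
    def enriched_pct(self) -> float:
        """Combined enriched percentage (both directions), one decimal."""
        n = self.counts[self.labels[1]] + self.counts[self.labels[2]]
        return round_half_away(100.0 * n / self.n_detected, 1)

    @property
    def specific_pct(self) -> float:
        n = self.counts[self.labels[3]] + self.counts[self.labels[4]]
        return round_half_away(100.0 * n / self.n_detected, 1)


def build_classification_table(classes: Sequence[GeneClass]) -> ClassificationTable:
    """Tabulate classified genes; undetected genes leave the denominator."""
    detected = [c for c in classes if c.label != "undetected"]
    if not detected:
        raise ValueError("no detected genes to tabulate")
    groups = detected[0].groups
    labels = label_names(*groups)
    genes = {lab: [] for lab in labels}
    for c in detected:
        if c.label not in genes:
            raise ValueError(f"unexpected label {c.label!r} for groups {groups}")
        genes[c.label].append(c.gene)
    genes = {lab: sorted(v) for lab, v in genes.items()}
    counts = {lab: len(v) for lab, v in genes.items()}
    n_detected = len(detected)
    percentages = {
        lab: round_half_away(100.0 * counts[lab] / n_detected, 1) for lab in labels
    }
    return ClassificationTable(
        groups=groups,
        labels=labels,
        genes=genes,
        counts=counts,
        percentages=percentages,
        n_detected=n_detected,
        undetected=sorted(c.gene for c in classes if c.label == "undetected"),
    )


def classes_from_assignments(
    columns: dict[str, Sequence[str]], groups: tuple[str, str]
) -> list[GeneClass]:
    """Build pre-assigned :class:`GeneClass` records from per-label gene lists.

    ``columns`` maps the generic column kinds (``even``, ``enriched_a``,
    ``enriched_b``, ``specific_a``, ``specific_b``) to gene symbols; used to
    feed published tables through :func:`build_classification_table`.
    """
    a, b = groups
    rename = dict(zip(LABEL_KINDS, label_names(a, b)))
    out = []
    for kind, symbols in columns.items():
        label = rename.get(kind, kind)
        for s in symbols:
            out.append(GeneClass(str(s), label, None, (0, 0), groups))
    return out


@dataclasses.dataclass
class PermutationReport:
    """Randomized group comparison of classification counts."""

    n_permutations: int
    seed: int
    labels: list[str]
    observed: dict[str, int]
    null_distribution: dict[str, np.ndarray]
    empirical_p: dict[str, float]


def _label_counts_vec(V, B, mask_a, mask_b, fold_threshold):
    """Counts (even, enr_a, enr_b, spec_a, spec_b) from value/ON matrices."""
    on_a = B[:, mask_a].sum(axis=1)
    on_b = B[:, mask_b].sum(axis=1)
    sum_a = V[:, mask_a].sum(axis=1)
    sum_b = V[:, mask_b].sum(axis=1)
    both = (on_a > 0) & (on_b > 0)
    spec_a = (on_a > 0) & (on_b == 0)
    spec_b = (on_b > 0) & (on_a == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.where(both, sum_a / np.maximum(on_a, 1), np.nan)
        mb = np.where(both, sum_b / np.maximum(on_b, 1), np.nan)
        ratio = np.maximum(ma, mb) / np.minimum(ma, mb)
    enr = both & (ratio > fold_threshold)
    enr_a = enr & (ma >= mb)
    enr_b = enr & (mb > ma)
    even = both & ~enr
    return np.array(
        [even.sum(), enr_a.sum(), enr_b.sum(), spec_a.sum(), spec_b.sum()], dtype=int
    )


def permutation_calibration(
    n_repeats: int = 200,
    n_permutations: int = 399,
    seed: int = 0,
    n_genes: int = 1500,
    n_cells_per_group: int = 10,
) -> tuple[np.ndarray, float]:
    """Null calibration of the randomized group comparison.

    Draws ``n_repeats`` exchangeable data sets (no group structure), runs
    the permutation analysis on each, and collects the empirical p-value of
    the combined differential (specific + enriched) count.  Under the null
    these p-values should be approximately uniform; the returned
    Kolmogorov-Smirnov distance against the uniform distribution measures
    how far they are from it.
    """
    import scipy.stats

    from .simulate import exchangeable_config, simulate

    pvals = np.empty(n_repeats)
    for r in range(n_repeats):
        cfg = exchangeable_config(
            seed=seed * 100_000 + r,
            n_genes=n_genes,
            n_cells_per_group=n_cells_per_group,
        )
        matrix, ann, _ = simulate(cfg)
        rep = randomized_group_reliability(
            matrix,
            ann,
            list(matrix.gene_ids),
            n_permutations=n_permutations,
            seed=seed * 100_000 + 7919 + r,
        )
        pvals[r] = rep.empirical_p["differential"]
    ks = float(scipy.stats.kstest(pvals, "uniform").statistic)
    return pvals, ks


def randomized_group_reliability(
    matrix: CountMatrix,
    ann: CellAnnotation,
    gene_set: GeneSet | Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    fold_threshold: float = 10.0,
) -> PermutationReport:
    """Permutation null for the per-label classification counts.

    Cell group labels are shuffled uniformly, preserving group sizes; the
    classification is recomputed for each shuffle.  Empirical p-values use
    the add-one estimator ``(1 + #{null >= observed}) / (1 + n)``.  Besides
    the five labels, a combined ``differential`` count (specific + enriched)
    is reported.  Fully reproducible from ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    label_a, label_b, mask_a, mask_b = ann.two_group_masks(matrix)
    pos, matched, _ = matrix.match_symbols(list(gene_set))
    V = matrix.values[np.asarray(pos, dtype=int)]
    B = V > 0
    labels = label_names(label_a, label_b) + ["differential"]

    def with_diff(c):
        return np.concatenate([c, [c[1:].sum()]])

    observed = with_diff(_label_counts_vec(V, B, mask_a, mask_b, fold_threshold))
    rng = np.random.default_rng(seed)
    n_cells = matrix.n_cells
    n_a = int(mask_a.sum())
    null = np.empty((n_permutations, len(labels)), dtype=int)
    for i in range(n_permutations):
        perm = rng.permutation(n_cells)
        pa = np.zeros(n_cells, dtype=bool)
        pa[perm[:n_a]] = True
        null[i] = with_diff(_label_counts_vec(V, B, pa, ~pa, fold_threshold))
    empirical_p = {
        lab: float((1 + (null[:, j] >= observed[j]).sum()) / (1 + n_permutations))
        for j, lab in enumerate(labels)
    }
    return PermutationReport(
        n_permutations=n_permutations,
        seed=seed,
        labels=labels,
        observed={lab: int(observed[j]) for j, lab in enumerate(labels)},
        null_distribution={lab: null[:, j].copy() for j, lab in enumerate(labels)},
        empirical_p=empirical_p,
    )
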