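import numpy as np
import pandas as pd
import pytest
import scipy.stats

from equiphen import (
    CellAnnotation,
    CountMatrix,
    GeneSet,
    bin_by_frequency,
    compare_groups,
    freq_copy_correlation,
    per_cell_geneset_count,
    summarize_gene,
    summarize_genes,
)
from equiphen.stats import GeneGroupSummary


def _matrix_with_on_pattern(on_counts_by_group, n_a=59, n_b=25, value=7.0):
    """One gene per entry; ON in the requested number of cells per group."""
    genes = list(on_counts_by_group)
    values = np.zeros((len(genes), n_a + n_b))
    for i, (oa, ob) in enumerate(on_counts_by_group.values()):
        values[i, :oa] = value
        values[i, n_a : n_a + ob] = value
    cells = [f"p{i}" for i in range(n_a)] + [f"f{i}" for i in range(n_b)]
    m = CountMatrix(values, genes, cells)
    ann = CellAnnotation.from_labels(cells, ["Pyr"] * n_a + ["FS"] * n_b)
    return m, ann


def test_on_frequency_is_rounded_share_of_cells():
    m, ann = _matrix_with_on_pattern({"g": (18, 2)})
    s = summarize_gene(m, ann, "g")
    assert s["Pyr"].on_freq_pct == 30.5  # 18/59
    assert s["FS"].on_freq_pct == 8.0  # 2/25
    assert s["all"].on_count == 20


def test_never_on_gene_and_constant_gene():
    m, ann = _matrix_with_on_pattern({"off": (0, 0), "const": (59, 25)})
    s_off = summarize_gene(m, ann, "off")
    assert s_off["all"].on_freq_pct == 0.0 and s_off["all"].nonzero_mean is None
    s_const = summarize_gene(m, ann, "const")
    assert s_const["FS"].on_freq_pct == 100.0
    assert s_const["FS"].nonzero_mean == pytest.approx(7.0)


def test_absent_gene_flagged_not_detected():
    m, ann = _matrix_with_on_pattern({"g": (3, 3)})
    s = summarize_gene(m, ann, "missing")
    assert not s["all"].in_matrix and s["all"].on_count == 0


def test_frequencies_are_multiples_of_cell_share(paperlike):
    m, ann, _ = paperlike
    for s in summarize_genes(m, ann, list(m.gene_ids)[:50]):
        implied = s.on_freq_raw * s.n_cells / 100.0
        assert implied == pytest.approx(round(implied), abs=1e-9)


def _summaries_from_freqs(freqs, n=1000):
    return [
        GeneGroupSummary(
            gene=f"g{i}", group="all", n_cells=n, on_count=int(round(f * n / 100)),
            on_freq_pct=f, nonzero_mean=1.0,
        )
        for i, f in enumerate(freqs)
    ]


def test_frequency_bins_boundary_enumeration():
    bins = bin_by_frequency(_summaries_from_freqs([55.0, 49.9, 10.0, 9.9]))
    assert bins.counts == (1, 2, 1)
    assert bins.n_zero == 0


def test_frequency_bins_edge_cases():
    assert bin_by_frequency([]).counts == (0, 0, 0)
    all50 = bin_by_frequency(_summaries_from_freqs([50.0] * 4))
    assert all50.counts == (4, 0, 0)
    with pytest.raises(ValueError, match="descending"):
        bin_by_frequency(_summaries_from_freqs([20.0]), edges=(10, 50))
    mixed = bin_by_frequency(_summaries_from_freqs([0.0, 5.0, 20.0, 60.0]))
    assert mixed.n_zero == 1 and mixed.n_binned == 3


def test_per_cell_set_counts_match_brute_force():
    rng = np.random.default_rng(5)
    values = (rng.random((20, 9)) < 0.4) * rng.integers(1, 9, (20, 9))
    m = CountMatrix(values.astype(float), [f"g{i}" for i in range(20)],
                    [f"c{j}" for j in range(9)])
    gene_set = GeneSet("half", [f"G{i}" for i in range(0, 20, 2)])  # case differs
    counts = per_cell_geneset_count(m, gene_set)
    for j, cell in enumerate(m.cell_ids):
        brute = sum(values[i, j] > 0 for i in range(0, 20, 2))
        assert counts[cell] == brute


def test_disjoint_set_warns_and_zeroes(tiny_matrix):
    with pytest.warns(UserWarning, match="no symbols"):
        counts = per_cell_geneset_count(tiny_matrix, GeneSet("none", ["Zzz"]))
    assert (counts == 0).all()


def test_group_comparison_matches_textbook_pooled_t():
    counts = pd.Series([1, 2, 3, 4, 5, 6, 7, 8.0],
                       index=[f"c{i}" for i in range(8)])
    ann = CellAnnotation.from_labels(counts.index, ["A"] * 4 + ["B"] * 4)
    cmp = compare_groups(counts, ann)
    # independent closed form: pooled variance t with 6 df
    sp2 = (np.var([1, 2, 3, 4], ddof=1) * 3 + np.var([5, 6, 7, 8], ddof=1) * 3) / 6
    t = (2.5 - 6.5) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
    p = 2 * scipy.stats.t.sf(abs(t), 6)
    assert cmp.statistic == pytest.approx(t)
    assert cmp.p_value == pytest.approx(p)
    n, mean, sd = cmp.group_stats["A"]
    assert n == 4 and mean == 2.5
    assert sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))


def test_group_comparison_degenerate_and_small_groups():
    counts = pd.Series([3.0] * 6, index=[f"c{i}" for i in range(6)])
    ann = CellAnnotation.from_labels(counts.index, ["A"] * 3 + ["B"] * 3)
    cmp = compare_groups(counts, ann)
    assert cmp.statistic == 0.0 and cmp.p_value == 1.0
    tiny = pd.Series([1.0, 2, 3, 4, 5], index=[f"c{i}" for i in range(5)])
    ann2 = CellAnnotation.from_labels(tiny.index, ["A"] * 3 + ["B"] * 2)
    with pytest.raises(ValueError, match="fewer than 3"):
        compare_groups(tiny, ann2)


def _pairs_to_summaries(pairs):
    return [
        GeneGroupSummary(
            gene=f"g{i}", group="all", n_cells=100, on_count=int(f),
            on_freq_pct=float(f), nonzero_mean=m,
        )
        for i, (f, m) in enumerate(pairs)
    ]


def test_freq_copy_correlation_monotone_and_tied():
    rho, p = freq_copy_correlation(
        _pairs_to_summaries([(10, 1.0), (20, 2.0), (30, 5.0), (40, 9.0)])
    )
    assert rho == pytest.approx(1.0)
    rho, _ = freq_copy_correlation(
        _pairs_to_summaries([(10, 9.0), (20, 5.0), (30, 2.0), (40, 1.0)])
    )
    assert rho == pytest.approx(-1.0)
    # one tie: compare against a brute-force average-rank computation
    from _oracles import average_ranks

    pairs = [(10, 3.0), (20, 3.0), (30, 8.0), (40, 1.0), (50, 12.0)]
    rho, _ = freq_copy_correlation(_pairs_to_summaries(pairs))
    rf = average_ranks([f for f, _ in pairs])
    rm = average_ranks([m for _, m in pairs])
    expected = np.corrcoef(rf, rm)[0, 1]
    assert rho == pytest.approx(expected)


def test_freq_copy_correlation_preconditions():
    with pytest.raises(ValueError, match="at least 4"):
        freq_copy_correlation(_pairs_to_summaries([(10, 1.0), (20, 2.0)]))
    with pytest.raises(ValueError, match="constant"):
        freq_copy_correlation(
            _pairs_to_summaries([(10, 1.0), (10, 2.0), (10, 3.0), (10, 4.0)])
        )
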