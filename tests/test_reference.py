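import numpy as np
import pytest

from equiphen import (
    SelectionConfig,
    filter_balanced_genes,
    prenormalize,
    select_frequent_genes,
    select_reference_genes,
    select_stable_genes,
)
from equiphen.containers import CellAnnotation, CountMatrix


def test_frequent_selection_by_on_count():
    values = np.array(
        [
            [1.0, 2.0, 3.0, 0.0],  # A: ON in 3
            [5.0, 0.0, 0.0, 0.0],  # B: ON in 1
            [0.0, 0.0, 0.0, 0.0],  # never ON
        ]
    )
    m = CountMatrix(values, ["A", "B", "C"], ["c1", "c2", "c3", "c4"])
    assert select_frequent_genes(m, 1) == ["A"]
    # saturation: never-expressed genes are not padded in
    assert select_frequent_genes(m, 10) == ["A", "B"]


def test_frequent_selection_matches_brute_force():
    rng = np.random.default_rng(3)
    values = rng.integers(0, 4, size=(10, 8)).astype(float)
    m = CountMatrix(values, [f"g{i}" for i in range(10)], [f"c{j}" for j in range(8)])
    got = select_frequent_genes(m, 10)
    # brute force: per-gene non-zero count, ties by total then symbol
    key = {
        g: (-(values[i] > 0).sum(), -values[i].sum(), g)
        for i, g in enumerate(m.gene_ids)
        if (values[i] > 0).any()
    }
    assert got == sorted(key, key=key.get)


def test_all_zero_matrix_rejected():
    m = CountMatrix(np.zeros((2, 2)), ["a", "b"], ["c", "d"])
    with pytest.raises(ValueError, match="no expressed genes"):
        select_frequent_genes(m, 1)


def test_prenormalize_equalizes_scalar_multiple_cells():
    profile = np.array([4.0, 10.0, 2.0])
    scales = [0.5, 1.0, 4.0]
    m = CountMatrix(
        np.column_stack([c * profile for c in scales]),
        ["g0", "g1", "g2"],
        ["c0", "c1", "c2"],
    )
    pn = prenormalize(m, ["g0", "g1", "g2"])
    assert pn.stage == "prenormalized"
    for j in range(3):
        np.testing.assert_allclose(pn.values[:, j], pn.values[:, 0])


def test_prenormalize_single_cell_is_identity():
    m = CountMatrix(np.array([[3.0], [7.0]]), ["a", "b"], ["only"])
    pn = prenormalize(m, ["a", "b"])
    np.testing.assert_allclose(pn.values, m.values)


def test_prenormalize_factors_match_grid_search():
    from _oracles import grid_search_factor

    rng = np.random.default_rng(8)
    values = rng.uniform(0, 30, size=(6, 3))
    values[rng.random(values.shape) < 0.2] = 0
    m = CountMatrix(values, [f"g{i}" for i in range(6)], ["x", "y", "z"])
    pn = prenormalize(m, list(m.gene_ids))
    on = values > 0
    counts = on.sum(axis=1)
    targets = np.where(counts > 0, values.sum(axis=1) / np.maximum(counts, 1), np.nan)
    usable = ~np.isnan(targets)
    for j in range(3):
        # recover the applied factor from any non-zero entry
        nz = np.flatnonzero(values[:, j])
        f_applied = pn.values[nz[0], j] / values[nz[0], j]
        gf, _ = grid_search_factor(values[usable, j], targets[usable])
        assert f_applied == pytest.approx(gf, rel=1e-4)


def test_prenormalize_flags_cell_with_no_frequent_gene():
    m = CountMatrix(
        np.array([[2.0, 0.0], [4.0, 0.0], [0.0, 5.0]]),
        ["f1", "f2", "other"],
        ["ok", "none"],
    )
    with pytest.warns(UserWarning, match="unscaled"):
        pn = prenormalize(m, ["f1", "f2"])
    np.testing.assert_allclose(pn.values[:, 1], m.values[:, 1])  # factor 1


def test_stable_selection_hand_computed_sds(tiny_matrix):
    pn = tiny_matrix.with_values(tiny_matrix.values, "prenormalized")
    # StableA non-zero SD(10,10,12,9,11,10) << NoisyB SD(5,20,35,4,18,40)
    assert select_stable_genes(pn, ["StableA", "NoisyB"], 1) == ["StableA"]
    # constant non-zero gene always ranks first
    const = pn.with_values(
        np.vstack([np.full(6, 7.0), pn.values[1:]]), "prenormalized"
    )
    assert select_stable_genes(const, list(const.gene_ids)[:2], 1) == ["StableA"]
    # k equal to eligible candidates: identity as a set
    got = select_stable_genes(pn, ["StableA", "NoisyB"], 2)
    assert set(got) == {"StableA", "NoisyB"}


def test_stable_selection_excludes_rarely_on_genes(tiny_matrix):
    pn = tiny_matrix.with_values(tiny_matrix.values, "prenormalized")
    with pytest.warns(UserWarning, match="eligible"):
        got = select_stable_genes(pn, ["StableA", "RareD"], 2)
    assert got == ["StableA"]  # RareD is ON in only 2 cells


def test_balance_filter_ratio_boundaries(tiny_ann):
    values = np.array(
        [
            [30.0, 30.0, 30.0, 4.0, 4.0, 4.0],  # ratio 7.5 -> kept
            [40.0, 40.0, 40.0, 4.0, 4.0, 4.0],  # ratio exactly 10 -> dropped
            [30.0, 28.0, 32.0, 0.0, 0.0, 0.0],  # only group A -> dropped
        ]
    )
    m = CountMatrix(
        values, ["Kept", "Boundary", "OneGroup"], [f"c{i}" for i in range(6)],
        "prenormalized",
    )
    refs = filter_balanced_genes(m, tiny_ann, list(m.gene_ids), 10.0)
    assert refs.symbols == ["Kept"]
    assert refs.targets[0] == pytest.approx(np.mean([30, 30, 30, 4, 4, 4]))
    with pytest.raises(ValueError, match="balance filter"):
        filter_balanced_genes(m, tiny_ann, ["OneGroup"], 10.0)


def test_cascade_is_deterministic(paperlike):
    m, ann, _ = paperlike
    cfg = SelectionConfig(k_frequent=400, k_stable=200)
    r1, _ = select_reference_genes(m, ann, cfg)
    r2, _ = select_reference_genes(m, ann, cfg)
    assert r1.symbols == r2.symbols
    np.testing.assert_array_equal(r1.targets, r2.targets)


def test_shrinking_selection_sizes_never_enlarges_set(paperlike):
    m, ann, _ = paperlike
    big, _ = select_reference_genes(m, ann, SelectionConfig(1000, 500))
    small, _ = select_reference_genes(m, ann, SelectionConfig(600, 300))
    assert len(small) <= len(big)


def test_reference_set_is_mostly_planted_housekeeping(paperlike):
    """The cascade recovers the planted stable core at default settings."""
    m, ann, truth = paperlike
    refs, _ = select_reference_genes(m, ann)
    hk = set(np.array(truth.gene_ids)[truth.classes == "housekeeping"])
    purity = np.mean([s in hk for s in refs.symbols])
    assert purity >= 0.8
    assert len(refs) >= 50


def test_reference_set_round_trip(tmp_path, paperlike):
    m, ann, _ = paperlike
    refs, _ = select_reference_genes(m, ann, SelectionConfig(400, 200))
    refs.write(tmp_path / "refs.tsv")
    from equiphen import ReferenceSet

    back = ReferenceSet.read(tmp_path / "refs.tsv")
    assert back.symbols == refs.symbols
    np.testing.assert_allclose(back.targets, refs.targets)
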