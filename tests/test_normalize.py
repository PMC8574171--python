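import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from equiphen import (
    UnnormalizableCellError,
    fit_scale_factor,
    normalize_matrix,
    qc_correlation,
)
from equiphen.containers import CountMatrix
from equiphen.reference import ReferenceSet, nonzero_row_means


from _oracles import grid_search_factor


def test_identity_profile_gives_unit_factor():
    mu = np.array([3.0, 8.0, 1.5])
    f, rmsd, n = fit_scale_factor(mu, mu)
    assert f == pytest.approx(1.0) and rmsd == pytest.approx(0.0) and n == 3


def test_two_gene_example_matches_grid_search():
    f, rmsd, n = fit_scale_factor([5.0, 5.0], [10.0, 20.0])
    assert f == pytest.approx(3.0) and rmsd == pytest.approx(5.0) and n == 2
    gf, grmsd = grid_search_factor([5.0, 5.0], [10.0, 20.0])
    assert f == pytest.approx(gf, rel=1e-3)
    assert rmsd == pytest.approx(grmsd, rel=1e-3)


def test_zero_entries_excluded_from_fit():
    f, rmsd, n = fit_scale_factor([0.0, 5.0], [10.0, 20.0])
    assert f == pytest.approx(4.0) and rmsd == pytest.approx(0.0) and n == 1


def test_all_zero_cell_raises():
    with pytest.raises(UnnormalizableCellError):
        fit_scale_factor([0.0, 0.0], [10.0, 20.0])


def test_closed_form_agrees_with_grid_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(2, 12)
        x = rng.uniform(0, 20, n) * (rng.random(n) > 0.3)
        if not (x > 0).any():
            x[0] = rng.uniform(0.5, 20)
        mu = rng.uniform(0.5, 50, n)
        f, rmsd, _ = fit_scale_factor(x, mu)
        gf, _ = grid_search_factor(x, mu)
        assert abs(f - gf) / gf < 1e-3


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_minimizer_is_global_under_perturbation(seed):
    """Strict convexity: nudging the factor either way worsens the RMSD."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 8))
    x = rng.uniform(0.1, 30, n)
    mu = rng.uniform(0.1, 50, n)
    f, rmsd, _ = fit_scale_factor(x, mu)

    def objective(g):
        return np.sqrt(np.mean((g * x - mu) ** 2))

    eps = 1e-3 * f
    assert objective(f + eps) >= rmsd
    assert objective(f - eps) >= rmsd


def _matrix_from_profile(profile, scales):
    values = np.column_stack([c * profile for c in scales])
    return CountMatrix(
        values,
        [f"g{i}" for i in range(len(profile))],
        [f"c{j}" for j in range(len(scales))],
    )


def test_exact_scalar_multiples_recover_inverse_factors():
    profile = np.array([10.0, 20.0, 5.0, 40.0])
    m = _matrix_from_profile(profile, [0.5, 2.0])
    refs = ReferenceSet(symbols=list(m.gene_ids), targets=profile)
    res = normalize_matrix(m, refs)
    np.testing.assert_allclose(res.factors.to_numpy(), [2.0, 0.5])
    np.testing.assert_allclose(res.rmsd.to_numpy(), 0.0, atol=1e-12)
    assert res.matrix.stage == "normalized"
    # normalized value = factor x raw value, for every gene
    np.testing.assert_allclose(res.matrix.values, m.values * res.factors.to_numpy())


def test_drop_policy_removes_unnormalizable_cell():
    profile = np.array([10.0, 20.0])
    m = CountMatrix(
        np.array([[10.0, 0.0], [20.0, 0.0], [1.0, 7.0]]),
        ["g0", "g1", "other"],
        ["good", "empty_on_refs"],
    )
    refs = ReferenceSet(symbols=["g0", "g1"], targets=profile)
    res = normalize_matrix(m, refs, policy="drop")
    assert res.matrix.cell_ids == ["good"]
    assert res.dropped_cells == ["empty_on_refs"]
    flagged = normalize_matrix(m, refs, policy="flag")
    assert flagged.matrix.n_cells == 2
    assert flagged.flagged_cells == ["empty_on_refs"]
    assert flagged.factors["empty_on_refs"] == 1.0


def test_disjoint_reference_set_rejected(tiny_matrix):
    refs = ReferenceSet(symbols=["Nope"], targets=[1.0])
    with pytest.raises(ValueError, match="no genes"):
        normalize_matrix(tiny_matrix, refs)


def test_self_targets_give_unit_scale_factors(paperlike):
    """Targets computed from the matrix itself: factors center on 1.

    Targets are arithmetic cross-cell averages while the per-cell factor is
    an inverse scale, so the factors' geometric mean carries the predictable
    Jensen gap AM(s)/GM(s) of the capture factors; beyond that gap there
    must be no scale drift.
    """
    m, ann, truth = paperlike
    sub = m.values[:300]
    refs = ReferenceSet(
        symbols=list(m.gene_ids)[:300], targets=nonzero_row_means(sub)
    )
    res = normalize_matrix(m, refs)
    geo_mean = float(np.exp(np.log(res.factors).mean()))
    s = truth.capture
    jensen_gap = s.mean() / float(np.exp(np.log(s).mean()))
    assert 0.9 < geo_mean / jensen_gap < 1.1
    # and with homogeneous capture the geometric mean itself is ~1
    from equiphen import SimulationConfig, simulate

    cfg = SimulationConfig(
        n_genes=300, n_cells_a=30, n_cells_b=20, seed=6,
        capture_sd=0.1, type_size_factor=1.0,
    )
    m2, _, _ = simulate(cfg)
    refs2 = ReferenceSet(
        symbols=list(m2.gene_ids)[:150], targets=nonzero_row_means(m2.values[:150])
    )
    res2 = normalize_matrix(m2, refs2)
    gm2 = float(np.exp(np.log(res2.factors).mean()))
    assert 0.9 < gm2 < 1.1


def test_qc_correlation_perfect_proportionality():
    m = _matrix_from_profile(np.array([1.0, 2.0, 3.0]), [1.0, 2.0, 3.0])
    refs = ReferenceSet(symbols=list(m.gene_ids), targets=[1.0, 2.0, 3.0])
    res = normalize_matrix(m, refs)
    # all cells detect all genes and sums equalize -> zero variance, flagged
    qc = qc_correlation(res)
    assert qc.undefined and qc.pearson_r is None


def test_qc_correlation_three_point_example():
    """detected (2, 3, 5) vs copy sums (10, 20, 25): r = 195/210 by hand."""
    values = np.zeros((5, 3))
    values[:2, 0] = [4.0, 6.0]  # 2 detected, sum 10
    values[:3, 1] = [5.0, 5.0, 10.0]  # 3 detected, sum 20
    values[:5, 2] = [5.0] * 5  # 5 detected, sum 25
    m = CountMatrix(values, [f"g{i}" for i in range(5)], ["a", "b", "c"], "normalized")
    from equiphen.normalize import NormalizationResult
    import pandas as pd

    res = NormalizationResult(
        matrix=m,
        factors=pd.Series(1.0, index=m.cell_ids),
        rmsd=pd.Series(0.0, index=m.cell_ids),
        n_ref_used=pd.Series(5, index=m.cell_ids),
        flagged_cells=[],
        dropped_cells=[],
        policy="flag",
    )
    qc = qc_correlation(res)
    assert qc.pearson_r == pytest.approx(195.0 / 210.0, abs=1e-9)


def test_qc_requires_three_cells():
    m = _matrix_from_profile(np.array([1.0, 2.0]), [1.0, 2.0])
    refs = ReferenceSet(symbols=list(m.gene_ids), targets=[1.0, 2.0])
    res = normalize_matrix(m, refs)
    with pytest.raises(ValueError, match="3 cells"):
        qc_correlation(res)
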