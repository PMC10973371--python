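"""Soft threshold, TOM, module detection, eigengenes, trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import _oracles as oracles
from sigforge.coexpr import (
    default_traits,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    soft_threshold_scan,
    tom_similarity,
)
from sigforge.datatypes import ClinicalTable, ExpressionMatrix, ValidationError
from sigforge.simulate import simulate_correlated_blocks, simulate_graded_blocks


def _expr(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            "log_normalized")


# ------------------------------------------------------------ soft threshold


def test_soft_threshold_on_planted_blocks_reaches_target():
    """Blocks with graded membership show scale-free topology at some power."""
    expr, _ = simulate_graded_blocks(n_samples=100, seed=0)
    scan, chosen = soft_threshold_scan(expr)
    assert scan["r_squared"].max() >= 0.8
    assert chosen in scan["power"].values
    # mean connectivity falls monotonically with the power
    assert (np.diff(scan["mean_connectivity"]) < 0).all()


def test_soft_threshold_independent_genes_poor_fit_at_power_one():
    rng = np.random.default_rng(1)
    expr = _expr(rng.standard_normal((60, 40)))
    scan, _ = soft_threshold_scan(expr)
    assert scan.loc[scan["power"] == 1, "r_squared"].iloc[0] < 0.8


def test_soft_threshold_input_checks():
    rng = np.random.default_rng(0)
    with pytest.raises(ValidationError):
        soft_threshold_scan(_expr(rng.standard_normal((40, 5))))
    with pytest.raises(ValidationError):
        soft_threshold_scan(_expr(rng.standard_normal((10, 20))))


# -------------------------------------------------------------------- TOM


def test_tom_identical_pair_is_one():
    expr = _expr([[1.0, 2, 3, 4], [2.0, 4, 6, 8]])
    tom = tom_similarity(expr, power=4)
    assert tom.iloc[0, 1] == pytest.approx(1.0)


def test_tom_orthogonal_pair_is_zero():
    expr = _expr([[1.0, -1, 1, -1], [1.0, 1, -1, -1]])
    tom = tom_similarity(expr, power=2)
    assert tom.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(2)
    expr = _expr(rng.standard_normal((10, 30)))
    tom = tom_similarity(expr, power=3).to_numpy()
    adj = np.abs(np.corrcoef(expr.values.to_numpy())) ** 3
    np.fill_diagonal(adj, 0.0)
    np.testing.assert_allclose(tom, oracles.tom_triple_loop(adj), atol=1e-12)


def test_tom_range_and_symmetry():
    rng = np.random.default_rng(3)
    expr = _expr(rng.standard_normal((25, 40)))
    tom = tom_similarity(expr, power=6).to_numpy()
    assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
    np.testing.assert_allclose(tom, tom.T, atol=1e-12)


# ------------------------------------------------------------------ modules


def test_planted_blocks_recovered_with_high_ari():
    expr, labels = simulate_correlated_blocks(n_samples=60, seed=5)
    tom = tom_similarity(expr, power=4)
    assignment = detect_modules(tom, expr, min_size=30)
    pred = assignment.labels.loc[labels.index]
    ari = adjusted_rand_score(labels.to_numpy(), pred.to_numpy())
    assert ari >= 0.8
    assert len(assignment.modules()) == 2


def test_min_size_larger_than_clusters_gives_all_grey():
    expr, _ = simulate_correlated_blocks(n_samples=40, blocks=[(10, 0.8)], n_noise=10, seed=0)
    tom = tom_similarity(expr, power=4)
    assignment = detect_modules(tom, expr, min_size=50)
    assert (assignment.labels == "grey").all()


def test_module_partition_invariant_to_gene_order():
    expr, labels = simulate_correlated_blocks(n_samples=60, seed=7)
    rng = np.random.default_rng(0)
    perm = rng.permutation(expr.values.index)
    expr_perm = ExpressionMatrix(expr.values.loc[perm], expr.flavor)
    a = detect_modules(tom_similarity(expr, 4), expr, min_size=30).labels
    b = detect_modules(tom_similarity(expr_perm, 4), expr_perm, min_size=30).labels
    assert adjusted_rand_score(a.loc[labels.index], b.loc[labels.index]) == pytest.approx(1.0)


# --------------------------------------------------------------- eigengene


def test_identical_genes_have_unit_membership():
    base = np.array([1.0, 3, 2, 5, 4])
    expr = _expr(np.vstack([base, base * 2, base + 1]))
    eig, mm = module_eigengene(expr, ["g0", "g1", "g2"])
    np.testing.assert_allclose(mm, 1.0, atol=1e-10)
    assert np.linalg.norm(eig) == pytest.approx(1.0)


def test_sign_convention_and_flip():
    rng = np.random.default_rng(4)
    arr = rng.standard_normal((5, 20))
    expr = _expr(arr)
    genes = list(expr.values.index)
    eig, mm = module_eigengene(expr, genes)
    eig_f, mm_f = module_eigengene(_expr(-arr), genes)
    np.testing.assert_allclose(eig.to_numpy(), -eig_f.to_numpy(), atol=1e-10)
    np.testing.assert_allclose(np.abs(mm), np.abs(mm_f), atol=1e-10)


def test_eigengene_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(5)
    arr = rng.standard_normal((5, 30))
    expr = _expr(arr)
    eig, _ = module_eigengene(expr, list(expr.values.index))
    std = (arr - arr.mean(1, keepdims=True)) / arr.std(1, keepdims=True)
    w, v = np.linalg.eigh(std.T @ std)
    lead = v[:, np.argmax(w)]
    dot = abs(float(np.dot(eig.to_numpy(), lead)))
    assert dot == pytest.approx(1.0, abs=1e-10)


def test_single_gene_module():
    expr = _expr([[1.0, 2, 3, 4]])
    eig, mm = module_eigengene(expr, ["g0"])
    assert mm.iloc[0] == 1.0
    assert np.linalg.norm(eig) == pytest.approx(1.0)


# ------------------------------------------------------------ module-trait


def _clin(n, rng):
    return ClinicalTable(pd.DataFrame({
        "patient_id": [f"S{j:03d}" for j in range(n)],
        "os_time": rng.uniform(100, 4000, n).round(1),
        "os_event": rng.integers(0, 2, n),
        "rfs_time": rng.uniform(100, 4000, n).round(1),
        "rfs_event": rng.integers(0, 2, n),
        "metastatic": 0,
    }))


def test_trait_equal_to_eigengene_correlates_perfectly():
    expr, _ = simulate_correlated_blocks(n_samples=40, blocks=[(35, 0.8)], n_noise=5, seed=1)
    tom = tom_similarity(expr, power=4)
    assignment = detect_modules(tom, expr, min_size=30)
    module = assignment.modules()[0]
    traits = pd.DataFrame({"echo": assignment.eigengenes[module]})
    mt = module_trait_correlation(assignment, traits)
    row = mt[(mt["module"] == module) & (mt["trait"] == "echo")].iloc[0]
    assert row["r"] == pytest.approx(1.0)
    assert row["significant"]


def test_constant_trait_flagged_undefined():
    expr, _ = simulate_correlated_blocks(n_samples=40, blocks=[(35, 0.8)], n_noise=5, seed=2)
    assignment = detect_modules(tom_similarity(expr, 4), expr, min_size=30)
    rng = np.random.default_rng(0)
    clin = _clin(40, rng)
    traits = default_traits(clin)  # metastatic is constant 0
    mt = module_trait_correlation(assignment, traits)
    met = mt[mt["trait"] == "metastatic"]
    assert (~met["defined"]).all()
    assert (~met["significant"]).all()


def test_survival_linked_module_has_largest_correlation():
    """A module whose factor drives the trait should dominate the panel."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        expr, labels = simulate_correlated_blocks(n_samples=50, seed=seed)
        assignment = detect_modules(tom_similarity(expr, 4), expr, min_size=30)
        if len(assignment.modules()) < 2:
            continue
        # trait = block-1 mean expression + noise
        block1 = expr.values.loc[labels[labels == 1].index].mean(axis=0)
        traits = pd.DataFrame({"linked": block1 + 0.3 * rng.standard_normal(50)})
        mt = module_trait_correlation(assignment, traits)
        best = mt.loc[mt["r"].abs().idxmax(), "module"]
        target = assignment.labels.loc[labels[labels == 1].index].mode()[0]
        hits += best == target
    assert hits >= 9
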