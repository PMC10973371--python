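"""Statistical structure and determinism of the synthetic-cohort generator."""

import numpy as np
import pandas as pd
import pytest

from sigforge.datatypes import ValidationError
from sigforge.simulate import (
    SimulationSpec,
    generate_cohort,
    generate_edge_list,
    generate_genesets,
    simulate_correlated_blocks,
    simulate_two_group,
)


def test_fixed_seed_is_bit_identical():
    a = generate_cohort(SimulationSpec(seed=7))
    b = generate_cohort(SimulationSpec(seed=7))
    pd.testing.assert_frame_equal(a[0].values, b[0].values)
    pd.testing.assert_frame_equal(a[1].table, b[1].table)
    assert (a[2].true_activity_scores == b[2].true_activity_scores).all()


def test_spec_validation():
    with pytest.raises(ValidationError):
        SimulationSpec(n_genes=10, n_up_signature=8, n_down_signature=8)
    with pytest.raises(ValidationError):
        SimulationSpec(module_blocks=[(2000, 0.5)])
    with pytest.raises(ValidationError):
        SimulationSpec(module_blocks=[(50, 1.2)])
    with pytest.raises(ValidationError):
        SimulationSpec(censoring_rate=1.5)


def test_expected_deaths_near_15_of_65():
    """Default hazard calibration reproduces the ~15/65 death rate."""
    deaths = [
        generate_cohort(SimulationSpec(seed=s))[1].table["os_event"].sum()
        for s in range(30)
    ]
    # mean event count within the binomial 95% band around 15/65
    se = np.sqrt(65 * (15 / 65) * (50 / 65) / 30)
    assert abs(np.mean(deaths) - 15) < 1.96 * se + 1


def test_deceased_always_relapse_and_times_ordered():
    for seed in range(5):
        _, clin, _ = generate_cohort(SimulationSpec(seed=seed))
        t = clin.table
        dead = t[t["os_event"] == 1]
        assert (dead["rfs_event"] == 1).all()
        assert (dead["rfs_time"] <= dead["os_time"]).all()
        assert (t["os_time"] >= 0).all() and (t["rfs_time"] >= 0).all()


def test_null_hazard_breaks_score_survival_link():
    """With hazard_beta=0 the latent activity is unrelated to death times."""
    corrs = []
    for seed in range(150):
        _, clin, truth = generate_cohort(SimulationSpec(hazard_beta=0.0, seed=seed))
        t = clin.table.set_index("patient_id")
        dead = t[t["os_event"] == 1]
        if len(dead) >= 5:
            s = truth.true_activity_scores.loc[dead.index]
            corrs.append(np.corrcoef(s, dead["os_time"])[0, 1])
    sem = np.std(corrs, ddof=1) / np.sqrt(len(corrs))
    assert abs(np.mean(corrs)) < 3 * sem + 1e-3


def test_planted_genes_track_activity():
    _, _, truth = generate_cohort(SimulationSpec(seed=3))
    expr, clin, truth = generate_cohort(SimulationSpec(seed=3))
    logc = np.log2(expr.values + 1)
    up_mean = logc.loc[truth.true_up_genes].mean(axis=0)
    r = np.corrcoef(up_mean, truth.true_activity_scores)[0, 1]
    assert r > 0.9


def test_edge_list_hubs_have_top_degree():
    spec = SimulationSpec(seed=2)
    _, _, truth = generate_cohort(spec)
    edges, hubs = generate_edge_list(spec=spec, truth=truth, n_nodes=20, n_hubs=3,
                                     p_edge=0.05, hub_p=0.8)
    deg = pd.concat([edges.edges["gene_a"], edges.edges["gene_b"]]).value_counts()
    assert set(deg.index[:3]) == set(hubs)
    assert deg.loc[hubs].min() >= 8
    assert deg.drop(index=hubs).max() <= deg.loc[hubs].min()


def test_edge_list_no_hubs_matches_er_expectation():
    spec = SimulationSpec(seed=0)
    _, _, truth = generate_cohort(spec)
    counts = []
    for seed in range(20):
        s = SimulationSpec(seed=seed)
        _, _, tr = generate_cohort(s)
        e, _ = generate_edge_list(tr, s, n_nodes=30, n_hubs=0, p_edge=0.1)
        counts.append(len(e))
    expected = 30 * 29 / 2 * 0.1
    sd = np.sqrt(30 * 29 / 2 * 0.1 * 0.9 / 20)
    assert abs(np.mean(counts) - expected) < 4 * sd


def test_edge_list_deterministic():
    spec = SimulationSpec(seed=5)
    _, _, truth = generate_cohort(spec)
    e1, _ = generate_edge_list(truth, spec)
    e2, _ = generate_edge_list(truth, spec)
    pd.testing.assert_frame_equal(e1.edges, e2.edges)


def test_genesets_planted_and_decoys():
    _, _, truth = generate_cohort(SimulationSpec(seed=4))
    col = generate_genesets(truth, n_decoys=0)
    assert len(col) == 2
    col = generate_genesets(truth, n_decoys=8, seed=1)
    assert len(col) == 10
    assert col.members("planted_up") == truth.true_up_genes
    assert len(col.members("planted_up")) == 30
    planted = {frozenset(truth.true_up_genes), frozenset(truth.true_down_genes)}
    for name in col.names():
        if name.startswith("decoy"):
            assert frozenset(col.members(name)) not in planted


def test_two_group_planted_fold_change_realized():
    expr, labels, up, down = simulate_two_group(seed=0)
    logc = np.log2(expr.values.to_numpy() + 1)
    lfc = logc[:, labels == 1].mean(axis=1) - logc[:, labels == 0].mean(axis=1)
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    up_lfc = np.mean([lfc[idx[g]] for g in up])
    down_lfc = np.mean([lfc[idx[g]] for g in down])
    assert 0.8 < up_lfc < 1.2
    assert -1.2 < down_lfc < -0.8


def test_correlated_blocks_have_target_correlation():
    expr, labels = simulate_correlated_blocks(n_samples=500, seed=0)
    block1 = expr.values.loc[labels[labels == 1].index].to_numpy()
    cors = np.corrcoef(block1)
    off = cors[np.triu_indices_from(cors, k=1)]
    assert abs(off.mean() - 0.8) < 0.05
    noise = expr.values.loc[labels[labels == 0].index].to_numpy()
    cross = np.corrcoef(block1[0], noise[0])[0, 1]
    assert abs(cross) < 0.2


def test_km_dominance_under_strong_hazard():
    """With a strong planted hazard the high-score tertile's survival curve
    sits at or below the low tertile's at every event time in nearly all
    cohorts (pointwise dominance is a small-sample property: a single early
    low-arm death breaks it, so the hazard must be decisively strong)."""
    from sigforge.datatypes import GeneSignature
    from sigforge.diffexpr import log_transform, normalize_counts
    from sigforge.sigscore import activity_score, tertile_stratify, zscore_by_gene
    from sigforge.survival import kaplan_meier

    ok = 0
    n_reps = 40
    for seed in range(n_reps):
        expr, clin, truth = generate_cohort(
            SimulationSpec(n_patients=60, hazard_beta=2.0, seed=seed)
        )
        z = zscore_by_gene(log_transform(normalize_counts(expr)))
        sig = GeneSignature("p", truth.true_up_genes, truth.true_down_genes)
        strata = tertile_stratify(activity_score(z, sig).scores)
        t = clin.table.set_index("patient_id")
        hi, lo = strata.patients("high"), strata.patients("low")
        km_hi = kaplan_meier(t.loc[hi, "os_time"], t.loc[hi, "os_event"])
        km_lo = kaplan_meier(t.loc[lo, "os_time"], t.loc[lo, "os_event"])
        times = np.concatenate([km_hi.event_times, km_lo.event_times])
        ok += all(
            km_hi.survival_at(tt) <= km_lo.survival_at(tt) + 1e-12 for tt in times
        )
    assert ok / n_reps >= 0.95
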