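"""Score patients with the 13-hub-gene signature format and read out survival.

Scores each patient by summed z-scores (up genes minus down genes),
stratifies into tertiles, and compares top vs bottom tertile by log-rank
and IPCW time-dependent AUC at 3/5/10 years. Here the signature is the
planted one, so strong separation is expected.
"""

from sigforge import (
    GeneSignature,
    SimulationSpec,
    generate_cohort,
    log_transform,
    normalize_counts,
    years_to_days,
)
from sigforge.sigscore import activity_score, tertile_stratify, zscore_by_gene
from sigforge.survival import logrank_test, time_dependent_auc, trait_correlation

expr, clin, truth = generate_cohort(SimulationSpec(n_patients=60, seed=1))
zmat = zscore_by_gene(log_transform(normalize_counts(expr)))
sig = GeneSignature("planted", truth.true_up_genes, truth.true_down_genes)

act = activity_score(zmat, sig)
strata = tertile_stratify(act.scores)
t = clin.table.set_index("patient_id")
hi, lo = strata.patients("high"), strata.patients("low")

lr = logrank_test(t.loc[hi, "os_time"], t.loc[hi, "os_event"],
                  t.loc[lo, "os_time"], t.loc[lo, "os_event"])
print(f"high vs low tertile ({len(hi)} vs {len(lo)} patients)")
print(f"log-rank chi2 = {lr.chi2:.2f}, p = {lr.p:.2g}")

for years in (3, 5, 10):
    res = time_dependent_auc(act.scores.loc[t.index], t["os_time"], t["os_event"],
                             years_to_days(years))
    print(f"AUC({years}y) = {res.auc:.3f}  ({res.n_cases} cases, {res.n_controls} controls)")

dead = t[t["os_event"] == 1]
corr = trait_correlation(act.scores.loc[dead.index], dead["os_time"])
print(f"score vs time-to-death among {corr.n} deceased: r = {corr.r:.2f}, p = {corr.p:.2g}")
# AUC well above 0.5 and a small log-rank p confirm the score separates risk.
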