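"""End-to-end discovery pipeline: from a count matrix and clinical table to
a hub-gene signature with survival read-outs, co-expression modules and
enrichment.

Stage order mirrors the discovery strategy the package implements:

1.  normalize counts (median-of-ratios) and log-transform
2.  differential expression, two contrasts within localized patients
    (deceased-within-window vs alive; relapsed vs event-free)
3.  up/down DEG-list overlap with hypergeometric p-values
4.  interaction-network centralities and hub selection
5.  signature assembly (hub genes signed by the survival contrast)
6.  z-score activity scoring and tertile stratification
7.  Kaplan-Meier / log-rank for OS and RFS, high vs low tertile
8.  time-dependent AUC at the requested horizons + correlation of the
    score with time to death among deceased patients
9.  co-expression modules on the overlap genes with trait correlations
10. gene-set enrichment (ORA per module, preranked on the DE ranking)

Each stage writes its artifacts into a numbered subdirectory of the run
directory, and a manifest records inputs, parameters and the seed; two runs
with identical inputs differ only in the manifest timestamp.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    ClinicalTable,
    EdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    GeneSignature,
    ValidationError,
)
from .diffexpr import (
    deg_lists,
    differential_expression,
    log_transform,
    normalize_counts,
    overlap_signatures,
)
from .sigscore import activity_score, tertile_stratify, zscore_by_gene
from .survival import (
    kaplan_meier,
    km_table,
    logrank_test,
    time_dependent_auc,
    trait_correlation,
    years_to_days,
)
from . import hubnet
from .coexpr import (
    default_traits,
    detect_modules,
    module_trait_correlation,
    tom_similarity,
)
from .enrich import ora, preranked_enrichment

log = logging.getLogger("sigforge")

STAGES = [
    "01_normalize",
    "02_de",
    "03_overlap",
    "04_hubs",
    "05_signature",
    "06_scores",
    "07_survival",
    "08_auc",
    "09_modules",
    "10_enrich",
]


@dataclass
class PipelineConfig:
    """Knobs of the discovery run; defaults mirror the published analysis."""

    out_dir: str = "run"
    fc_thresh: float = 1.5
    fdr_thresh: float = 0.05
    de_window_years: float | None = 3.0
    exclude_censored_before_window: bool = True
    min_confidence: float = 400.0
    k_hubs: int = 10
    soft_power: int = 4
    min_module_size: int = 30
    merge_cut: float = 0.25
    horizons_years: tuple[float, ...] = (3.0, 5.0, 10.0)
    n_perm: int = 200
    seed: int = 0


def _survival_groups(clin: ClinicalTable, config: PipelineConfig) -> pd.Series | None:
    """Deceased-within-window vs alive-at-study-end labels (1 = deceased)."""
    t = clin.table.set_index("patient_id")
    if config.de_window_years is None:
        dead = t["os_event"] == 1
        alive = t["os_event"] == 0
    else:
        window = years_to_days(config.de_window_years)
        dead = (t["os_event"] == 1) & (t["os_time"] <= window)
        alive = t["os_event"] == 0
        if config.exclude_censored_before_window:
            alive = alive & (t["os_time"] >= window)
    labels = pd.Series(np.nan, index=t.index)
    labels[alive] = 0
    labels[dead] = 1
    return labels.dropna().astype(int)


def _relapse_groups(clin: ClinicalTable) -> pd.Series:
    """Relapsed vs event-free labels (1 = relapsed)."""
    t = clin.table.set_index("patient_id")
    return t["rfs_event"].astype(int)


def run_discovery(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    config: PipelineConfig,
    edges: EdgeList | None = None,
    genesets: GeneSetCollection | None = None,
) -> dict:
    """Execute the full discovery pipeline; returns the result bundle.

    Artifacts are written under ``config.out_dir``; the returned dict also
    carries the in-memory objects (DE tables, signature, scores, strata,
    survival statistics, modules, enrichment) for programmatic use.
    """
    out = Path(config.out_dir)
    t_start = time.time()
    results: dict = {"config": asdict(config)}
    stage_times: dict[str, float] = {}

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def run_stage(name, fn):
        t0 = time.time()
        log.info("stage %s ...", name)
        try:
            fn(stage_dir(name))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name} failed: {exc}") from exc
        stage_times[name] = round(time.time() - t0, 3)

    localized = clinical.localized()
    keep = [p for p in expr.sample_ids if p in set(localized.patient_ids)]
    if len(keep) < 6:
        raise ValidationError("fewer than 6 localized patients with expression")
    expr_loc = expr.subset_samples(keep)
    clin_loc = ClinicalTable(
        localized.table[localized.table["patient_id"].isin(keep)].copy()
    )

    # 01 normalize -------------------------------------------------------
    holder: dict = {}

    def s01(d: Path):
        holder["norm"] = normalize_counts(expr_loc)
        holder["logged"] = log_transform(holder["norm"])
        holder["logged"].values.to_csv(d / "log_normalized.tsv", sep="\t")

    run_stage("01_normalize", s01)
    logged = holder["logged"]

    # 02 differential expression ----------------------------------------
    def s02(d: Path):
        surv_labels = _survival_groups(clin_loc, config)
        surv_samples = [p for p in surv_labels.index if p in keep]
        de_surv = differential_expression(
            logged.subset_samples(surv_samples),
            surv_labels.loc[surv_samples].to_numpy(),
            fc_thresh=config.fc_thresh,
            fdr_thresh=config.fdr_thresh,
        )
        rel_labels = _relapse_groups(clin_loc)
        rel_samples = [p for p in rel_labels.index if p in keep]
        de_rel = differential_expression(
            logged.subset_samples(rel_samples),
            rel_labels.loc[rel_samples].to_numpy(),
            fc_thresh=config.fc_thresh,
            fdr_thresh=config.fdr_thresh,
        )
        de_surv.to_csv(d / "de_survival.tsv", sep="\t")
        de_rel.to_csv(d / "de_relapse.tsv", sep="\t")
        results["de_survival"], results["de_relapse"] = de_surv, de_rel

    run_stage("02_de", s02)

    # 03 overlap ---------------------------------------------------------
    def s03(d: Path):
        up_s, down_s = deg_lists(results["de_survival"])
        up_r, down_r = deg_lists(results["de_relapse"])
        n_bg = len(results["de_survival"])
        ov_up = overlap_signatures(up_s, up_r, n_bg)
        ov_down = overlap_signatures(down_s, down_r, n_bg)
        results["overlap_up"], results["overlap_down"] = ov_up, ov_down
        with open(d / "overlap.json", "w") as fh:
            json.dump(
                {
                    "up": {"k": ov_up.k, "size_a": ov_up.size_a, "size_b": ov_up.size_b,
                           "log10_p": ov_up.log10_p},
                    "down": {"k": ov_down.k, "size_a": ov_down.size_a,
                             "size_b": ov_down.size_b, "log10_p": ov_down.log10_p},
                    "background_n": n_bg,
                },
                fh,
                indent=2,
            )

    run_stage("03_overlap", s03)
    overlap_genes = results["overlap_up"].overlap_genes + results["overlap_down"].overlap_genes

    # 04 hubs ------------------------------------------------------------
    def s04(d: Path):
        if edges is None or len(overlap_genes) == 0:
            results["hubs"] = None
            (d / "SKIPPED.txt").write_text("no edge list or no overlap genes\n")
            return
        graph = hubnet.build_graph(edges, restrict_to=overlap_genes)
        cents = hubnet.centrality_table(graph)
        k = min(config.k_hubs, len(cents))
        sel = hubnet.select_hubs(cents, k=k)
        results["hubs"] = sel
        cents.to_csv(d / "centralities.tsv", sep="\t")
        sel.provenance().to_csv(d / "hubs.tsv", sep="\t", index=False)

    run_stage("04_hubs", s04)

    # 05 signature assembly ---------------------------------------------
    def s05(d: Path):
        members = results["hubs"].hubs if results["hubs"] is not None else overlap_genes
        if not members:
            raise ValidationError("no genes available for signature assembly")
        lfc = results["de_survival"]["log2_fold_change"]
        up = [g for g in members if lfc.get(g, 0.0) > 0]
        down = [g for g in members if lfc.get(g, 0.0) <= 0]
        sig = GeneSignature("discovered", up, down, provenance="pipeline run")
        results["signature"] = sig
        with open(d / "signature.tsv", "w") as fh:
            for g in up:
                fh.write(f"{g}\tup\n")
            for g in down:
                fh.write(f"{g}\tdown\n")

    run_stage("05_signature", s05)

    # 06 scoring ---------------------------------------------------------
    def s06(d: Path):
        zmat = zscore_by_gene(logged)
        act = activity_score(zmat, results["signature"])
        strata = tertile_stratify(act.scores)
        results["scores"], results["strata"] = act, strata
        pd.DataFrame({"score": act.scores, "stratum": strata.labels}).to_csv(
            d / "scores.tsv", sep="\t", index_label="patient_id"
        )

    run_stage("06_scores", s06)

    # 07 survival --------------------------------------------------------
    def s07(d: Path):
        t = clin_loc.table.set_index("patient_id")
        strata = results["strata"]
        surv_stats = {}
        for endpoint, tcol, ecol in (("os", "os_time", "os_event"), ("rfs", "rfs_time", "rfs_event")):
            hi, lo = strata.patients("high"), strata.patients("low")
            km_hi = kaplan_meier(t.loc[hi, tcol], t.loc[hi, ecol])
            km_lo = kaplan_meier(t.loc[lo, tcol], t.loc[lo, ecol])
            lr = logrank_test(t.loc[hi, tcol], t.loc[hi, ecol], t.loc[lo, tcol], t.loc[lo, ecol])
            km_table(km_hi).to_csv(d / f"km_{endpoint}_high.tsv", sep="\t", index=False)
            km_table(km_lo).to_csv(d / f"km_{endpoint}_low.tsv", sep="\t", index=False)
            surv_stats[endpoint] = {"chi2": lr.chi2, "logrank_p": lr.p}
        results["survival"] = surv_stats
        with open(d / "logrank.json", "w") as fh:
            json.dump(surv_stats, fh, indent=2)

    run_stage("07_survival", s07)

    # 08 AUC + time-to-death correlation --------------------------------
    def s08(d: Path):
        t = clin_loc.table.set_index("patient_id")
        scores = results["scores"].scores
        aucs = {}
        for h in config.horizons_years:
            days = years_to_days(h)
            try:
                res = time_dependent_auc(
                    scores.loc[t.index], t["os_time"], t["os_event"], days
                )
                aucs[f"{h:g}y"] = {"auc": res.auc, "n_cases": res.n_cases,
                                   "n_controls": res.n_controls}
            except ValidationError as exc:
                aucs[f"{h:g}y"] = {"auc": None, "note": str(exc)}
        deceased = t[t["os_event"] == 1]
        if len(deceased) >= 3 and scores.loc[deceased.index].std() > 0:
            corr = trait_correlation(scores.loc[deceased.index], deceased["os_time"])
            ttd = {"r": corr.r, "p": corr.p, "n": corr.n}
        else:
            ttd = {"r": None, "note": "too few deceased patients"}
        results["auc"], results["time_to_death"] = aucs, ttd
        with open(d / "auc.json", "w") as fh:
            json.dump({"auc": aucs, "time_to_death_correlation": ttd}, fh, indent=2)

    run_stage("08_auc", s08)

    # 09 modules ---------------------------------------------------------
    def s09(d: Path):
        panel = logged.subset_genes(overlap_genes)
        if panel.shape[0] < 3:
            results["modules"] = None
            (d / "SKIPPED.txt").write_text("too few overlap genes for modules\n")
            return
        tom = tom_similarity(panel, power=config.soft_power)
        assignment = detect_modules(
            tom,
            panel,
            min_size=min(config.min_module_size, max(3, panel.shape[0] // 2)),
            merge_cut=config.merge_cut,
        )
        traits = default_traits(clin_loc)
        mt = module_trait_correlation(assignment, traits)
        results["modules"], results["module_traits"] = assignment, mt
        assignment.labels.to_frame("module").to_csv(d / "modules.tsv", sep="\t")
        assignment.eigengenes.to_csv(d / "eigengenes.tsv", sep="\t")
        mt.to_csv(d / "module_traits.tsv", sep="\t", index=False)

    run_stage("09_modules", s09)

    # 10 enrichment ------------------------------------------------------
    def s10(d: Path):
        if genesets is None or len(genesets) == 0:
            results["enrichment"] = None
            (d / "SKIPPED.txt").write_text("no gene-set collection provided\n")
            return
        background = list(results["de_survival"].index)
        ora_tables = {}
        assignment = results.get("modules")
        if assignment is not None:
            for color in assignment.modules():
                ora_tables[color] = ora(assignment.genes_in(color), genesets, background)
                ora_tables[color].to_csv(d / f"ora_{color}.tsv", sep="\t")
        ranks = results["de_survival"]["log2_fold_change"]
        pre = preranked_enrichment(
            ranks, genesets, n_perm=config.n_perm, seed=config.seed
        )
        pre.to_csv(d / "preranked.tsv", sep="\t")
        results["enrichment"] = {"ora": ora_tables, "preranked": pre}

    run_stage("10_enrich", s10)

    manifest = {
        "package": "sigforge",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "inputs": {
            "n_genes": expr.shape[0],
            "n_samples": expr.shape[1],
            "n_localized": len(keep),
            "edges": None if edges is None else len(edges),
            "genesets": None if genesets is None else len(genesets),
        },
        "stages": STAGES,
        "stage_seconds": stage_times,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "wall_seconds": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results


def compare_signatures(
    signatures: list[GeneSignature],
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    horizons_years: tuple[float, ...] = (3.0, 5.0, 10.0),
) -> pd.DataFrame:
    """Head-to-head evaluation of several signatures on one cohort.

    For each signature: Pearson r/p of the activity score against time to
    death (deceased patients only), overall-survival time and first-event
    time; the high-vs-low tertile log-rank p; and the time-dependent AUC at
    each horizon. Signatures with zero matrix coverage are flagged, not
    dropped.
    """
    if len(signatures) < 2:
        raise ValidationError("need at least 2 signatures to compare")
    localized = clinical.localized()
    keep = [p for p in expr.sample_ids if p in set(localized.patient_ids)]
    t = localized.table.set_index("patient_id").loc[keep]
    logged = expr if expr.flavor.value != "raw_counts" else log_transform(normalize_counts(expr))
    zmat = zscore_by_gene(logged.subset_samples(keep))

    rows = []
    for sig in signatures:
        row: dict = {"signature": sig.name, "n_genes": len(sig.genes)}
        try:
            act = activity_score(zmat, sig)
        except ValidationError:
            row["covered"] = False
            rows.append(row)
            continue
        row["covered"] = True
        row["n_genes_used"] = act.n_up_used + act.n_down_used
        scores = act.scores
        deceased = t[t["os_event"] == 1]
        if len(deceased) >= 3:
            c = trait_correlation(scores.loc[deceased.index], deceased["os_time"])
            row["r_time_to_death"], row["p_time_to_death"] = c.r, c.p
        c_os = trait_correlation(scores, t["os_time"])
        c_fe = trait_correlation(scores, t["rfs_time"])
        row["r_os_time"], row["p_os_time"] = c_os.r, c_os.p
        row["r_first_event_time"], row["p_first_event_time"] = c_fe.r, c_fe.p
        strata = tertile_stratify(scores)
        hi, lo = strata.patients("high"), strata.patients("low")
        lr = logrank_test(
            t.loc[hi, "os_time"], t.loc[hi, "os_event"],
            t.loc[lo, "os_time"], t.loc[lo, "os_event"],
        )
        row["logrank_p_os"] = lr.p
        for h in horizons_years:
            try:
                res = time_dependent_auc(
                    scores, t["os_time"], t["os_event"], years_to_days(h)
                )
                row[f"auc_{h:g}y"] = res.auc
            except ValidationError:
                row[f"auc_{h:g}y"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
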