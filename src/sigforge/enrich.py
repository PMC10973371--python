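"""Gene-set enrichment: hypergeometric over-representation and a preranked
weighted Kolmogorov-Smirnov statistic with a gene-label permutation null.

The ORA p-value shares the log-space hypergeometric kernel with the
signature-overlap test. The preranked statistic walks the ranked gene list
accumulating |metric|^p-weighted hits against uniform misses; ES is the
running-sum extremum, NES normalizes against same-sign permutation scores,
and q-values come from BH over permutation p-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, ValidationError
from .diffexpr import bh_adjust, hypergeom_upper_logp

log = logging.getLogger("sigforge")


def ora(
    query_genes: list[str],
    collection: GeneSetCollection,
    background: list[str],
) -> pd.DataFrame:
    """Over-representation of the query in each set of the collection.

    Sets are intersected with the background before testing; the p-value is
    the upper-tail hypergeometric probability of the observed overlap, with
    BH adjustment across sets. Returns a frame indexed by set name with
    columns ``k, set_size, query_size, background_n, log10_p, p, q``.
    """
    bg = set(background)
    query = set(query_genes) & bg
    if not query:
        raise ValidationError("query is empty (after background intersection)")
    if not bg:
        raise ValidationError("background is empty")
    rows = []
    for name in collection.names():
        members = set(collection.members(name)) & bg
        k = len(query & members)
        if members:
            log10_p = hypergeom_upper_logp(k, len(members), len(query), len(bg))
        else:
            log10_p = 0.0
        rows.append(
            {"set": name, "k": k, "set_size": len(members), "query_size": len(query),
             "background_n": len(bg), "log10_p": log10_p}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["p"] = np.minimum(10.0 ** out["log10_p"], 1.0)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("log10_p")


def enrichment_score(
    ranked_metric: pd.Series, geneset: list[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score for one gene set.

    ``ranked_metric`` maps gene -> score; genes are walked in descending
    metric order. Hits contribute |metric|^weight_p normalized to sum 1,
    misses contribute 1/(N - n_set); ES is the extremum of the running sum.
    """
    members = set(geneset) & set(ranked_metric.index)
    if not members:
        raise ValidationError("gene set has no member in the ranked list")
    dropped = len(set(geneset)) - len(members)
    if dropped:
        log.info("%d gene-set members absent from the ranked list", dropped)
    order = ranked_metric.sort_values(ascending=False, kind="mergesort")
    is_hit = order.index.isin(members)
    n, n_hit = len(order), int(is_hit.sum())
    if n_hit == n:
        return 1.0, np.ones(n)
    weights = np.abs(order.to_numpy()) ** weight_p
    hit_w = np.where(is_hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-hit metrics zero: fall back to uniform hit steps
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    step_hit = hit_w / total
    step_miss = np.where(is_hit, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(step_hit - step_miss)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def preranked_enrichment(
    ranked_metric: pd.Series,
    collection: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked enrichment with a seeded gene-label permutation null.

    For each set the null redraws random same-size gene sets from the
    ranked list. NES = ES / mean(|null ES of the same sign|); the
    permutation p is the same-sign tail frequency and q its BH adjustment
    across sets. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    gene_index = np.array(ranked_metric.index)
    rows = []
    for name in collection.names():
        members = [g for g in collection.members(name) if g in ranked_metric.index]
        if not members:
            raise ValidationError(f"gene set {name!r} has no member in the ranked list")
        es, _ = enrichment_score(ranked_metric, members, weight_p)
        null = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.choice(gene_index, size=len(members), replace=False)
            null[i], _ = enrichment_score(ranked_metric, list(draw), weight_p)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        if es >= 0:
            p = (1 + (null >= es).sum()) / (1 + n_perm)
        else:
            p = (1 + (null <= es).sum()) / (1 + n_perm)
        rows.append({"set": name, "n_genes": len(members), "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")
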