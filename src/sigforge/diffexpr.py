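"""Differential expression, FDR control and signature-overlap testing.

The DE stage is deliberately simple: median-of-ratios normalization followed
by a per-gene Welch t-test on log2(normalized + 1), Benjamini-Hochberg
adjustment, and the field-standard thresholds (FDR < 0.05 and absolute fold
change strictly exceeding 1.5). Its contract is recovery of planted truth in
simulation, not equivalence with any particular NB-GLM fitter.

The hypergeometric overlap test runs in log space so that the extreme
p-values typical of concordant DEG lists (1e-200 and below) remain
representable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, Flavor, ValidationError

log = logging.getLogger("sigforge")

LOG2_FC_DEFAULT = 1.5


def normalize_counts(expr: ExpressionMatrix, pseudo_reference: bool = False) -> ExpressionMatrix:
    """Median-of-ratios library-size normalization.

    The reference is the per-gene geometric mean over samples, restricted to
    genes with all-positive counts; each sample's size factor is the median
    ratio to that reference, rescaled so the factors have geometric mean 1.
    ``pseudo_reference=True`` adds 0.5 to all counts when no gene is
    all-positive (sparse data fallback).
    """
    if expr.flavor is not Flavor.raw_counts:
        raise ValidationError("normalize_counts expects raw counts")
    if expr.shape[1] < 2:
        raise ValidationError("need at least 2 samples to normalize")
    counts = expr.values.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        if not pseudo_reference:
            raise ValidationError(
                "no gene has all-positive counts; re-run with pseudo_reference=True"
            )
        counts = counts + 0.5
        positive = np.ones(counts.shape[0], dtype=bool)
    log_ref = np.log(counts[positive]).mean(axis=1)
    ratios = np.log(counts[positive]) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    log.info("size factors: %s", np.round(factors, 3))
    normalized = expr.values / factors
    return ExpressionMatrix(normalized, Flavor.normalized)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(normalized + 1); the pseudocount enters only here."""
    if expr.flavor not in (Flavor.normalized, Flavor.raw_counts):
        raise ValidationError("log_transform expects normalized or raw counts")
    return ExpressionMatrix(np.log2(expr.values + 1.0), Flavor.log_normalized)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential_expression(
    expr: ExpressionMatrix,
    group_labels: np.ndarray | pd.Series,
    fc_thresh: float = LOG2_FC_DEFAULT,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Welch-t differential expression between two sample groups.

    ``group_labels`` holds 0 (reference, A) / 1 (comparison, B) per sample;
    log2 fold change is mean(B) - mean(A) on the log2(normalized + 1) scale.
    A gene is ``up`` iff its q-value is below ``fdr_thresh`` and its fold
    change strictly exceeds ``fc_thresh`` (symmetrically ``down``);
    otherwise ``ns``.

    Returns a DataFrame indexed by gene with columns
    ``log2_fold_change, raw_p, fdr_q, direction``.
    """
    labels = np.asarray(group_labels)
    if expr.shape[1] != labels.size:
        raise ValidationError("group_labels length must match sample count")
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("group_labels must be binary 0/1")
    n_a, n_b = int((labels == 0).sum()), int((labels == 1).sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least 2 samples")

    if expr.flavor is Flavor.log_normalized:
        logged = expr
    else:
        logged = log_transform(expr)
    mat = logged.values.to_numpy()
    a, b = mat[:, labels == 0], mat[:, labels == 1]

    lfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        log.warning("%d genes with zero variance in both groups; p set to 1", degenerate.sum())
        p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)

    log2_cut = np.log2(fc_thresh)
    direction = np.where(
        (q < fdr_thresh) & (lfc > log2_cut),
        "up",
        np.where((q < fdr_thresh) & (lfc < -log2_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2_fold_change": lfc, "raw_p": p, "fdr_q": q, "direction": direction},
        index=logged.values.index,
    )


def deg_lists(deg_table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Up- and down-regulated gene lists from a DE table."""
    up = list(deg_table.index[deg_table["direction"] == "up"])
    down = list(deg_table.index[deg_table["direction"] == "down"])
    return up, down


# ------------------------------------------------------------------ overlap


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two gene lists over a stated universe."""

    overlap_genes: list[str]
    k: int
    size_a: int
    size_b: int
    background_n: int
    log10_p: float

    @property
    def p(self) -> float:
        """Upper-tail p; may underflow to 0.0 for extreme overlaps (use log10_p)."""
        return float(10.0**self.log10_p)


def hypergeom_upper_logp(k: int, n_a: int, n_b: int, background_n: int) -> float:
    """log10 of P(X >= k), X ~ Hypergeom(N=background_n, K=n_a, n=n_b).

    Summed in log space from the logpmf so values around 1e-300 and below
    stay finite.
    """
    if k <= 0:
        return 0.0
    upper = min(n_a, n_b)
    if k > upper:
        raise ValidationError("overlap exceeds the smaller list")
    xs = np.arange(k, upper + 1)
    logpmf = stats.hypergeom.logpmf(xs, background_n, n_a, n_b)
    return float(special.logsumexp(logpmf) / np.log(10.0))


def overlap_signatures(
    list_a: list[str], list_b: list[str], background_n: int
) -> OverlapResult:
    """Size of the intersection of two gene lists and its upper-tail
    hypergeometric p-value over an explicit background universe."""
    set_a, set_b = set(list_a), set(list_b)
    if background_n < max(len(set_a), len(set_b)):
        raise ValidationError("background_n smaller than a gene list")
    overlap = sorted(set_a & set_b)
    log10_p = hypergeom_upper_logp(len(overlap), len(set_a), len(set_b), background_n)
    return OverlapResult(
        overlap_genes=overlap,
        k=len(overlap),
        size_a=len(set_a),
        size_b=len(set_b),
        background_n=background_n,
        log10_p=log10_p,
    )
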