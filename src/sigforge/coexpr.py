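"""Weighted co-expression analysis: soft threshold, TOM, modules, eigengenes.

A compact re-implementation of the weighted co-expression workflow for
moderate gene panels: unsigned adjacency |cor|^beta with a scale-free-fit
power scan, topological overlap similarity, average-linkage clustering on
TOM dissimilarity with a static cut, a minimum module size, and iterative
merging of modules with correlated eigengenes. Modules are named by
descending size through the conventional color vocabulary (turquoise, blue,
brown, ...), with "grey" holding unassigned genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .datatypes import ClinicalTable, ExpressionMatrix, ValidationError

log = logging.getLogger("sigforge")

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
]
GREY = "grey"


def _gene_correlation(expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    mat = expr.values.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        log.warning("excluding %d constant genes from the co-expression network", (~keep).sum())
    genes = [g for g, k in zip(expr.values.index, keep) if k]
    cor = np.corrcoef(mat[keep])
    if not np.isfinite(cor).all():
        raise ValidationError("non-finite gene-gene correlations")
    return cor, genes


def soft_threshold_scan(
    expr: ExpressionMatrix,
    powers: list[int] | None = None,
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Scale-free topology scan over candidate soft-threshold powers.

    For each power the unsigned adjacency's connectivity distribution is
    binned and log10 p(k) regressed on log10 k; the chosen power is the
    smallest reaching ``r2_target``, else the argmax R^2.
    """
    if powers is None:
        powers = list(range(1, 13))
    if expr.shape[1] < 8:
        raise ValidationError("soft-threshold scan needs at least 8 samples")
    if expr.shape[0] < 30:
        raise ValidationError("soft-threshold scan needs at least 30 genes")
    cor, _ = _gene_correlation(expr)
    acor = np.abs(cor)
    np.fill_diagonal(acor, 0.0)
    rows = []
    for beta in powers:
        adj = acor**beta
        k = adj.sum(axis=1)
        rows.append(
            {"power": beta, "r_squared": _scale_free_r2(k, n_bins), "mean_connectivity": k.mean()}
        )
    scan = pd.DataFrame(rows)
    ok = scan[scan["r_squared"] >= r2_target]
    chosen = int(ok["power"].iloc[0]) if len(ok) else int(scan.loc[scan["r_squared"].idxmax(), "power"])
    return scan, chosen


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2) if slope < 0 else 0.0


def tom_similarity(expr: ExpressionMatrix, power: int = 4) -> pd.DataFrame:
    """Topological overlap similarity of the unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    unit diagonal; values lie in [0, 1] and the matrix is symmetric.
    """
    if power < 1:
        raise ValidationError("power must be >= 1")
    cor, genes = _gene_correlation(expr)
    adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    num = shared + adj
    den = np.minimum.outer(k, k) + 1.0 - adj
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=genes, columns=genes)


def module_eigengene(
    expr: ExpressionMatrix, module_genes: list[str]
) -> tuple[pd.Series, pd.Series]:
    """First principal component of a module's standardized expression.

    Returns the per-sample eigengene (unit norm, sign aligned with the mean
    standardized expression) and per-gene module membership (Pearson
    correlation of each member with the eigengene).
    """
    if len(module_genes) == 0:
        raise ValidationError("module is empty")
    sub = expr.values.loc[module_genes].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    std = np.where(sd > 0, (sub - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if len(module_genes) == 1:
        vec = std[0]
        norm = np.linalg.norm(vec)
        eig = vec / norm if norm > 0 else vec
        return (
            pd.Series(eig, index=expr.values.columns),
            pd.Series([1.0], index=module_genes),
        )
    _, _, vt = np.linalg.svd(std, full_matrices=False)
    eig = vt[0]
    ref = std.mean(axis=0)
    if ref.std() > 0 and np.corrcoef(eig, ref)[0, 1] < 0:
        eig = -eig
    mm = np.array(
        [np.corrcoef(row, eig)[0, 1] if row.std() > 0 else 0.0 for row in std]
    )
    return (
        pd.Series(eig, index=expr.values.columns),
        pd.Series(mm, index=module_genes),
    )


@dataclass
class ModuleAssignment:
    """Gene-to-module labels with eigengenes and module membership."""

    labels: pd.Series  # gene -> color string, GREY = unassigned
    eigengenes: pd.DataFrame  # samples x modules
    module_membership: pd.Series  # gene -> cor with its own module eigengene

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != GREY].value_counts()

    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def genes_in(self, color: str) -> list[str]:
        return list(self.labels.index[self.labels == color])


def detect_modules(
    tom: pd.DataFrame,
    expr: ExpressionMatrix,
    min_size: int = 30,
    merge_cut: float = 0.25,
    cut_height: float = 0.97,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters below ``min_size`` fall into grey; modules whose eigengenes
    correlate above ``1 - merge_cut`` are merged iteratively; surviving
    modules are named by descending size through the standard color list.
    Deterministic for fixed input.
    """
    genes = list(tom.index)
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes.index[sizes >= min_size]
    groups: list[list[str]] = [
        [g for g, c in zip(genes, raw) if c == cid] for cid in sorted(keep)
    ]
    if not groups:
        log.warning("no cluster reached min_size=%d; all genes grey", min_size)
        labels = pd.Series(GREY, index=genes, dtype=object)
        return ModuleAssignment(
            labels=labels,
            eigengenes=pd.DataFrame(index=expr.values.columns),
            module_membership=pd.Series(np.nan, index=genes),
        )
    if len(groups) == 1 and len(groups[0]) == len(genes):
        log.warning("all genes fell into a single module")

    # merge modules with correlated eigengenes until none exceed the cut
    while len(groups) > 1:
        eigs = [module_eigengene(expr, g)[0].to_numpy() for g in groups]
        best, best_cor = None, 1.0 - merge_cut
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                c = np.corrcoef(eigs[i], eigs[j])[0, 1]
                if c > best_cor:
                    best, best_cor = (i, j), c
        if best is None:
            break
        i, j = best
        groups[i] = groups[i] + groups[j]
        del groups[j]

    groups.sort(key=lambda g: (-len(g), g[0]))
    labels = pd.Series(GREY, index=genes, dtype=object)
    eig_cols, mm = {}, pd.Series(np.nan, index=genes)
    for color, members in zip(MODULE_COLORS, groups):
        labels.loc[members] = color
        eig, member_mm = module_eigengene(expr, members)
        eig_cols[color] = eig
        mm.loc[members] = member_mm
    return ModuleAssignment(
        labels=labels,
        eigengenes=pd.DataFrame(eig_cols),
        module_membership=mm,
    )


def default_traits(clinical: ClinicalTable) -> pd.DataFrame:
    """Numeric trait panel: first event, vital status, metastatic + extras."""
    t = clinical.table
    traits = pd.DataFrame(
        {
            "first_event": t["rfs_event"].to_numpy(),
            "vital_status": t["os_event"].to_numpy(),
            "metastatic": t["metastatic"].to_numpy(),
        },
        index=t["patient_id"],
    )
    for col in clinical.extra_traits:
        traits[col] = t[col].to_numpy()
    return traits


def module_trait_correlation(
    assignment: ModuleAssignment, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Returns a tidy frame (module, trait, r, p, significant, defined);
    constant traits are flagged undefined rather than leaking NaN silently.
    """
    rows = []
    common = [p for p in assignment.eigengenes.index if p in traits.index]
    if len(common) < 3:
        raise ValidationError("fewer than 3 samples shared between eigengenes and traits")
    for module in assignment.modules():
        eig = assignment.eigengenes[module].loc[common].to_numpy()
        for trait in traits.columns:
            tv = traits[trait].loc[common].to_numpy(dtype=float)
            if np.std(tv) == 0 or np.std(eig) == 0:
                rows.append(
                    {"module": module, "trait": trait, "r": np.nan, "p": np.nan,
                     "significant": False, "defined": False}
                )
                continue
            r, p = stats.pearsonr(eig, tv)
            rows.append(
                {"module": module, "trait": trait, "r": float(r), "p": float(p),
                 "significant": bool(p < alpha), "defined": True}
            )
    return pd.DataFrame(rows)
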