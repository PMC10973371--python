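"""Signature activity scoring and tertile risk stratification.

Each gene's expression is converted to a z-score across patients (population
standard deviation); a patient's activity score for a signature is the raw
sum of up-gene z-scores minus down-gene z-scores. Patients are then split
into bottom / middle / top thirds of the score, and survival contrasts use
the top (high-risk) versus bottom (low-risk) tertiles only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, Flavor, GeneSignature, ValidationError

log = logging.getLogger("sigforge")


def zscore_by_gene(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores across samples (population sd, i.e. ddof=0).

    Zero-variance genes become all-zero rows with a warning; a single-sample
    matrix is an error because the sd is undefined.
    """
    if expr.shape[1] < 2:
        raise ValidationError("z-scores need at least 2 samples")
    mat = expr.values.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("%d zero-variance genes set to all-zero z-scores", flat.sum())
    z = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns), Flavor.zscore
    )


@dataclass
class ActivityScores:
    """Per-patient signature activity with coverage bookkeeping."""

    scores: pd.Series  # patient -> score
    n_up_used: int
    n_down_used: int
    signature: str


def activity_score(
    zmat: ExpressionMatrix, signature: GeneSignature, mean_scale: bool = False
) -> ActivityScores:
    """Sum of up-gene z-scores minus down-gene z-scores per patient.

    Signature genes absent from the matrix are skipped and counted, never
    silently ignored; a signature with zero matrix coverage is an error.
    ``mean_scale=True`` divides by the number of genes used, for comparing
    signatures of different sizes; the default is the raw sum.
    """
    if zmat.flavor is not Flavor.zscore:
        raise ValidationError("activity_score expects a z-score matrix")
    idx = zmat.values.index
    up = [g for g in signature.up_genes if g in idx]
    down = [g for g in signature.down_genes if g in idx]
    missing = len(signature.genes) - len(up) - len(down)
    if len(up) + len(down) == 0:
        raise ValidationError(f"no gene of signature {signature.name!r} is in the matrix")
    if missing:
        log.warning("signature %s: %d genes absent from matrix", signature.name, missing)
    score = zmat.values.loc[up].sum(axis=0) - zmat.values.loc[down].sum(axis=0)
    if mean_scale:
        score = score / (len(up) + len(down))
    return ActivityScores(
        scores=score.astype(float),
        n_up_used=len(up),
        n_down_used=len(down),
        signature=signature.name,
    )


@dataclass
class RiskStrata:
    """Tertile labels per patient plus the score cut points."""

    labels: pd.Series  # patient -> {"low", "middle", "high"}
    lower_cut: float
    upper_cut: float

    def patients(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def tertile_stratify(scores: pd.Series) -> RiskStrata:
    """Split patients into score tertiles: bottom floor(n/3) are ``low``,
    top floor(n/3) are ``high``, the remainder ``middle``.

    Ranking is by (score, patient ID) so ties resolve deterministically.
    """
    n = len(scores)
    if n < 3:
        raise ValidationError("tertile stratification needs at least 3 patients")
    order = sorted(scores.index, key=lambda p: (scores[p], p))
    third = n // 3
    labels = pd.Series("middle", index=scores.index, dtype=object)
    low, high = order[:third], order[-third:]
    labels.loc[low] = "low"
    labels.loc[high] = "high"
    return RiskStrata(
        labels=labels,
        lower_cut=float(scores[low[-1]]),
        upper_cut=float(scores[high[0]]),
    )
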