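"""Core in-memory containers shared by every pipeline stage.

All tabular data is held in pandas objects; these thin dataclasses add the
identity/validation rules the pipeline relies on (unique identifiers,
non-negative integer counts for raw data, binary event flags) and raise on
violation instead of coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class Flavor(str, Enum):
    """What the numbers in an expression matrix mean."""

    raw_counts = "raw_counts"
    normalized = "normalized"
    log_normalized = "log_normalized"
    zscore = "zscore"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with identifier bookkeeping.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows, samples as columns.
    flavor : Flavor
        Unit of the values; ``raw_counts`` must be non-negative integers.
    """

    values: pd.DataFrame
    flavor: Flavor = Flavor.raw_counts

    def __post_init__(self) -> None:
        self.flavor = Flavor(self.flavor)
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if self.flavor is Flavor.raw_counts:
            if (arr < 0).any():
                raise ValidationError("raw counts must be >= 0")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("raw counts must be integer-valued")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.flavor)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.flavor)


#: columns every clinical table must provide
CLINICAL_REQUIRED = [
    "patient_id",
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
    "metastatic",
]


@dataclass
class ClinicalTable:
    """Per-patient survival/relapse endpoints plus auxiliary numeric traits.

    ``os_time``/``rfs_time`` are in days; ``os_event`` is 1 for deceased,
    ``rfs_event`` 1 for relapse, ``metastatic`` 1 for metastatic disease.
    Any extra numeric columns are carried along as traits.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CLINICAL_REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if t["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id values")
        for col in ("os_time", "rfs_time"):
            vals = t[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValidationError(f"{col} contains non-finite values")
            if (vals < 0).any():
                raise ValidationError(f"{col} contains negative times")
        for col in ("os_event", "rfs_event", "metastatic"):
            if not t[col].isin([0, 1]).all():
                raise ValidationError(f"{col} must be binary 0/1")
        self.table = t.reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"])

    @property
    def extra_traits(self) -> list[str]:
        return [c for c in self.table.columns if c not in CLINICAL_REQUIRED]

    def localized(self) -> "ClinicalTable":
        """Subset to non-metastatic (localized) patients."""
        return ClinicalTable(self.table[self.table["metastatic"] == 0].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets, each with a description and unique member list."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class EdgeList:
    """Undirected interaction edges with STRING-style confidence in [0, 1000].

    Self-loops are removed and symmetric duplicates collapsed at
    construction; each unordered pair appears once, endpoints sorted.
    """

    edges: pd.DataFrame  # columns: gene_a, gene_b, confidence

    def __post_init__(self) -> None:
        e = self.edges
        for col in ("gene_a", "gene_b", "confidence"):
            if col not in e.columns:
                raise ValidationError(f"edge list missing column {col!r}")
        conf = e["confidence"].to_numpy(dtype=float)
        if ((conf < 0) | (conf > 1000)).any():
            raise ValidationError("confidence scores must lie in [0, 1000]")
        e = e[e["gene_a"] != e["gene_b"]].copy()
        lo = e[["gene_a", "gene_b"]].min(axis=1)
        hi = e[["gene_a", "gene_b"]].max(axis=1)
        e["gene_a"], e["gene_b"] = lo, hi
        e = (
            e.sort_values("confidence", ascending=False)
            .drop_duplicates(subset=["gene_a", "gene_b"], keep="first")
            .sort_values(["gene_a", "gene_b"])
            .reset_index(drop=True)
        )
        self.edges = e

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))


@dataclass
class GeneSignature:
    """An up/down prognostic gene signature.

    ``up_genes`` rise and ``down_genes`` fall in the poor-prognosis group;
    the activity score adds z-scores of up genes and subtracts those of
    down genes.
    """

    name: str
    up_genes: list[str]
    down_genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(f"genes in both up and down lists: {sorted(overlap)[:5]}")
        if len(self.up_genes) + len(self.down_genes) == 0:
            raise ValidationError("signature must contain at least one gene")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)

    def flipped(self) -> "GeneSignature":
        return GeneSignature(
            self.name + "_flipped", list(self.down_genes), list(self.up_genes), self.provenance
        )
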