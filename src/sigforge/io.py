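"""Readers and writers for the plain-text formats the pipeline touches.

Expression and clinical tables are tab-separated; gene sets use the GMT
dialect (name TAB description TAB member...); interaction edges use a
STRING-style three-column TSV with combined scores on the 0-1000 scale.
Every reader validates strictly and raises :class:`ParseError` with a line
number rather than silently coercing; every reader/writer pair is a
lossless round trip on valid input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    CLINICAL_REQUIRED,
    EdgeList,
    ExpressionMatrix,
    Flavor,
    GeneSetCollection,
    GeneSignature,
)

log = logging.getLogger("sigforge")


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------- expression


def read_expression(path: str | Path, flavor: Flavor | str = Flavor.raw_counts) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene IDs, header = samples)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: header must name at least one sample")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise ParseError(f"{path}:1: duplicate sample identifiers in header")
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(samples) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
                )
            gene = fields[0]
            if gene in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene row {gene!r}")
            seen.add(gene)
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            genes.append(gene)
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=genes, columns=samples)
    return ExpressionMatrix(values, Flavor(flavor))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values
    if expr.flavor is Flavor.raw_counts:
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


# ------------------------------------------------------------------ clinical


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV; unknown extra columns become numeric traits."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if col == "patient_id":
            continue
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: column {col!r} is not numeric")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB gene...``."""
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# --------------------------------------------------------------------- edges


def read_edge_list(path: str | Path, min_confidence: float = 400.0) -> EdgeList:
    """Read STRING-style edges, dropping those below ``min_confidence``.

    Self-loops are discarded and symmetric duplicates collapsed (the
    higher-confidence record wins).
    """
    path = Path(path)
    records: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ParseError(f"{path}:1: expected 3 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from None
            if not 0 <= score <= 1000:
                raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            if score >= min_confidence:
                records.append((fields[0], fields[1], score))
    df = pd.DataFrame(records, columns=["gene_a", "gene_b", "confidence"])
    return EdgeList(df)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    edges.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- signatures


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a two-column signature TSV: gene TAB direction (up|down)."""
    path = Path(path)
    up: list[str] = []
    down: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'gene<TAB>direction'")
            gene, direction = fields
            if direction == "up":
                up.append(gene)
            elif direction == "down":
                down.append(gene)
            else:
                raise ParseError(f"{path}:{lineno}: direction must be 'up' or 'down'")
    return GeneSignature(name or path.stem, up, down, provenance=str(path))


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sig.up_genes:
            fh.write(f"{g}\tup\n")
        for g in sig.down_genes:
            fh.write(f"{g}\tdown\n")


def hub13_signature() -> GeneSignature:
    """The shipped 13-hub-gene osteosarcoma prognosis signature fixture."""
    here = Path(__file__).parent / "data" / "hub13.tsv"
    return read_signature(here, name="hub13")
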