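"""Readers and writers for the package's text formats.

Formats: binary expression matrices as TSV (header of situation ids, first
column of gene ids) or FIMI sparse transactions (one line per gene listing
0-based column indices of its 1-cells); annotation relations as two-column
TSV; ontologies as a minimal OBO subset (read through obonet); unrolled
datasets as ARFF with binary nominal attributes; machine-readable reports
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import obonet

from .core import (
    AnnotationRelation,
    ExpressionMatrix,
    SemanticBiclusterSystem,
)
from .enrichment import EDGE_TYPES, EnrichmentResult, Ontology
from .errors import FormatError
from .learners import UnrolledDataset

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_matrix_fimi",
    "write_matrix_fimi",
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "write_annotations",
    "read_obo",
    "write_obo",
    "read_arff",
    "write_arff",
    "bicluster_report",
    "write_json",
]


# ---------------------------------------------------------------------------
# Expression matrices


def read_matrix_tsv(path: str | Path) -> ExpressionMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].rstrip("\n").split("\t")
    situations = tuple(header[1:])
    genes: list[str] = []
    rows: list[list[int]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(situations) + 1:
            raise FormatError(f"{path}:{ln}: expected {len(situations) + 1} columns, got {len(parts)}")
        genes.append(parts[0])
        row = []
        for v in parts[1:]:
            if v not in ("0", "1"):
                raise FormatError(f"{path}:{ln}: non-binary cell {v!r}")
            row.append(int(v))
        rows.append(row)
    return ExpressionMatrix(tuple(genes), situations, np.array(rows, dtype=np.uint8).reshape(len(genes), len(situations)))


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.situation_ids) + "\n")
        for i, g in enumerate(matrix.gene_ids):
            fh.write(g + "\t" + "\t".join(str(v) for v in matrix.values[i]) + "\n")


def read_matrix_fimi(
    path: str | Path,
    n_columns: int | None = None,
    gene_ids: tuple[str, ...] | None = None,
    situation_ids: tuple[str, ...] | None = None,
) -> ExpressionMatrix:
    """Read FIMI sparse transactions: 0-based column indices of 1-cells per row.

    Row and column ids are synthesized (``r0..``, ``c0..``) unless given.
    """
    lines = Path(path).read_text().splitlines()
    rows: list[list[int]] = []
    max_col = -1
    for ln, line in enumerate(lines, start=1):
        items = line.split()
        try:
            idx = [int(x) for x in items]
        except ValueError:
            raise FormatError(f"{path}:{ln}: non-integer column index") from None
        if any(i < 0 for i in idx):
            raise FormatError(f"{path}:{ln}: negative column index")
        rows.append(idx)
        if idx:
            max_col = max(max_col, max(idx))
    n_cols = n_columns if n_columns is not None else max_col + 1
    if situation_ids is not None:
        n_cols = len(situation_ids)
    if max_col >= n_cols:
        raise FormatError(f"{path}: column index {max_col} exceeds declared width {n_cols}")
    values = np.zeros((len(rows), n_cols), dtype=np.uint8)
    for i, idx in enumerate(rows):
        values[i, idx] = 1
    genes = gene_ids or tuple(f"r{i}" for i in range(len(rows)))
    sits = situation_ids or tuple(f"c{j}" for j in range(n_cols))
    return ExpressionMatrix(genes, sits, values)


def write_matrix_fimi(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(matrix.shape[0]):
            fh.write(" ".join(str(j) for j in np.flatnonzero(matrix.values[i])) + "\n")


def read_matrix(path: str | Path, fmt: str = "tsv", **kwargs) -> ExpressionMatrix:
    if fmt == "tsv":
        return read_matrix_tsv(path)
    if fmt == "fimi":
        return read_matrix_fimi(path, **kwargs)
    raise FormatError(f"unknown matrix format {fmt!r}")


def write_matrix(matrix: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        write_matrix_tsv(matrix, path)
    elif fmt == "fimi":
        write_matrix_fimi(matrix, path)
    else:
        raise FormatError(f"unknown matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path) -> AnnotationRelation:
    """Two-column TSV: entity_id <TAB> term_id, one pair per line."""
    mapping: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected 2 tab-separated columns")
        mapping.setdefault(parts[0], set()).add(parts[1])
    return AnnotationRelation(mapping)


def write_annotations(relation: AnnotationRelation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for entity, terms in sorted(relation.items()):
            for term in sorted(terms):
                fh.write(f"{entity}\t{term}\n")


# ---------------------------------------------------------------------------
# Ontologies (minimal OBO subset)


def read_obo(path: str | Path) -> Ontology:
    graph = obonet.read_obo(str(path))
    names = {t: data.get("name", t) for t, data in graph.nodes(data=True)}
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key in EDGE_TYPES:
            edges.append((child, parent, key))
    return Ontology(names, edges)


def write_obo(onto: Ontology, path: str | Path, ontology_name: str = "sembic") -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n\n")
        for term in sorted(onto.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {onto.name(term)}\n")
            for _, parent, data in onto.graph.out_edges(term, data=True):
                etype = data["type"]
                if etype == "is_a":
                    fh.write(f"is_a: {parent} ! {onto.name(parent)}\n")
                else:
                    fh.write(f"relationship: {etype} {parent} ! {onto.name(parent)}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# ARFF


def write_arff(data: UnrolledDataset, path: str | Path, relation: str = "unrolled") -> None:
    """Binary nominal attributes {0,1}, class last; rows in row-major cell order."""
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for name in data.feature_names:
            fh.write(f"@attribute {name} {{0,1}}\n")
        fh.write("@attribute expression {0,1}\n\n@data\n")
        ns = len(data.situation_ids)
        for r in range(data.n_rows):
            g, s = r // ns, r % ns
            feats = np.concatenate([data.gene_features[g], data.situation_features[s]])
            fh.write(",".join(str(int(v)) for v in feats) + f",{int(data.labels[r])}\n")


def read_arff(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a binary nominal ARFF back as (feature_names, X, y)."""
    names: list[str] = []
    rows: list[list[int]] = []
    in_data = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("%"):
            continue
        low = stripped.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            names.append(stripped.split()[1])
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if in_data:
            vals = stripped.split(",")
            if len(vals) != len(names):
                raise FormatError(f"{path}:{ln}: expected {len(names)} values")
            if any(v not in ("0", "1") for v in vals):
                raise FormatError(f"{path}:{ln}: non-binary value")
            rows.append([int(v) for v in vals])
    arr = np.array(rows, dtype=np.uint8).reshape(len(rows), len(names))
    return names[:-1], arr[:, :-1], arr[:, -1]


# ---------------------------------------------------------------------------
# Reports


def bicluster_report(
    system: SemanticBiclusterSystem,
    result: EnrichmentResult | None = None,
    induced: list[tuple[list[str], list[str]]] | None = None,
) -> dict[str, Any]:
    """JSON-ready description of a semantic system: terms, weights, p-values, extents."""
    out: dict[str, Any] = {"n_biclusters": len(system), "biclusters": []}
    if result is not None:
        out["alpha_genes"] = result.alpha_genes
        out["alpha_situations"] = result.alpha_situations
    for i, sb in enumerate(system):
        entry: dict[str, Any] = {
            "gene_terms": [
                {"term": t, "weight": w, "negated": not pos} for t, w, pos in sb.gene_terms.items()
            ],
            "situation_terms": [
                {"term": t, "weight": w, "negated": not pos}
                for t, w, pos in sb.situation_terms.items()
            ],
        }
        if result is not None and i < len(result.gene_terms):
            entry["gene_p_values"] = {ts.term: ts.p_value for ts in result.gene_terms[i]}
            entry["situation_p_values"] = {
                ts.term: ts.p_value for ts in result.situation_terms[i]
            }
        if induced is not None and i < len(induced):
            entry["induced_genes"] = sorted(induced[i][0])
            entry["induced_situations"] = sorted(induced[i][1])
        out["biclusters"].append(entry)
    return out


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
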