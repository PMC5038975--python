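"""File formats: ontology / annotation / benchmark TSVs and the
supplementary-table dialects.

Everything is tab-separated UTF-8 text; lines starting with ``#`` are
comments; multi-valued cells use ``|`` as the intra-cell separator.

Formats
-------
ontology TSV        term_id  label  level  parent_ids (pipe-separated)
OBO subset          [Term] stanzas with id / name / is_a (via obonet)
annotation TSV      entity_id  term_id            (one pair per row)
positives TSV       drug_id  gene_id  [evidence]  (pipe-separated drug lists
                    split into one positive per drug)
PPI TSV             protein_a  protein_b  [confidence]
causal TSV          gene_id  term_id

Supplementary dialects (``read_supplementary_table``) mirror the column
layouts of the published supporting tables so their row / entity counts can
be recomputed; no licensed content ships with the package.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .corpus import AnnotationCorpus, load_corpus
from .ontology import Ontology, TermNode, load_ontology

__all__ = [
    "DialectError",
    "read_ontology_tsv",
    "read_ontology_obo",
    "read_annotations_tsv",
    "read_gene_mapping_tsv",
    "read_positives_tsv",
    "read_ppi_tsv",
    "read_causal_tsv",
    "write_ontology_tsv",
    "write_annotations_tsv",
    "write_pairs_tsv",
    "read_supplementary_table",
    "SUPPLEMENTARY_DIALECTS",
]


class DialectError(ValueError):
    """A file does not match the expected column layout."""


def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping comments and blanks."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _header_and_rows(
    path: str | Path, expected: Sequence[str], dialect_name: str
) -> list[tuple[int, list[str]]]:
    it = _rows(path)
    try:
        lineno, header = next(it)
    except StopIteration:
        raise DialectError(f"{path}: empty file (expected {dialect_name} header)")
    if [h.strip() for h in header] != list(expected):
        raise DialectError(
            f"{path}:{lineno}: header {header!r} does not match the "
            f"{dialect_name} dialect {list(expected)!r}"
        )
    out = []
    for lineno, fields in it:
        if len(fields) != len(expected):
            raise DialectError(
                f"{path}:{lineno}: expected {len(expected)} columns, "
                f"got {len(fields)}"
            )
        out.append((lineno, fields))
    return out


# -- core formats ----------------------------------------------------------


def read_ontology_tsv(path: str | Path, **kwargs) -> Ontology:
    """Read the four-column ontology TSV (header required)."""
    rows = _header_and_rows(
        path, ["term_id", "label", "level", "parent_ids"], "ontology"
    )
    records = [
        {"term_id": f[0], "label": f[1], "level": f[2] or None, "parent_ids": f[3]}
        for _, f in rows
    ]
    return load_ontology(records, **kwargs)


def read_ontology_obo(path: str | Path, **kwargs) -> Ontology:
    """Read an OBO-format subset (id, name, is_a) via obonet."""
    import obonet

    graph = obonet.read_obo(path)
    nodes = []
    for term_id, data in graph.nodes(data=True):
        nodes.append(
            TermNode(
                term_id=term_id,
                label=data.get("name", ""),
                parent_ids=frozenset(data.get("is_a", [])),
            )
        )
    return Ontology(nodes, **kwargs)


def read_annotations_tsv(
    path: str | Path, ontology: Ontology, entity_class: str, strict: bool = True
) -> AnnotationCorpus:
    """Read the two-column annotation TSV into a corpus."""
    rows = _header_and_rows(path, ["entity_id", "term_id"], "annotation")
    return load_corpus(
        [(f[0], f[1]) for _, f in rows], ontology, entity_class, strict=strict
    )


GENE_MAPPING_COLUMNS = [
    "mouse_gene",
    "human_gene",
    "mpo_term",
    "super_class_mpo",
    "meddra_code",
    "meddra_level",
]


def read_gene_mapping_tsv(
    path: str | Path, ontology: Ontology, strict: bool = True
) -> AnnotationCorpus:
    """Read the mouse-gene mapping dialect into a gene corpus.

    Entity = human gene symbol, term = the mapped ontology code; the mouse
    gene, MPO term and optional super-class columns are carried in the file
    for provenance but not used for scoring.
    """
    rows = _header_and_rows(path, GENE_MAPPING_COLUMNS, "gene mapping")
    return load_corpus(
        [(f[1], f[4]) for _, f in rows], ontology, "gene", strict=strict
    )


def read_positives_tsv(path: str | Path) -> set[tuple[str, str]]:
    """Read labeled positive pairs; multi-drug cells split per drug."""
    positives = set()
    first = True
    for lineno, fields in _rows(path):
        if first:
            first = False
            if fields[0].strip() == "drug_id":
                continue
        if len(fields) < 2:
            raise DialectError(f"{path}:{lineno}: need at least 2 columns")
        for drug in fields[0].split("|"):
            if drug:
                positives.add((drug, fields[1]))
    return positives


def read_ppi_tsv(
    path: str | Path, min_confidence: float | None = None
) -> list[tuple[str, str]]:
    """Read the PPI edge list, optionally keeping only high-confidence edges.

    A confidence column is required when ``min_confidence`` is set (the
    curated networks use a 0.7 cutoff).
    """
    edges = []
    first = True
    for lineno, fields in _rows(path):
        if first:
            first = False
            if fields[0].strip() == "protein_a":
                continue
        if len(fields) < 2:
            raise DialectError(f"{path}:{lineno}: need at least 2 columns")
        if min_confidence is not None:
            if len(fields) < 3:
                raise DialectError(
                    f"{path}:{lineno}: confidence filtering needs a third column"
                )
            if float(fields[2]) < min_confidence:
                continue
        edges.append((fields[0], fields[1]))
    return edges


def read_causal_tsv(path: str | Path) -> set[tuple[str, str]]:
    """Read known causal (gene_id, term_id) pairs."""
    rows = _header_and_rows(path, ["gene_id", "term_id"], "causal")
    return {(f[0], f[1]) for _, f in rows}


def write_ontology_tsv(ontology: Ontology, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tlabel\tlevel\tparent_ids\n")
        for tid in sorted(ontology.terms):
            node = ontology.terms[tid]
            level = "" if node.level is None else str(node.level)
            parents = "|".join(sorted(node.parent_ids))
            fh.write(f"{tid}\t{node.label}\t{level}\t{parents}\n")


def write_annotations_tsv(corpus: AnnotationCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tterm_id\n")
        for entity in corpus.entities:
            for term in sorted(corpus.profile(entity)):
                fh.write(f"{entity}\t{term}\n")


def write_pairs_tsv(pairs: Sequence[Sequence[str]], path: str | Path, header: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in pairs:
            fh.write("\t".join(str(x) for x in row) + "\n")


# -- supplementary-table dialects -----------------------------------------

SUPPLEMENTARY_DIALECTS: dict[str, list[str]] = {
    "s1_pairs": ["drug_name", "gene_symbol", "score"],
    "s2_biologicals": ["drug_name", "gene_symbol", "score"],
    "s3_toxcast": ["drug_name", "gene_symbol", "score", "hit"],
    "s4_mapping": GENE_MAPPING_COLUMNS,
    "s5_targets": ["cid", "drug_name", "ensembl_gene_id", "gene_name"],
}

_DRUG_COL = {
    "s1_pairs": "drug_name",
    "s2_biologicals": "drug_name",
    "s3_toxcast": "drug_name",
    "s4_mapping": None,
    "s5_targets": "drug_name",
}
_GENE_COL = {
    "s1_pairs": "gene_symbol",
    "s2_biologicals": "gene_symbol",
    "s3_toxcast": "gene_symbol",
    "s4_mapping": "human_gene",
    "s5_targets": "gene_name",
}


def read_supplementary_table(
    path: str | Path, dialect: str
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parse a supplementary-table dialect and recompute its summary counts.

    Returns (table, summary) where summary holds ``n_rows`` and, where the
    dialect defines them, ``n_drugs``, ``n_genes`` and ``n_hits`` (rows with
    a truthy hit flag in the assay dialect).  Malformed rows raise
    :class:`DialectError` with the offending line number.
    """
    if dialect not in SUPPLEMENTARY_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; choose from "
            + ", ".join(sorted(SUPPLEMENTARY_DIALECTS))
        )
    columns = SUPPLEMENTARY_DIALECTS[dialect]
    rows = _header_and_rows(path, columns, dialect)
    table = pd.DataFrame([f for _, f in rows], columns=columns)
    summary: dict[str, int] = {"n_rows": len(table)}
    if _DRUG_COL[dialect]:
        summary["n_drugs"] = int(table[_DRUG_COL[dialect]].nunique())
    if _GENE_COL[dialect]:
        summary["n_genes"] = int(table[_GENE_COL[dialect]].nunique())
    if dialect == "s3_toxcast":
        summary["n_hits"] = int((table["hit"].astype(str) == "1").sum())
    if dialect == "s4_mapping":
        summary["n_mpo_terms"] = int(table["mpo_term"].nunique())
        summary["n_meddra_terms"] = int(table["meddra_code"].nunique())
    return table, summary
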