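"""Readers and writers for every external format the tool touches.

TSV throughout (bioinformatics convention), UTF-8, LF line endings; OBO 1.2
for ontologies, GAF 2.x or a two-column TSV for annotations, GTF for
gene→transcript extraction.  All writers are deterministic byte-for-byte
given identical inputs: fixed row order, fixed float formatting, no
timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import obonet
import pandas as pd

from .containers import BagMap, ExpressionMatrix
from .evaluation import EvaluationReport
from .gold_standard import Ontology
from .preprocess import ExperimentMeta

__all__ = [
    "PredictionRecord",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "read_gene_map",
    "write_gene_map",
    "read_obo",
    "write_obo",
    "read_gaf",
    "read_annotations",
    "write_annotations",
    "write_predictions",
    "read_predictions",
    "write_report",
    "write_json",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class PredictionRecord:
    """One row of the final prediction table."""

    term_id: str
    gene_id: str
    isoform_id: str
    decision_score: float
    probability: float
    fold_change: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"{self.term_id}/{self.isoform_id}: probability {self.probability} not in [0,1]"
            )


# ---------------------------------------------------------------- expression


def read_expression_tsv(path: str | Path, space: str = "fpkm") -> ExpressionMatrix:
    """Read an isoform-by-experiment TSV (first column = isoform id, NA = missing)."""
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed expression table: {exc}") from None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate isoform id {dup!r}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate experiment id in header")
    values = df.to_numpy(dtype=float)
    if space == "log2" and np.isnan(values).any():
        raise ValueError(f"{path}: log2-space matrix contains NA cells")
    return ExpressionMatrix(
        isoform_ids=tuple(str(i) for i in df.index),
        experiment_ids=tuple(str(c) for c in df.columns),
        values=values,
        space=space,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("isoform_id\t" + "\t".join(matrix.experiment_ids) + "\n")
        for i, iso in enumerate(matrix.isoform_ids):
            cells = [
                "NA" if np.isnan(v) else _FLOAT_FMT % v for v in matrix.values[i]
            ]
            fh.write(iso + "\t" + "\t".join(cells) + "\n")


def read_metadata_tsv(path: str | Path) -> list[ExperimentMeta]:
    """Experiment metadata: columns experiment_id, total_reads, mapped_fraction."""
    df = pd.read_csv(path, sep="\t")
    required = {"experiment_id", "total_reads", "mapped_fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    return [
        ExperimentMeta(str(r.experiment_id), int(r.total_reads), float(r.mapped_fraction))
        for r in df.itertuples()
    ]


# ------------------------------------------------------------------ gene map


def read_gene_map(path: str | Path) -> BagMap:
    """gene→isoform map from a two-column TSV or (gene_id, transcript_id) of a GTF."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        pairs = _gene_map_from_gtf(path)
    else:
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] != 2:
            raise ValueError(f"{path}: gene map must have exactly 2 columns")
        gene_col, iso_col = df.columns
        pairs = [(str(g), str(i)) for g, i in zip(df[gene_col], df[iso_col])]
    mapping: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for gene, iso in pairs:
        if iso in seen:
            if seen[iso] != gene:
                raise ValueError(
                    f"{path}: isoform {iso!r} mapped to both {seen[iso]!r} and {gene!r}"
                )
            continue  # duplicate identical pair: collapse
        seen[iso] = gene
        mapping.setdefault(gene, []).append(iso)
    return BagMap(mapping)


def _gene_map_from_gtf(path: Path) -> list[tuple[str, str]]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    pairs = []
    for feat in db.features_of_type("transcript"):
        try:
            gene = feat.attributes["gene_id"][0]
            tx = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(f"{path}: transcript feature missing {exc} attribute") from None
        pairs.append((gene, tx))
    return pairs


def write_gene_map(bags: BagMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tisoform_id\n")
        for gene in sorted(bags):
            for iso in bags[gene]:
                fh.write(f"{gene}\t{iso}\n")


# ------------------------------------------------------------------ ontology


def read_obo(path: str | Path) -> Ontology:
    """OBO 1.2 ontology; is_a edges only, obsolete terms skipped (counted)."""
    graph = obonet.read_obo(str(path))  # skips obsolete terms by default
    n_obsolete = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() == "is_obsolete: true":
                n_obsolete += 1
    if n_obsolete:
        logger.info("%s: skipped %d obsolete terms", path, n_obsolete)
    edges = tuple(
        sorted((child, parent) for child, parent, key in graph.edges(keys=True) if key == "is_a")
    )
    return Ontology(term_ids=frozenset(graph.nodes), is_a_edges=edges)


def write_obo(ont: Ontology, path: str | Path, name: str = "synthetic ontology") -> None:
    parents: dict[str, list[str]] = {}
    for child, parent in ont.is_a_edges:
        parents.setdefault(child, []).append(parent)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {name}\n")
        for term in sorted(ont.term_ids):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for p in sorted(parents.get(term, [])):
                fh.write(f"is_a: {p}\n")


# --------------------------------------------------------------- annotations


def read_gaf(path: str | Path) -> list[tuple[str, str]]:
    """GAF 2.x gene→term annotations (DB Object ID, GO ID columns)."""
    out: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) not in (15, 17):
                raise ValueError(
                    f"{path}:{ln}: expected 15 or 17 GAF columns, found {len(fields)}"
                )
            out.append((fields[1], fields[4]))
    return out


def read_annotations(path: str | Path) -> list[tuple[str, str]]:
    """Gene→term pairs from either a GAF file or a two-column TSV (with header)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    n_cols = len(first.rstrip("\n").split("\t"))
    if first.startswith("!") or n_cols in (15, 17):
        return read_gaf(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: annotation TSV must have exactly 2 columns")
    g_col, t_col = df.columns
    return [(str(g), str(t)) for g, t in zip(df[g_col], df[t_col])]


def write_annotations(annotations: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene, term in sorted(set(annotations)):
            fh.write(f"{gene}\t{term}\n")


# --------------------------------------------------------------- predictions


_PRED_COLUMNS = (
    "term_id", "gene_id", "isoform_id", "decision_score", "probability", "fold_change",
)


def write_predictions(records: list[PredictionRecord], path: str | Path) -> None:
    """Prediction table, rows ordered (term, gene, isoform) for determinism."""
    ordered = sorted(records, key=lambda r: (r.term_id, r.gene_id, r.isoform_id))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_PRED_COLUMNS) + "\n")
        for r in ordered:
            fh.write(
                f"{r.term_id}\t{r.gene_id}\t{r.isoform_id}\t"
                + "\t".join(_FLOAT_FMT % v for v in (r.decision_score, r.probability, r.fold_change))
                + "\n"
            )


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != _PRED_COLUMNS:
        raise ValueError(f"{path}: unexpected prediction columns {tuple(df.columns)}")
    return [
        PredictionRecord(
            term_id=str(r.term_id),
            gene_id=str(r.gene_id),
            isoform_id=str(r.isoform_id),
            decision_score=float(r.decision_score),
            probability=float(r.probability),
            fold_change=float(r.fold_change),
        )
        for r in df.itertuples()
    ]


def write_report(reports: list[EvaluationReport], path: str | Path) -> None:
    """Evaluation table: term_id, group_tag, auc, auprc, p@1%, p@10%, test sizes."""
    ordered = sorted(reports, key=lambda r: (r.term_id, r.group_tag))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "term_id\tgroup_tag\tauc\tauprc\tp_at_1pct\tp_at_10pct\tn_pos_test\tn_neg_test\n"
        )
        for r in ordered:
            p1 = r.precision_at_recall.get(0.01, float("nan"))
            p10 = r.precision_at_recall.get(0.10, float("nan"))
            fh.write(
                f"{r.term_id}\t{r.group_tag}\t"
                + "\t".join(_FLOAT_FMT % v for v in (r.auc, r.auprc, p1, p10))
                + f"\t{r.n_pos_test}\t{r.n_neg_test}\n"
            )


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
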