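"""End-to-end evaluation workflows tying the modules together.

Each workflow produces out-of-fold gene-level scores (every gene scored by a
model that never saw it) and turns them into :class:`EvaluationReport`
rows.  The gene-level SVM on isoform-averaged features is the comparison
baseline: it answers whether modelling isoforms individually — rather than
collapsing each gene to one averaged feature vector — buys predictive power.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.svm import SVC

from .containers import BagMap, ExpressionMatrix
from .evaluation import (
    EvaluationReport,
    evaluate_scores,
    kfold_by_gene,
    partition_by_expression,
    partition_by_homolog,
    split_multi_single,
)
from .gold_standard import TermGoldStandard
from .mil_core import MILConfig, aggregate_gene_scores, run_mil

__all__ = [
    "crossval_scores",
    "gene_svm_scores",
    "kfold_report",
    "multi_single_reports",
    "expression_reports",
    "homolog_reports",
]

logger = logging.getLogger(__name__)


def _restrict(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    genes: list[str],
) -> tuple[ExpressionMatrix, BagMap, TermGoldStandard]:
    sub_bags = bags.subset(genes)
    sub_matrix = matrix.subset_isoforms(sub_bags.isoforms)
    gene_set = set(genes)
    sub_standard = TermGoldStandard(
        term_id=standard.term_id,
        positives=standard.positives & gene_set,
        negatives=standard.negatives & gene_set,
    )
    return sub_matrix, sub_bags, sub_standard


def crossval_scores(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    config: MILConfig,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float], list[int]]:
    """Gene-partitioned k-fold CV of the MIL pipeline.

    Returns pooled out-of-fold gene scores (max over isoforms), out-of-fold
    isoform scores, and the per-fold iteration counts.
    """
    folds = kfold_by_gene(list(bags.genes), k, seed, positives=set(standard.positives))
    gene_scores: dict[str, float] = {}
    iso_scores: dict[str, float] = {}
    iterations: list[int] = []
    for train_genes, test_genes in folds:
        tr_m, tr_b, tr_s = _restrict(matrix, bags, standard, train_genes)
        run = run_mil(tr_m, tr_b, tr_s, config)
        iterations.append(run.n_iterations)
        test_bags = bags.subset(test_genes)
        scores = run.model.decision_scores(matrix.subset_isoforms(test_bags.isoforms))
        iso_scores.update(scores)
        gene_scores.update(aggregate_gene_scores(scores, test_bags))
    return gene_scores, iso_scores, iterations


def gene_svm_scores(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    class_weighting: bool = True,
) -> dict[str, float]:
    """Baseline: ordinary gene-level SVM on isoform-averaged feature vectors.

    Each gene's feature vector is the plain mean of its isoform rows; the
    same gene-partitioned folds are used, so the comparison with the MIL
    pipeline is apples-to-apples.
    """
    genes = list(bags.genes)
    feats = np.vstack([matrix.values[[matrix.row_position(i) for i in bags[g]]].mean(axis=0)
                       for g in genes])
    pos = set(standard.positives)
    y = np.array([1 if g in pos else 0 for g in genes])
    row_of = {g: i for i, g in enumerate(genes)}
    folds = kfold_by_gene(genes, k, seed, positives=pos)
    out: dict[str, float] = {}
    for train_genes, test_genes in folds:
        tr = [row_of[g] for g in train_genes]
        te = [row_of[g] for g in test_genes]
        est = SVC(kernel="linear", C=C,
                  class_weight="balanced" if class_weighting else None)
        est.fit(feats[tr], y[tr])
        scores = est.decision_function(feats[te])
        out.update(zip(test_genes, scores.tolist()))
    return out


def kfold_report(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    config: MILConfig,
    k: int = 5,
    seed: int = 0,
    group_tag: str = "kfold",
) -> EvaluationReport:
    gene_scores, _, _ = crossval_scores(matrix, bags, standard, config, k, seed)
    return evaluate_scores(gene_scores, standard, group_tag=group_tag)


def multi_single_reports(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    config: MILConfig,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Two-fold CV over all genes, evaluated on ratio-matched isoform-count groups.

    One model per fold is trained on the full training half; the out-of-fold
    gene scores are then assessed separately for multi-isoform and
    single-isoform genes, with negatives downsampled so both groups share
    the same positive:negative ratio (hence the same baseline precision).
    """
    gene_scores, _, _ = crossval_scores(matrix, bags, standard, config, k=2, seed=seed)
    groups = split_multi_single(bags, standard, seed)
    reports = []
    for tag, (pos, neg) in sorted(groups.items()):
        sub_scores = {g: gene_scores[g] for g in pos | neg}
        sub_standard = TermGoldStandard(
            term_id=standard.term_id, positives=frozenset(pos), negatives=frozenset(neg)
        )
        reports.append(evaluate_scores(sub_scores, sub_standard, group_tag=tag))
    return reports


def expression_reports(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    config: MILConfig,
    k: int = 5,
    seed: int = 0,
) -> list[EvaluationReport]:
    """One pooled k-fold CV, evaluated separately on expression thirds."""
    gene_scores, _, _ = crossval_scores(matrix, bags, standard, config, k, seed)
    high, mid, low = partition_by_expression(matrix, bags)
    reports = []
    for tag, group in (("expr-high", high), ("expr-mid", mid), ("expr-low", low)):
        sub = {g: gene_scores[g] for g in group}
        gene_set = set(group)
        sub_standard = TermGoldStandard(
            term_id=standard.term_id,
            positives=standard.positives & gene_set,
            negatives=standard.negatives & gene_set,
        )
        if not (sub_standard.positives and sub_standard.negatives):
            logger.warning("%s: %s group lacks a class; skipped", standard.term_id, tag)
            continue
        reports.append(evaluate_scores(sub, sub_standard, group_tag=tag))
    return reports


def homolog_reports(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    config: MILConfig,
    homolog_groups: dict[str, str],
    seed: int = 0,
) -> EvaluationReport:
    """Homolog-safe two-way split: train on each side, score the other, pool."""
    side_a, side_b = partition_by_homolog(list(bags.genes), homolog_groups, seed)
    gene_scores: dict[str, float] = {}
    for train_set, test_set in ((side_a, side_b), (side_b, side_a)):
        tr_m, tr_b, tr_s = _restrict(matrix, bags, standard, sorted(train_set))
        run = run_mil(tr_m, tr_b, tr_s, config)
        test_bags = bags.subset(sorted(test_set))
        scores = run.model.decision_scores(matrix.subset_isoforms(test_bags.isoforms))
        gene_scores.update(aggregate_gene_scores(scores, test_bags))
    return evaluate_scores(gene_scores, standard, group_tag="homolog-safe")
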