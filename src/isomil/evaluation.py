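"""Performance-estimation procedures: gene-partitioned CV, ranking metrics,
and the stratified comparisons (multi- vs single-isoform, expression level,
homolog-aware splits).

All partitioning is by gene, never by isoform: isoforms of one gene share
most of their expression signal, so splitting them across train and test
would leak information and inflate every metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .containers import BagMap, ExpressionMatrix
from .gold_standard import TermGoldStandard

__all__ = [
    "EvaluationReport",
    "kfold_by_gene",
    "roc_auc",
    "auprc",
    "precision_at_recall",
    "split_multi_single",
    "partition_by_expression",
    "partition_by_homolog",
    "evaluate_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationReport:
    """Gene-level ranking metrics for one term under one evaluation scheme."""

    term_id: str
    auc: float
    auprc: float
    precision_at_recall: dict[float, float]
    n_pos_test: int
    n_neg_test: int
    group_tag: str = ""

    @property
    def baseline_precision(self) -> float:
        return self.n_pos_test / (self.n_pos_test + self.n_neg_test)


def kfold_by_gene(
    genes: list[str],
    k: int,
    seed: int,
    positives: set[str] | None = None,
) -> list[tuple[list[str], list[str]]]:
    """k disjoint, exhaustive, near-equal folds over genes.

    With ``positives`` given, positive and negative genes are shuffled
    separately and dealt round-robin, so every fold holds at least one
    positive whenever there are at least k positives.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(genes) < k:
        raise ValueError(f"cannot make {k} folds from {len(genes)} genes")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    if positives is None:
        shuffled = list(genes)
        rng.shuffle(shuffled)
        for i, g in enumerate(shuffled):
            folds[i % k].append(g)
    else:
        pos = [g for g in genes if g in positives]
        neg = [g for g in genes if g not in positives]
        rng.shuffle(pos)
        rng.shuffle(neg)
        for i, g in enumerate(pos + neg):
            folds[i % k].append(g)
    out = []
    for i in range(k):
        test = sorted(folds[i])
        train = sorted(g for j, f in enumerate(folds) if j != i for g in f)
        out.append((train, test))
    return out


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    return s, y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + 0.5 P(tie)."""
    s, y = _check_scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC undefined with a single class")
    return float(roc_auc_score(y, s))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve, average-precision convention.

    Mean over positives of the precision at each positive's rank in the
    score-descending ordering (ties broken by input order).
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined without positives")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    cum_pos = np.cumsum(y_sorted)
    ranks = np.arange(1, len(y_sorted) + 1)
    prec_at_pos = cum_pos[y_sorted == 1] / ranks[y_sorted == 1]
    return float(prec_at_pos.mean())


def precision_at_recall(scores, labels, r: float) -> float:
    """Precision of the smallest score-threshold prediction set reaching recall r.

    The required number of recovered positives is ceil(r * n_pos); the
    threshold sweep moves down distinct score values, so tied scores enter
    the prediction set together.
    """
    if not 0 < r <= 1:
        raise ValueError("recall target must be in (0, 1]")
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("precision at recall undefined without positives")
    need = math.ceil(r * n_pos)
    for thr in sorted(set(s.tolist()), reverse=True):
        picked = s >= thr
        tp = int(y[picked].sum())
        if tp >= need:
            return float(tp / picked.sum())
    raise AssertionError("unreachable: full set always reaches recall 1")


def split_multi_single(
    bags: BagMap,
    standard: TermGoldStandard,
    seed: int,
) -> dict[str, tuple[set[str], set[str]]]:
    """Partition genes by isoform count into ratio-matched sub-problems.

    Genes are split into multi-isoform (>1) and single-isoform (=1) groups;
    negatives in the group with the lower positive:negative ratio are
    randomly downsampled until both groups share the same ratio — removing
    negatives can only raise a ratio, so both are equalised to the larger
    one.  Equal ratios mean equal baseline precision, making the two AUPRCs
    comparable.  A group without positives is dropped with a logged reason.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, tuple[set[str], set[str]]] = {}
    raw: dict[str, tuple[list[str], list[str]]] = {}
    for tag, pred in (("multi", lambda g: len(bags[g]) > 1),
                      ("single", lambda g: len(bags[g]) == 1)):
        pos = sorted(g for g in bags if pred(g) and g in standard.positives)
        neg = sorted(g for g in bags if pred(g) and g in standard.negatives)
        if not pos:
            logger.warning("%s: %s-isoform group has no positive genes; skipped",
                           standard.term_id, tag)
            continue
        raw[tag] = (pos, neg)
    if len(raw) < 2:
        for tag, (pos, neg) in raw.items():
            groups[tag] = (set(pos), set(neg))
        return groups
    ratios = {tag: len(pos) / len(neg) for tag, (pos, neg) in raw.items() if neg}
    target = max(ratios.values()) if ratios else 1.0
    for tag, (pos, neg) in raw.items():
        want = int(round(len(pos) / target))
        if want < len(neg):
            neg = sorted(rng.choice(neg, size=want, replace=False).tolist())
        groups[tag] = (set(pos), set(neg))
    return groups


def partition_by_expression(
    matrix: ExpressionMatrix, bags: BagMap
) -> tuple[list[str], list[str], list[str]]:
    """Split genes into high / medium / low expression thirds.

    A gene's expression level is the mean of its isoforms' non-sentinel
    cells, averaged across all experiments; genes with only sentinel cells
    fall to the low group.
    """
    level: dict[str, float] = {}
    sentinel_only: list[str] = []
    for gene in bags:
        cells = []
        for iso in bags[gene]:
            row = matrix.row(iso)
            cells.append(row[row != matrix.missing_sentinel])
        allc = np.concatenate(cells) if cells else np.array([])
        if allc.size == 0:
            sentinel_only.append(gene)
        else:
            level[gene] = float(allc.mean())
    ordered = sorted(level, key=lambda g: (-level[g], g))
    n = len(ordered) + len(sentinel_only)
    cut1, cut2 = round(n / 3), round(2 * n / 3)
    ranked = ordered + sorted(sentinel_only)
    high, mid, low = ranked[:cut1], ranked[cut1:cut2], ranked[cut2:]
    return high, mid, low


def partition_by_homolog(
    genes: list[str],
    homolog_groups: dict[str, str],
    seed: int,
) -> tuple[set[str], set[str]]:
    """Split genes into two near-halves without splitting any homolog group.

    Genes sharing a homolog group travel together (sequence similarity means
    correlated expression and annotations, another leak channel).  Groups
    are assigned greedily, largest first, to the currently smaller side;
    ties in size are broken by a seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for g in genes:
        by_group.setdefault(homolog_groups.get(g, f"__singleton__{g}"), []).append(g)
    groups = list(by_group.values())
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]
    groups.sort(key=len, reverse=True)  # stable: seeded order breaks ties
    a: set[str] = set()
    b: set[str] = set()
    for grp in groups:
        (a if len(a) <= len(b) else b).update(grp)
    return a, b


def evaluate_scores(
    gene_scores: dict[str, float],
    standard: TermGoldStandard,
    recalls: tuple[float, ...] = (0.01, 0.10),
    group_tag: str = "",
) -> EvaluationReport:
    """Bundle the ranking metrics for one set of gene-level scores."""
    genes = sorted(gene_scores)
    scores = [gene_scores[g] for g in genes]
    labels = [1 if g in standard.positives else 0 for g in genes]
    return EvaluationReport(
        term_id=standard.term_id,
        auc=roc_auc(scores, labels),
        auprc=auprc(scores, labels),
        precision_at_recall={r: precision_at_recall(scores, labels, r) for r in recalls},
        n_pos_test=sum(labels),
        n_neg_test=len(labels) - sum(labels),
        group_tag=group_tag,
    )
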