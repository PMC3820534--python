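"""Bootstrap-bagged out-of-bag scoring and probability calibration.

Final per-isoform predictions come from 0.632 bootstrap bagging: genes are
sampled with replacement to form a training set, the MIL loop is run on it,
and every isoform of a gene never drawn (out-of-bag, ~36.8% of genes per
round) is scored by the resulting model.  After 30 rounds each isoform's
decision score is the median over the rounds in which it was held out.
Scores are mapped to probabilities by a Platt-style sigmoid fitted on the
final labeling of a full-data run, and reported alongside the fold change
over the term's background probability (positives / universe, defined over
genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .containers import BagMap, ExpressionMatrix, InstanceLabeling, Label
from .gold_standard import TermGoldStandard
from .mil_core import MILConfig, run_mil

__all__ = [
    "TermPredictions",
    "bootstrap_split",
    "bagged_predict",
    "calibrate_probability",
    "fold_change",
]

logger = logging.getLogger(__name__)


@dataclass
class TermPredictions:
    """Final per-isoform predictions for one term."""

    term_id: str
    decision_score: dict[str, float]
    probability: dict[str, float]
    fold_change: dict[str, float]
    gene_score: dict[str, float]
    n_rounds_covered: dict[str, int]
    never_oob: frozenset[str] = field(default_factory=frozenset)


def bootstrap_split(genes: list[str], seed: int) -> tuple[list[str], set[str]]:
    """Draw n genes with replacement; the never-drawn genes are out-of-bag.

    Splitting is by gene so that all isoforms of a gene travel together —
    otherwise isoforms of one gene could sit on both sides and leak.
    """
    if not genes:
        raise ValueError("no genes to split")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(genes), size=len(genes))
    train = [genes[i] for i in idx]
    out_of_bag = set(genes) - set(train)
    return train, out_of_bag


def _replicated_training_problem(
    train: list[str],
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
) -> tuple[ExpressionMatrix, BagMap, TermGoldStandard]:
    """Materialise a bootstrap multiset as a concrete problem.

    A gene drawn k times contributes k bag copies (ids suffixed ``#2``…)
    whose isoform rows are duplicated, so repeated draws carry the standard
    bootstrap weight in the SVM fit.
    """
    counts: dict[str, int] = {}
    gene_ids: list[str] = []
    bag_def: dict[str, tuple[str, ...]] = {}
    iso_src: list[str] = []
    iso_new: list[str] = []
    for g in train:
        counts[g] = counts.get(g, 0) + 1
        k = counts[g]
        new_gene = g if k == 1 else f"{g}#{k}"
        gene_ids.append(new_gene)
        new_isos = []
        for iso in bags[g]:
            new_iso = iso if k == 1 else f"{iso}#{k}"
            iso_src.append(iso)
            iso_new.append(new_iso)
            new_isos.append(new_iso)
        bag_def[new_gene] = tuple(new_isos)
    sub_matrix = ExpressionMatrix(
        isoform_ids=tuple(iso_new),
        experiment_ids=matrix.experiment_ids,
        values=matrix.values[[matrix.row_position(i) for i in iso_src]],
        space=matrix.space,
        missing_sentinel=matrix.missing_sentinel,
    )
    positives = frozenset(g for g in gene_ids if g.split("#")[0] in standard.positives)
    negatives = frozenset(g for g in gene_ids if g.split("#")[0] in standard.negatives)
    sub_standard = TermGoldStandard(
        term_id=standard.term_id, positives=positives, negatives=negatives
    )
    return sub_matrix, BagMap(bag_def), sub_standard


def bagged_predict(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    config: MILConfig,
    n_rounds: int = 30,
) -> TermPredictions:
    """Median-of-out-of-bag-scores prediction for every isoform.

    Per round: bootstrap genes, run the MIL loop on the resample, score the
    out-of-bag isoforms with the final model.  An isoform's decision score is
    the median over the rounds in which it was out-of-bag.  Isoforms that
    were never out-of-bag (probability (1−1/n)^(n·rounds), tiny but nonzero)
    are scored by one supplementary round trained on all other genes, and
    flagged.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    genes = list(bags.genes)
    rng = np.random.default_rng(config.seed)
    round_seeds = rng.integers(0, 2**31 - 1, size=n_rounds + 1)

    oob_scores: dict[str, list[float]] = {i: [] for i in bags.isoforms}
    for r in range(n_rounds):
        train, oob = bootstrap_split(genes, int(round_seeds[r]))
        sub_m, sub_b, sub_s = _replicated_training_problem(train, matrix, bags, standard)
        run = run_mil(sub_m, sub_b, sub_s, config)
        oob_isos = [i for g in sorted(oob) for i in bags[g]]
        if not oob_isos:
            continue
        scores = run.model.decision_scores(matrix.subset_isoforms(oob_isos))
        for iso, s in scores.items():
            oob_scores[iso].append(s)

    never = frozenset(i for i, s in oob_scores.items() if not s)
    if never:
        never_genes = sorted({bags.gene_of(i) for i in never})
        logger.warning(
            "%d isoforms (genes %s) were never out-of-bag in %d rounds; "
            "scoring them with one supplementary hold-out round",
            len(never), ", ".join(never_genes[:5]), n_rounds,
        )
        train = [g for g in genes if g not in set(never_genes)]
        sub_m, sub_b, sub_s = _replicated_training_problem(train, matrix, bags, standard)
        run = run_mil(sub_m, sub_b, sub_s, config)
        held_isos = [i for g in never_genes for i in bags[g]]
        scores = run.model.decision_scores(matrix.subset_isoforms(held_isos))
        for iso in never:
            oob_scores[iso].append(scores[iso])

    decision = {i: float(np.median(s)) for i, s in oob_scores.items()}
    covered = {i: (0 if i in never else len(s)) for i, s in oob_scores.items()}

    # calibrate on the labeling a full-data run converges to
    full_run = run_mil(matrix, bags, standard, config)
    probability = calibrate_probability(decision, full_run.labeling)
    fc = {i: fold_change(p, standard, len(standard.universe)) for i, p in probability.items()}
    gene_score = {g: max(decision[i] for i in bags[g]) for g in bags}
    return TermPredictions(
        term_id=standard.term_id,
        decision_score=decision,
        probability=probability,
        fold_change=fc,
        gene_score=gene_score,
        n_rounds_covered=covered,
        never_oob=never,
    )


def calibrate_probability(
    decision_scores: dict[str, float],
    final_labeling: InstanceLabeling,
) -> dict[str, float]:
    """Platt-style monotone sigmoid map from decision scores to [0, 1].

    The logistic fit uses the (score, label) pairs of POS/NEG isoforms in the
    final labeling; NEUTRAL isoforms contribute no fit data but do receive
    probabilities.  Monotone, so ranking by probability equals ranking by
    score.
    """
    fit_isos = [
        i for i in decision_scores
        if i in final_labeling and final_labeling[i] is not Label.NEUTRAL
    ]
    y = np.array([1 if final_labeling[i] is Label.POS else 0 for i in fit_isos])
    if len(np.unique(y)) < 2:
        raise ValueError("calibration needs both classes in the final labeling")
    X = np.array([[decision_scores[i]] for i in fit_isos])
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
    lr.fit(X, y)
    isos = list(decision_scores)
    probs = lr.predict_proba(np.array([[decision_scores[i]] for i in isos]))[:, 1]
    return dict(zip(isos, probs.tolist()))


def fold_change(
    probability: float, standard: TermGoldStandard, universe_size: int
) -> float:
    """Calibrated probability relative to the term's background probability."""
    if not standard.positives:
        raise ValueError(f"term {standard.term_id}: zero prior, fold change undefined")
    prior = len(standard.positives) / universe_size
    return probability / prior
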