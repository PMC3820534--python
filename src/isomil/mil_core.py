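"""Iterative mi-SVM / MI-SVM heuristic for isoform-level function prediction.

The learning problem: each gene (bag) carries an observed function label; its
isoforms (instances) carry hidden labels.  A positive gene must have at least
one functional isoform (the "witness"); no isoform of a negative gene is
functional.  Exact optimisation over the hidden labels is a mixed-integer
program, so the loop below alternates between the two tractable halves:

1. given the current instance labels, fit a soft-margin linear SVM;
2. given the fitted hyperplane, reassign hidden labels in the positive bags
   (mi-SVM: threshold on the decision score with an at-least-one-positive
   rescue; MI-SVM: keep only the arg-max isoform as witness, drop the rest
   from the margin computation as NEUTRAL);

until the assignment stops changing or revisits an earlier state (cycle
detection), or an iteration cap is hit.

mi-SVM threshold variants, in increasing strictness, are computed from the
decision scores of negative-bag instances: ``mode`` (histogram mode),
``p75`` (75th percentile — the default) and ``max``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .containers import BagMap, ExpressionMatrix, InstanceLabeling, Label
from .gold_standard import TermGoldStandard

__all__ = [
    "MILConfig",
    "MarginModel",
    "MILRun",
    "initialize_labels",
    "train_margin_classifier",
    "score_instances",
    "compute_threshold",
    "update_labels_mi",
    "update_labels_MI",
    "has_converged",
    "run_mil",
    "aggregate_gene_scores",
    "svm_objective",
]

logger = logging.getLogger(__name__)

FORMULATIONS = ("mi_svm", "MI_svm", "MI_svm_random")
THRESHOLD_VARIANTS = ("mode", "p75", "max")
#: grid searched when regularization_strength is None
C_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class MILConfig:
    """Configuration of one MIL run.

    regularization_strength is the soft-margin trade-off C; ``None`` selects
    it once per term by 3-fold inner cross-validation over a small grid.
    class_weighting up-weights the minority class inversely to its frequency
    (positive:negative gene ratios are typically ~1:100).
    threshold_source controls which instances feed the mi-SVM threshold:
    ``negative_bags`` (default: instances of negative genes) or
    ``current_neg`` (all instances currently labelled NEG).
    """

    formulation: str = "mi_svm"
    threshold_variant: str = "p75"
    regularization_strength: float | None = 1.0
    max_iterations: int = 50
    class_weighting: bool = False
    seed: int = 0
    threshold_source: str = "negative_bags"

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.threshold_variant not in THRESHOLD_VARIANTS:
            raise ValueError(f"unknown threshold variant {self.threshold_variant!r}")
        if self.threshold_source not in ("negative_bags", "current_neg"):
            raise ValueError(f"unknown threshold source {self.threshold_source!r}")
        if self.regularization_strength is not None and self.regularization_strength <= 0:
            raise ValueError("regularization_strength must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class MarginModel:
    """A fitted linear maximum-margin classifier bound to a feature space."""

    estimator: LinearSVC
    experiment_ids: tuple[str, ...]
    C: float

    def decision_scores(self, matrix: ExpressionMatrix) -> dict[str, float]:
        if matrix.experiment_ids != self.experiment_ids:
            raise ValueError("experiment columns do not match the model's feature space")
        scores = self.estimator.decision_function(matrix.values)
        return dict(zip(matrix.isoform_ids, scores.tolist()))

    @property
    def coef(self) -> np.ndarray:
        return self.estimator.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.estimator.intercept_[0])


class MILRun(NamedTuple):
    model: MarginModel
    labeling: InstanceLabeling
    n_iterations: int  # number of label assignments, counting the initial one
    thresholds: tuple[float, ...]
    converged: bool


def initialize_labels(standard: TermGoldStandard, bags: BagMap) -> InstanceLabeling:
    """Start the loop: every isoform of a positive gene POS, all others NEG."""
    labels: dict[str, Label] = {}
    for gene in bags:
        if gene in standard.positives:
            lab = Label.POS
        elif gene in standard.negatives:
            lab = Label.NEG
        else:
            raise ValueError(f"gene {gene!r} missing from the gold standard")
        for iso in bags[gene]:
            labels[iso] = lab
    return InstanceLabeling(labels)


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, class_weighting: bool) -> LinearSVC:
    # liblinear dual solver: standard hinge loss, deterministic via fixed
    # random_state; tolerance loose enough for the ~4k x 120 fits that
    # dominate the pipeline, tight enough not to move label updates
    est = LinearSVC(
        C=C,
        loss="hinge",
        dual=True,
        tol=1e-3,
        max_iter=50_000,
        random_state=0,
        class_weight="balanced" if class_weighting else None,
    )
    est.fit(X, y)
    return est


def select_regularization(
    X: np.ndarray,
    y: np.ndarray,
    class_weighting: bool,
    seed: int,
    grid: tuple[float, ...] = C_GRID,
) -> float:
    """Pick C by 3-fold stratified CV accuracy over a small grid (ties -> smaller C)."""
    n_folds = min(3, int(np.bincount(y).min()))
    if n_folds < 2:
        return grid[len(grid) // 2]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    best_c, best_acc = grid[0], -1.0
    for c in grid:
        accs = []
        for tr, te in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                continue
            est = _fit_svc(X[tr], y[tr], c, class_weighting)
            accs.append(float((est.predict(X[te]) == y[te]).mean()))
        acc = float(np.mean(accs)) if accs else -1.0
        if acc > best_acc + 1e-12:
            best_acc, best_c = acc, c
    return best_c


def train_margin_classifier(
    matrix: ExpressionMatrix,
    labeling: InstanceLabeling,
    config: MILConfig,
    term_id: str = "?",
) -> MarginModel:
    """Fit the soft-margin model on POS/NEG instances (NEUTRAL excluded)."""
    train_isos = [i for i in matrix.isoform_ids if labeling[i] is not Label.NEUTRAL]
    y = np.array([1 if labeling[i] is Label.POS else 0 for i in train_isos])
    if len(np.unique(y)) < 2:
        raise ValueError(f"term {term_id}: labeling has a single class; cannot train")
    X = matrix.values[[matrix.row_position(i) for i in train_isos]]
    C = config.regularization_strength
    if C is None:
        C = select_regularization(X, y, config.class_weighting, config.seed)
        logger.debug("term %s: inner CV selected C=%g", term_id, C)
    est = _fit_svc(X, y, C, config.class_weighting)
    return MarginModel(estimator=est, experiment_ids=matrix.experiment_ids, C=C)


def score_instances(model: MarginModel, matrix: ExpressionMatrix) -> dict[str, float]:
    """Signed distance to the hyperplane for every isoform in the matrix."""
    return model.decision_scores(matrix)


def compute_threshold(neg_scores, variant: str) -> float:
    """Witness-selection cutoff from the negative-instance score distribution.

    ``max``: exact maximum.  ``p75``: 75th percentile, linear interpolation
    between order statistics.  ``mode``: midpoint of the most populated
    histogram bin, Freedman–Diaconis bin widths, ties to the lower bin.
    """
    scores = np.asarray(list(neg_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot compute a threshold from zero negative scores")
    if variant == "max":
        return float(scores.max())
    if variant == "p75":
        return float(np.percentile(scores, 75))
    if variant == "mode":
        if np.ptp(scores) == 0:
            return float(scores[0])
        counts, edges = np.histogram(scores, bins="fd")
        b = int(np.argmax(counts))  # argmax returns the first (lowest) max bin
        return float((edges[b] + edges[b + 1]) / 2)
    raise ValueError(f"unknown threshold variant {variant!r}")


def update_labels_mi(
    scores: dict[str, float],
    bags: BagMap,
    standard: TermGoldStandard,
    threshold: float,
) -> InstanceLabeling:
    """mi-SVM update: threshold positive-bag instances, rescue empty bags.

    In each positive gene, isoforms scoring strictly above the threshold
    become POS and the rest NEG; if none clears it, the maximum-scoring
    isoform (ties to the lexicographically smallest id) is forced POS so the
    bag constraint always holds.  Negative-gene isoforms stay NEG.
    """
    labels: dict[str, Label] = {}
    for gene in bags:
        isos = bags[gene]
        if gene in standard.positives:
            above = [i for i in isos if scores[i] > threshold]
            if above:
                for i in isos:
                    labels[i] = Label.POS if scores[i] > threshold else Label.NEG
            else:
                top = max(scores[i] for i in isos)
                best = min(i for i in isos if scores[i] == top)
                for i in isos:
                    labels[i] = Label.POS if i == best else Label.NEG
        else:
            for i in isos:
                labels[i] = Label.NEG
    return InstanceLabeling(labels)


def update_labels_MI(
    scores: dict[str, float],
    bags: BagMap,
    standard: TermGoldStandard,
    random_witness: bool = False,
    seed: int = 0,
) -> InstanceLabeling:
    """MI-SVM update: one witness per positive gene, the rest NEUTRAL.

    The witness is the maximum-scoring isoform (ties to the smallest id), or
    a uniformly random isoform when ``random_witness`` is set (the baseline
    that measures how much witness *selection* contributes).
    """
    rng = np.random.default_rng(seed)
    labels: dict[str, Label] = {}
    for gene in bags:
        isos = bags[gene]
        if gene in standard.positives:
            if random_witness:
                witness = isos[int(rng.integers(len(isos)))]
            else:
                top = max(scores[i] for i in isos)
                witness = min(i for i in isos if scores[i] == top)
            for i in isos:
                labels[i] = Label.POS if i == witness else Label.NEUTRAL
        else:
            for i in isos:
                labels[i] = Label.NEG
    return InstanceLabeling(labels)


def has_converged(
    history: list[InstanceLabeling], candidate: InstanceLabeling
) -> bool:
    """True iff the candidate repeats the last assignment or any earlier one."""
    if not history:
        raise ValueError("empty labeling history")
    return candidate == history[-1] or candidate in history


def run_mil(
    matrix: ExpressionMatrix,
    bags: BagMap,
    standard: TermGoldStandard,
    config: MILConfig,
) -> MILRun:
    """Run the full iterative heuristic for one term.

    Returns the model of the final iteration, the final labeling (which
    always satisfies the bag constraint), the number of label assignments
    generated (including the initial all-positive one), the threshold
    trajectory, and whether the loop converged before the iteration cap.
    """
    pos_in_bags = [g for g in bags if g in standard.positives]
    neg_in_bags = [g for g in bags if g in standard.negatives]
    if not pos_in_bags or not neg_in_bags:
        raise ValueError(
            f"term {standard.term_id}: need at least one positive and one "
            f"negative gene among the bags"
        )
    neg_bag_isoforms = [i for g in neg_in_bags for i in bags[g]]

    labeling = initialize_labels(standard, bags)
    history = [labeling]
    seen = {labeling}
    thresholds: list[float] = []
    converged = False
    model: MarginModel | None = None
    config_eff = config
    if config.regularization_strength is None:
        # tune once on the initial labeling, then hold C fixed across iterations
        train_isos = list(matrix.isoform_ids)
        y = np.array([1 if labeling[i] is Label.POS else 0 for i in train_isos])
        X = matrix.values[[matrix.row_position(i) for i in train_isos]]
        c = select_regularization(X, y, config.class_weighting, config.seed)
        config_eff = replace(config, regularization_strength=c)

    for it in range(config.max_iterations):
        model = train_margin_classifier(matrix, labeling, config_eff, standard.term_id)
        scores = score_instances(model, matrix)
        if config.formulation == "mi_svm":
            if config.threshold_source == "negative_bags":
                neg_scores = [scores[i] for i in neg_bag_isoforms]
            else:
                neg_scores = [scores[i] for i in matrix.isoform_ids if labeling[i] is Label.NEG]
            thr = compute_threshold(neg_scores, config.threshold_variant)
            thresholds.append(thr)
            candidate = update_labels_mi(scores, bags, standard, thr)
        else:
            candidate = update_labels_MI(
                scores,
                bags,
                standard,
                random_witness=(config.formulation == "MI_svm_random"),
                seed=(config.seed * 1000003 + it) % (2**31),
            )
        done = candidate == history[-1] or candidate in seen
        history.append(candidate)
        seen.add(candidate)
        labeling = candidate
        if done:
            converged = True
            break

    if not converged:
        logger.warning(
            "term %s: MIL loop did not converge within %d iterations",
            standard.term_id, config.max_iterations,
        )
    assert model is not None
    return MILRun(
        model=model,
        labeling=labeling,
        n_iterations=len(history),
        thresholds=tuple(thresholds),
        converged=converged,
    )


def aggregate_gene_scores(
    scores: dict[str, float], bags: BagMap
) -> dict[str, float]:
    """Gene score = maximum decision score over the gene's isoforms."""
    out: dict[str, float] = {}
    for gene in bags:
        vals = []
        for iso in bags[gene]:
            if iso not in scores:
                raise KeyError(f"isoform {iso!r} of gene {gene!r} has no score")
            vals.append(scores[iso])
        out[gene] = max(vals)
    return out


def svm_objective(
    model: MarginModel,
    matrix: ExpressionMatrix,
    labeling: InstanceLabeling,
    C: float | None = None,
) -> float:
    """Primal soft-margin objective 0.5 ||w||^2 + C * sum of hinge losses.

    Evaluated on the POS/NEG instances of ``labeling`` (NEUTRAL excluded),
    without class weights, so objectives of different labelings of the same
    data are directly comparable.
    """
    if C is None:
        C = model.C
    isos = [i for i in matrix.isoform_ids if labeling[i] is not Label.NEUTRAL]
    y = np.array([1.0 if labeling[i] is Label.POS else -1.0 for i in isos])
    X = matrix.values[[matrix.row_position(i) for i in isos]]
    margins = y * (X @ model.coef + model.intercept)
    hinge = np.maximum(0.0, 1.0 - margins).sum()
    return float(0.5 * model.coef @ model.coef + C * hinge)
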