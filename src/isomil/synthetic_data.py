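"""Synthetic bag-structured expression data with planted witness isoforms.

The generator emulates the statistical structure the MIL method relies on:
functional isoforms of positive genes share a co-expression signature (a
fixed subset of experiments where their log2 expression is shifted upward),
while non-functional isoforms — whether in positive or negative genes — are
baseline noise.  Per-isoform baseline means vary, mimicking
expression-level heterogeneity, and a small fraction of cells is missing
(set to the −15 sentinel), mimicking undetected transcripts.

Everything is drawn from one seeded generator, so a dataset is reproducible
bit-for-bit from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING_SENTINEL, BagMap, ExpressionMatrix
from .gold_standard import Ontology, TermGoldStandard

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_term_dataset",
    "generate_toy_ontology",
    "recovery_balanced_accuracy",
]

#: isoform-count probabilities over 1..6; most genes are single-isoform
DEFAULT_ISOFORM_COUNT_PROBS = (0.60, 0.15, 0.10, 0.07, 0.05, 0.03)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic term.

    Defaults plant one witness per positive gene, a 30-experiment signature
    shifted by 2 log2 units over unit-variance noise, and a ~2.4% positive
    prevalence (50 of 2050 genes) — the regime of a mid-sized GO term.
    ``witness_fraction=None`` means exactly one witness per positive gene;
    a fraction f plants ceil(f * n_isoforms) witnesses.
    """

    n_pos_genes: int = 50
    n_neg_genes: int = 2000
    n_experiments: int = 120
    isoform_count_probs: tuple[float, ...] = DEFAULT_ISOFORM_COUNT_PROBS
    witness_fraction: float | None = None
    signature_dim: int = 30
    effect_size: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    baseline_mean: float = 2.0
    baseline_sd: float = 2.0
    seed: int = 0
    term_id: str = "GO:SYN0001"

    def __post_init__(self) -> None:
        if min(self.n_pos_genes, self.n_neg_genes, self.n_experiments) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0,1]")
        if self.witness_fraction is not None and not 0 < self.witness_fraction <= 1:
            raise ValueError("witness_fraction must be in (0,1]")
        if self.signature_dim > self.n_experiments:
            raise ValueError("signature_dim cannot exceed n_experiments")
        if abs(sum(self.isoform_count_probs) - 1.0) > 1e-9:
            raise ValueError("isoform_count_probs must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted functional/non-functional status of every isoform."""

    functional: frozenset[str]
    signature_experiments: tuple[str, ...] = field(default=())

    def is_functional(self, isoform_id: str) -> bool:
        return isoform_id in self.functional


def _isoform_counts(rng: np.random.Generator, n_genes: int, probs) -> np.ndarray:
    return rng.choice(np.arange(1, len(probs) + 1), size=n_genes, p=np.asarray(probs))


def generate_term_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, BagMap, TermGoldStandard, GroundTruth]:
    """One complete synthetic study: matrix, bags, gold standard, truth.

    The matrix is in log2 space.  Every positive gene has at least one
    functional isoform and no negative gene has any, so the planted truth
    satisfies the bag-label constraint the learner assumes.
    """
    rng = np.random.default_rng(config.seed)
    experiments = tuple(f"EXP{j:04d}" for j in range(config.n_experiments))
    sig_cols = np.sort(
        rng.choice(config.n_experiments, size=config.signature_dim, replace=False)
    )

    pos_genes = [f"GP{i:04d}" for i in range(config.n_pos_genes)]
    neg_genes = [f"GN{i:04d}" for i in range(config.n_neg_genes)]
    counts = _isoform_counts(
        rng, config.n_pos_genes + config.n_neg_genes, config.isoform_count_probs
    )

    bag_def: dict[str, tuple[str, ...]] = {}
    functional: set[str] = set()
    rows: list[np.ndarray] = []
    isoform_ids: list[str] = []
    for g_idx, gene in enumerate(pos_genes + neg_genes):
        k = int(counts[g_idx])
        isos = tuple(f"{gene}.{j + 1}" for j in range(k))
        bag_def[gene] = isos
        is_pos = g_idx < config.n_pos_genes
        if is_pos:
            if config.witness_fraction is None:
                n_wit = 1
            else:
                n_wit = max(1, int(np.ceil(config.witness_fraction * k)))
            wit_idx = set(rng.choice(k, size=min(n_wit, k), replace=False).tolist())
        else:
            wit_idx = set()
        for j, iso in enumerate(isos):
            baseline = rng.normal(config.baseline_mean, config.baseline_sd)
            row = baseline + rng.normal(0.0, config.noise_sd, size=config.n_experiments)
            if j in wit_idx:
                row[sig_cols] += config.effect_size
                functional.add(iso)
            rows.append(row)
            isoform_ids.append(iso)

    values = np.vstack(rows)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = MISSING_SENTINEL

    matrix = ExpressionMatrix(
        isoform_ids=tuple(isoform_ids),
        experiment_ids=experiments,
        values=values,
        space="log2",
    )
    bags = BagMap(bag_def)
    standard = TermGoldStandard(
        term_id=config.term_id,
        positives=frozenset(pos_genes),
        negatives=frozenset(neg_genes),
    )
    truth = GroundTruth(
        functional=frozenset(functional),
        signature_experiments=tuple(experiments[c] for c in sig_cols),
    )
    return matrix, bags, standard, truth


def recovery_balanced_accuracy(labeling, bags, standard, truth: GroundTruth) -> float:
    """Balanced accuracy of a labeling against the planted truth.

    Restricted to isoforms of positive genes (the only place hidden labels
    exist): mean of the recall on planted-functional isoforms (labelled POS)
    and the recall on planted-non-functional ones (labelled NEG).  With no
    non-functional isoforms present, the functional recall is returned.
    """
    from .containers import Label

    tp = fn = tn = fp = 0
    for g in standard.positives:
        for iso in bags[g]:
            if truth.is_functional(iso):
                tp += labeling[iso] is Label.POS
                fn += labeling[iso] is not Label.POS
            else:
                tn += labeling[iso] is Label.NEG
                fp += labeling[iso] is not Label.NEG
    tpr = tp / (tp + fn)
    if tn + fp == 0:
        return tpr
    return (tpr + tn / (tn + fp)) / 2


def generate_toy_ontology(
    n_terms: int, seed: int
) -> tuple[Ontology, list[tuple[str, str]]]:
    """Random is_a tree with gene annotations straddling the 20–300 window.

    Direct annotation counts are drawn so that, after descendant
    propagation, some terms fall below 20 positives, some inside [20, 300]
    and (for large enough trees) the root exceeds 300 — exercising the
    term-size selection bounds.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    terms = [f"GO:T{i:04d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = terms[int(rng.integers(0, i))]
        edges.append((terms[i], parent))
    ont = Ontology(term_ids=frozenset(terms), is_a_edges=tuple(edges))

    pool = [f"G{i:05d}" for i in range(60 * n_terms)]
    count_menu = np.array([3, 8, 25, 40, 80, 120])
    annotations: list[tuple[str, str]] = []
    for t_idx, term in enumerate(terms):
        # leaves stay small, deeper indices get varied counts
        n_ann = int(count_menu[int(rng.integers(0, len(count_menu)))])
        if t_idx == n_terms - 1:
            n_ann = 3  # guarantee at least one undersized term
        chosen = rng.choice(len(pool), size=n_ann, replace=False)
        annotations.extend((pool[g], term) for g in sorted(chosen.tolist()))
    return ont, annotations
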