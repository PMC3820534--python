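"""Quality filters and transforms for an already-quantified FPKM isoform table.

Quantification (alignment + FPKM estimation) happens upstream; this module
takes its tabular output and produces the log2 feature matrix the learner
consumes.  Three steps, in the order a pipeline applies them:

1. :func:`filter_experiments` — drop sequencing runs with too few reads or a
   poor mapping rate.
2. :func:`filter_genes` — drop genes detected in less than half of the
   surviving experiments (with all their isoform rows).
3. :func:`log_transform` — log2 of FPKM; unobserved (missing or zero FPKM)
   cells become a fixed low sentinel, −15 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import MISSING_SENTINEL, BagMap, ExpressionMatrix

__all__ = [
    "ExperimentMeta",
    "ExpressionMatrix",
    "filter_experiments",
    "filter_genes",
    "log_transform",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentMeta:
    """Sequencing-depth metadata for one RNA-seq run."""

    experiment_id: str
    total_reads: int
    mapped_fraction: float

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError(f"{self.experiment_id}: negative total_reads")
        if not 0.0 <= self.mapped_fraction <= 1.0:
            raise ValueError(
                f"{self.experiment_id}: mapped_fraction {self.mapped_fraction} not in [0,1]"
            )


def filter_experiments(
    metas: list[ExperimentMeta],
    min_reads: int = 10_000_000,
    min_mapped: float = 0.5,
) -> set[str]:
    """Return the ids of experiments with adequate depth and mapping rate.

    An experiment is removed when it has *less than* ``min_reads`` total reads
    or *less than* ``min_mapped`` of its reads mapped; boundary values are
    kept.
    """
    if not metas:
        raise ValueError("no experiment metadata given")
    seen: set[str] = set()
    for m in metas:
        if m.experiment_id in seen:
            raise ValueError(f"duplicate experiment id {m.experiment_id!r}")
        seen.add(m.experiment_id)
    kept = {
        m.experiment_id
        for m in metas
        if m.total_reads >= min_reads and m.mapped_fraction >= min_mapped
    }
    if not kept:
        logger.warning("experiment filter removed all %d experiments", len(metas))
    return kept


def filter_genes(
    raw: ExpressionMatrix,
    bags: BagMap,
    min_detect_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, BagMap]:
    """Drop genes detected in less than ``min_detect_fraction`` of experiments.

    A gene counts as detected in an experiment iff at least one of its
    isoforms has FPKM > 0 there (missing cells never count).  Surviving
    isoform rows keep their original order; the returned :class:`BagMap`
    covers exactly the surviving rows.
    """
    if raw.space != "fpkm":
        raise ValueError("gene detection filter expects an FPKM-space matrix")
    known = set(bags.isoforms)
    for iso in raw.isoform_ids:
        if iso not in known:
            raise ValueError(f"isoform row {iso!r} has no gene assignment")

    with np.errstate(invalid="ignore"):
        detected_row = raw.values > 0  # NaN compares False
    n_exp = raw.n_experiments
    keep_genes = []
    for gene in bags:
        rows = [raw.row_position(i) for i in bags[gene] if raw.has_isoform(i)]
        if not rows:
            continue
        detected = detected_row[rows].any(axis=0).sum()
        if detected >= min_detect_fraction * n_exp:
            keep_genes.append(gene)
    kept_gene_set = set(keep_genes)
    keep_isoforms = [i for i in raw.isoform_ids if bags.gene_of(i) in kept_gene_set]
    logger.info(
        "gene detection filter kept %d/%d genes (%d isoform rows)",
        len(keep_genes), len(bags), len(keep_isoforms),
    )
    sub_bags = BagMap(
        {g: tuple(i for i in bags[g] if raw.has_isoform(i)) for g in keep_genes}
    )
    return raw.subset_isoforms(keep_isoforms), sub_bags


def log_transform(
    raw: ExpressionMatrix, sentinel: float = MISSING_SENTINEL
) -> ExpressionMatrix:
    """log2-transform an FPKM matrix; missing and zero cells become ``sentinel``.

    Zero FPKM is indistinguishable from "not observed" in quantifier output,
    so zeros are floored to the same sentinel as missing cells.  Applying the
    transform to an already-log2 matrix raises (the space flag guards against
    double transforms).
    """
    if raw.space == "log2":
        raise ValueError("matrix is already in log2 space")
    vals = raw.values
    if (vals[np.isfinite(vals)] < 0).any():
        raise ValueError("negative FPKM value encountered")
    out = np.full_like(vals, sentinel)
    positive = np.isfinite(vals) & (vals > 0)
    out[positive] = np.log2(vals[positive])
    return ExpressionMatrix(
        isoform_ids=raw.isoform_ids,
        experiment_ids=raw.experiment_ids,
        values=out,
        space="log2",
        missing_sentinel=sentinel,
    )
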