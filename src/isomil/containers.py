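"""Shared in-memory containers: expression matrix, gene->isoform bags, instance labels.

The learning problem is bag-structured: a *gene* is a bag, its transcript
*isoforms* are the instances inside it.  Gene-level function labels are
observed; isoform-level labels are hidden and have to be inferred.
"""

from __future__ import annotations

import enum
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "BagMap",
    "Label",
    "InstanceLabeling",
]

#: sentinel written into log2-space matrices where expression was unobserved
MISSING_SENTINEL = -15.0


@dataclass
class ExpressionMatrix:
    """Isoform-by-experiment expression values.

    ``space`` tracks whether cells are raw FPKM (``"fpkm"``, missing cells are
    NaN) or log2-transformed (``"log2"``, every cell finite, missing cells hold
    ``missing_sentinel`` exactly).  Operations check the flag so a matrix can
    never be log-transformed twice.
    """

    isoform_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]
    values: np.ndarray
    space: str = "fpkm"
    missing_sentinel: float = MISSING_SENTINEL
    _row_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.isoform_ids = tuple(self.isoform_ids)
        self.experiment_ids = tuple(self.experiment_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.isoform_ids), len(self.experiment_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.isoform_ids)} isoforms x {len(self.experiment_ids)} experiments"
            )
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ValueError("duplicate isoform ids")
        if len(set(self.experiment_ids)) != len(self.experiment_ids):
            raise ValueError("duplicate experiment ids")
        if self.space not in ("fpkm", "log2"):
            raise ValueError(f"unknown expression space {self.space!r}")
        if self.space == "log2" and not np.all(np.isfinite(self.values)):
            raise ValueError("log2-space matrix must be fully finite")
        self._row_index = {iso: i for i, iso in enumerate(self.isoform_ids)}

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def row(self, isoform_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[isoform_id]]
        except KeyError:
            raise KeyError(f"isoform {isoform_id!r} not in matrix") from None

    def row_position(self, isoform_id: str) -> int:
        return self._row_index[isoform_id]

    def has_isoform(self, isoform_id: str) -> bool:
        return isoform_id in self._row_index

    def subset_isoforms(self, isoform_ids) -> "ExpressionMatrix":
        ids = tuple(isoform_ids)
        idx = [self.row_position(i) for i in ids]
        return ExpressionMatrix(
            isoform_ids=ids,
            experiment_ids=self.experiment_ids,
            values=self.values[idx],
            space=self.space,
            missing_sentinel=self.missing_sentinel,
        )

    def subset_experiments(self, experiment_ids) -> "ExpressionMatrix":
        ids = tuple(experiment_ids)
        col = {e: j for j, e in enumerate(self.experiment_ids)}
        idx = [col[e] for e in ids]
        return ExpressionMatrix(
            isoform_ids=self.isoform_ids,
            experiment_ids=ids,
            values=self.values[:, idx],
            space=self.space,
            missing_sentinel=self.missing_sentinel,
        )


class BagMap(Mapping[str, tuple[str, ...]]):
    """Partition of isoforms into genes (bags).

    Every isoform belongs to exactly one gene; every gene holds at least one
    isoform.  Iteration order is the insertion order of genes.
    """

    def __init__(self, mapping: Mapping[str, object]) -> None:
        self._bags: dict[str, tuple[str, ...]] = {}
        self._gene_of: dict[str, str] = {}
        for gene, isoforms in mapping.items():
            isos = tuple(isoforms)  # type: ignore[arg-type]
            if not isos:
                raise ValueError(f"gene {gene!r} has no isoforms")
            for iso in isos:
                if iso in self._gene_of:
                    raise ValueError(
                        f"isoform {iso!r} mapped to both {self._gene_of[iso]!r} and {gene!r}"
                    )
                self._gene_of[iso] = gene
            self._bags[gene] = isos

    def __getitem__(self, gene: str) -> tuple[str, ...]:
        return self._bags[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(self._bags)

    def __len__(self) -> int:
        return len(self._bags)

    def __repr__(self) -> str:
        return f"BagMap({len(self._bags)} genes, {len(self._gene_of)} isoforms)"

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self._bags)

    @property
    def isoforms(self) -> tuple[str, ...]:
        return tuple(self._gene_of)

    def gene_of(self, isoform_id: str) -> str:
        try:
            return self._gene_of[isoform_id]
        except KeyError:
            raise KeyError(f"isoform {isoform_id!r} has no gene assignment") from None

    def subset(self, genes) -> "BagMap":
        return BagMap({g: self._bags[g] for g in genes})


class Label(enum.Enum):
    """Working label of an isoform during MIL iterations."""

    POS = "POS"
    NEG = "NEG"
    NEUTRAL = "NEUTRAL"


class InstanceLabeling(Mapping[str, Label]):
    """Immutable isoform -> label assignment with a canonical hash.

    Two labelings compare equal iff they assign the same label to the same
    isoforms; the hash makes cycle detection in the MIL loop O(1) per check.
    """

    __slots__ = ("_labels", "_key")

    def __init__(self, labels: Mapping[str, Label]) -> None:
        self._labels = dict(labels)
        self._key = hash(frozenset((i, lab.value) for i, lab in self._labels.items()))

    def __getitem__(self, isoform_id: str) -> Label:
        return self._labels[isoform_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InstanceLabeling):
            return NotImplemented
        return self._labels == other._labels

    def __hash__(self) -> int:
        return self._key

    def with_label(self, label: Label) -> frozenset[str]:
        return frozenset(i for i, lab in self._labels.items() if lab is label)

    @property
    def n_pos(self) -> int:
        return sum(1 for lab in self._labels.values() if lab is Label.POS)
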