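"""Per-term gene-level gold standards from an ontology and gene annotations.

For each ontology term, positives are the genes annotated to the term or any
of its descendants (is_a transitive closure); every other gene in the
universe is a negative.  Terms are then restricted to a size window (by
default 20–300 positives) and optionally grouped into size quantiles for
stratified reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Ontology",
    "TermGoldStandard",
    "descendants",
    "build_term_standard",
    "select_terms",
    "group_terms_by_size",
]

logger = logging.getLogger(__name__)


@dataclass
class Ontology:
    """A DAG of terms connected by child -> parent is_a edges."""

    term_ids: frozenset[str]
    is_a_edges: tuple[tuple[str, str], ...]  # (child, parent)
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.term_ids = frozenset(self.term_ids)
        self.is_a_edges = tuple(tuple(e) for e in self.is_a_edges)
        g = nx.DiGraph()
        g.add_nodes_from(self.term_ids)
        for child, parent in self.is_a_edges:
            if child not in self.term_ids or parent not in self.term_ids:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown term")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a edges contain a cycle")
        self._graph = g

    def __contains__(self, term: str) -> bool:
        return term in self.term_ids


@dataclass(frozen=True)
class TermGoldStandard:
    """Positive/negative gene sets for one term; the observed bag labels."""

    term_id: str
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError(f"{self.term_id}: positives and negatives overlap")

    @property
    def universe(self) -> frozenset[str]:
        return self.positives | self.negatives

    @property
    def prior(self) -> float:
        """Background probability that a gene carries the term."""
        return len(self.positives) / len(self.universe)


def descendants(ont: Ontology, term: str) -> set[str]:
    """All terms below ``term`` in the is_a hierarchy, excluding ``term``."""
    if term not in ont:
        raise KeyError(f"unknown term {term!r}")
    # edges point child -> parent, so descendants are the graph-ancestors
    return set(nx.ancestors(ont._graph, term))


def build_term_standard(
    ont: Ontology,
    annotations: list[tuple[str, str]],
    term: str,
    universe: set[str],
) -> TermGoldStandard:
    """Build the gold standard for one term with descendant propagation.

    A gene is positive iff it is annotated to ``term`` or to any descendant
    of ``term``; all other universe genes are negatives.  Annotations of
    genes outside the universe are dropped (counted in a log summary).
    """
    if not universe:
        raise ValueError("empty gene universe")
    universe = set(universe)
    relevant = descendants(ont, term) | {term}
    positives: set[str] = set()
    dropped = 0
    for gene, t in annotations:
        if t not in relevant:
            continue
        if gene not in universe:
            dropped += 1
            continue
        positives.add(gene)
    if dropped:
        logger.info("%s: dropped %d annotations to genes outside the universe", term, dropped)
    return TermGoldStandard(
        term_id=term,
        positives=frozenset(positives),
        negatives=frozenset(universe - positives),
    )


def select_terms(
    standards: list[TermGoldStandard],
    min_pos: int = 20,
    max_pos: int = 300,
) -> list[TermGoldStandard]:
    """Keep terms whose positive-set size lies in [min_pos, max_pos] inclusive."""
    return [s for s in standards if min_pos <= len(s.positives) <= max_pos]


def group_terms_by_size(
    standards: list[TermGoldStandard], n_groups: int = 5
) -> list[tuple[tuple[int, int], list[TermGoldStandard]]]:
    """Split terms into ``n_groups`` size quantiles of near-equal cardinality.

    Terms are sorted by positive-set size (ties broken by term id for
    determinism) and cut into contiguous groups whose cardinalities differ by
    at most one.  Each group is returned with its (min_size, max_size) bounds.
    """
    if not standards:
        raise ValueError("no term standards to group")
    if n_groups > len(standards):
        raise ValueError(f"cannot split {len(standards)} terms into {n_groups} groups")
    ordered = sorted(standards, key=lambda s: (len(s.positives), s.term_id))
    n = len(ordered)
    base, extra = divmod(n, n_groups)
    groups: list[tuple[tuple[int, int], list[TermGoldStandard]]] = []
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < extra else 0)
        chunk = ordered[start : start + size]
        start += size
        bounds = (len(chunk[0].positives), len(chunk[-1].positives))
        groups.append((bounds, chunk))
    return groups
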