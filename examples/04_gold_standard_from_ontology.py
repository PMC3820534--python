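"""Build per-term gene gold standards from an ontology with propagation.

Genes annotated to a term *or any of its descendants* are positives; every
other gene in the universe is a negative.  Terms are then restricted to the
20-300 positive-gene window and grouped into size quantiles.
"""

from isomil import build_term_standard, group_terms_by_size, select_terms
from isomil.synthetic_data import generate_toy_ontology

ontology, annotations = generate_toy_ontology(n_terms=15, seed=4)
universe = {gene for gene, _ in annotations}
print(f"toy ontology: {len(ontology.term_ids)} terms, "
      f"{len(ontology.is_a_edges)} is_a edges, {len(universe)} genes")

standards = [
    build_term_standard(ontology, annotations, term, universe)
    for term in sorted(ontology.term_ids)
]
kept = select_terms(standards, min_pos=20, max_pos=300)
print(f"{len(kept)}/{len(standards)} terms have 20-300 positives after propagation")

for bounds, group in group_terms_by_size(kept, n_groups=min(3, len(kept))):
    sizes = [len(s.positives) for s in group]
    print(f"  size group {bounds}: {len(group)} terms, positives {sizes}")
# each size group holds roughly the same number of terms; performance is
# typically reported per group because small terms are harder to learn.
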