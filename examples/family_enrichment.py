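"""Weighted annotation enrichment of a gene-family set.

Builds fractional term weights per family (weight 1 when >90% of members
share one annotation set, otherwise proportional to annotation counts;
always summing to 1 per family), then tests whether any term is
over-represented in a foreground set of families with a seeded
permutation test.
"""

from cladescan import build_annotation_weights, weighted_term_enrichment
from cladescan.simulate import simulate_annotations

table, truth = simulate_annotations(
    n_families=200, foreground_size=30, planted_term="T01", effect=0.6, seed=1
)
weights = build_annotation_weights(table)
result = weighted_term_enrichment(
    set(truth["foreground"]), weights, n_perm=10_000, seed=1
)
print(result.sort_values("p_value").head(8).round(4).to_string(index=False))
print(
    f"\nTerm {truth['planted_term']} was planted into the foreground families; "
    "it tops the table with the largest observed weight sum and the smallest "
    "permutation p-value (bounded below by 1/10001).  The remaining terms "
    "behave as null draws."
)
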