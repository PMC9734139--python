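"""Flag genes with an elevated nonsynonymous rate on the focal stem.

Simulates 12 codon alignments (three with a 5x nonsynonymous rate shift on
the focal stem branch), derives per-branch dN from each gene's realised
substitution record, and applies the rapid-evolution decision: FDR-adjusted
p < 0.05 AND focal-stem dN greater than the sister lineage's.
"""

from cladescan import reg_analysis
from cladescan.simulate import simulate_codon_alignment

tables = []
for g in range(12):
    shifted = g < 3
    _, table = simulate_codon_alignment(
        n_codons=200, seed=100 + g, focal_multiplier=5.0 if shifted else 1.0,
        gene=f"gene{g + 1:02d}{'*' if shifted else ''}",
    )
    tables.append(table)

result = reg_analysis(tables, alpha=0.05)
print(result.round(4).to_string(index=False))
print(
    "\nGenes marked * carry the simulated 5x focal rate shift; is_reg=True "
    "rows are the ones the test recovers.  focal_dN is the nonsynonymous "
    "rate on the focal clade's stem branch, compared against all other "
    "branches (p_value) and against the sister lineage (the AND condition)."
)
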