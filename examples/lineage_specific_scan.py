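"""Detect a clade-wide amino-acid replacement and map it to its codon.

Simulates a protein alignment along the bundled 13-taxon tree with an
A->T replacement planted at residue 208 in every focal (seahorse-like)
tip, reconstructs ancestral states, and runs the full lineage-specific
mutation scan with its posterior (>= 0.95) and window-similarity
(mean >= 0.7, min >= 0.35) filters.
"""

from cladescan import scan_alignment
from cladescan.simulate import default_tree, simulate_alignment

tree = default_tree()
alignment, truth = simulate_alignment(tree, length=300, seed=1, planted=(208, "A", "T"))

calls = scan_alignment(alignment, tree, gene="tlx1-like")
print("column  focal  background  post_f  post_b  win_mean  verdict  cds_pos")
for c in calls:
    print(
        f"{c.column:6d}  {c.focal_residue:>5s}  {c.background_residue:>10s}"
        f"  {c.posterior_focal:6.3f}  {c.posterior_background:6.3f}"
        f"  {c.window_mean_similarity:8.3f}  {c.verdict:>7s}  {c.cds_position:7d}"
    )

planted = next(c for c in calls if c.column == truth["planted"]["column"])
print(
    f"\nThe planted replacement at residue {planted.column} "
    f"({planted.background_residue}->{planted.focal_residue}) passes all filters and "
    f"maps to coding-sequence position {planted.cds_position}: the first base of its "
    "codon, i.e. where the corresponding point mutation would sit in the gene."
)
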