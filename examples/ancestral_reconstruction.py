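"""Marginal ancestral reconstruction on a five-taxon alignment.

Shows the posterior state probabilities the downstream filters consume:
for each internal node of a small tree, the probability of each amino
acid at one alignment column, given all the tip data.
"""

from cladescan import Phylogeny, ProteinAlignment, SubstitutionModel, marginal_posteriors

tree = Phylogeny.from_newick("(((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05):0.05,e:0.1);")
alignment = ProteinAlignment(
    {"a": "MKT", "b": "MKT", "c": "MKA", "d": "MKA", "e": "MKA"}
)

model = SubstitutionModel.poisson()
post = marginal_posteriors(tree, alignment, model)

print("node   site  MAP  P(MAP)  P(A)    P(T)")
for node in post.node_labels:
    for site in (1, 2, 3):
        print(
            f"{node:>5s}  {site:4d}  {post.map_state(node, site):>3s}"
            f"  {post.map_probability(node, site):6.3f}"
            f"  {post.probability(node, site, 'A'):6.3f}"
            f"  {post.probability(node, site, 'T'):6.3f}"
        )

print(
    "\nColumns 1-2 are invariant, so every ancestor is reconstructed with "
    "probability near 1.  At column 3 the two-tip (a,b) clade carries T while "
    "the rest carry A: its MRCA is confidently T, the deeper nodes A — the "
    "posterior pattern that certifies a substitution on that clade's stem."
)
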