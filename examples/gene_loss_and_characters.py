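"""Call focal-clade gene losses and map binary traits onto the tree.

The loss rule: a family is lost when no focal species retains a copy but
at least one sister-lineage species does.  The character mapping places
minimum-change (parsimony) transitions of binary traits on branches and
reports branches where independent traits change together.
"""

import pandas as pd

from cladescan import call_gene_loss, cooccurrence_report
from cladescan.simulate import default_tree, simulate_orthogroups

tree = default_tree()
matrix, truth = simulate_orthogroups(tree, n_families=40, n_losses=4, seed=3)
lost = call_gene_loss(matrix, tree)
print(f"planted losses: {truth}")
print(f"called  losses: {sorted(lost)}")

chars = pd.DataFrame(
    {
        t: [
            "1" if t in tree.focal_clade else "0",  # focal replacement
            "1" if t in tree.focal_clade else "0",  # organ loss
            "1" if t == "outgroup" else "0",        # unrelated trait
        ]
        for t in tree.tip_labels
    },
    index=pd.Index(["tlx1_replacement", "asplenia", "unrelated"], name="character"),
)
table = cooccurrence_report(tree, chars)
print("\nbranch-by-character change incidence:")
print(table.to_string())
print(
    "\nThe loss calls match the planted truth exactly (the rule is "
    "deterministic).  Both focal-clade traits change on the same stem branch "
    "(n_changes = 2): the co-occurrence pattern that suggests correlated "
    "evolution, while the unrelated trait changes elsewhere."
)
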