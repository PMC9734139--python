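"""Parsimony mapping of binary characters onto the phylogeny.

Implements minimum-change (Fitch/Hartigan) reconstruction of binary traits
— e.g. the focal amino-acid replacement, brood-pouch development, spleen
presence and immune-repertoire simplification — and reports on which
branches independent characters change together.

The bottom-up pass uses Hartigan's counting form, which yields the exact
minimum change count on multifurcating trees as well as binary ones.
Missing states (``'?'``) enter as the full ambiguity set {0, 1}.  The
top-down pass resolves ambiguity by keeping the parent's state whenever it
is optimal (changes are thereby placed as late — tipward — as possible);
a change is recorded on a branch when the resolved states of its two
endpoints differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .phylo import Phylogeny

__all__ = ["FitchResult", "read_character_matrix", "fitch_parsimony", "cooccurrence_report"]

MISSING = "?"


@dataclass
class FitchResult:
    character: str
    changes: int
    branch_changes: dict[str, tuple[int, int]]  # branch (child label) -> (from, to)
    root_states: frozenset[int]


def read_character_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with a ``character`` column and one column per species
    (values 0, 1 or ?)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).set_index("character")
    bad = set(df.to_numpy().ravel()) - {"0", "1", MISSING}
    if bad:
        raise ValueError(f"illegal character states: {sorted(bad)}")
    return df


def _tip_state_set(value) -> frozenset[int]:
    v = str(value)
    if v == MISSING:
        return frozenset({0, 1})
    if v in {"0", "1"}:
        return frozenset({int(v)})
    raise ValueError(f"illegal state {value!r}")


def fitch_parsimony(tree: Phylogeny, states: Mapping[str, object], character: str = "") -> FitchResult:
    """Minimum-change reconstruction of one binary character.

    ``states`` maps every tip label to 0, 1 or '?'.  Returns the minimal
    number of changes, an explicit per-branch change placement, and the set
    of root states attaining the minimum.
    """
    missing_tips = set(tree.tip_labels) - set(map(str, states.keys()))
    if missing_tips:
        raise KeyError(f"tips without a state: {sorted(missing_tips)}")
    tip_sets = {t: _tip_state_set(states[t]) for t in tree.tip_labels}
    if all(s == frozenset({0, 1}) for s in tip_sets.values()):
        raise ValueError("character is '?' for every tip")

    optimal: dict[int, frozenset[int]] = {}
    changes = 0
    for idx in tree.postorder():
        node = tree.nodes[idx]
        if node.is_tip:
            optimal[idx] = tip_sets[node.label]
        else:
            count = {0: 0, 1: 0}
            for c in node.children:
                for s in optimal[c]:
                    count[s] += 1
            best = max(count.values())
            optimal[idx] = frozenset(s for s in (0, 1) if count[s] == best)
            changes += len(node.children) - best

    final: dict[int, int] = {}
    branch_changes: dict[str, tuple[int, int]] = {}
    for idx in tree.preorder():
        node = tree.nodes[idx]
        if node.parent is None:
            final[idx] = min(optimal[idx])
        else:
            p = final[node.parent]
            final[idx] = p if p in optimal[idx] else min(optimal[idx])
            if final[idx] != p:
                branch_changes[node.label] = (p, final[idx])
    assert len(branch_changes) == changes, "placement must realise the minimum"
    return FitchResult(
        character=character,
        changes=changes,
        branch_changes=branch_changes,
        root_states=optimal[tree.root],
    )


def cooccurrence_report(tree: Phylogeny, chars: pd.DataFrame) -> pd.DataFrame:
    """Branch-by-character incidence of parsimony changes.

    Rows are branches (named by child node) on which at least one character
    changes; one boolean column per character plus ``n_changes``.  Branches
    with ``n_changes >= 2`` are where characters co-occur.
    """
    if len(chars) < 2:
        raise ValueError("need at least two characters")
    results = [fitch_parsimony(tree, chars.loc[c].to_dict(), character=str(c)) for c in chars.index]
    branches = sorted({b for r in results for b in r.branch_changes})
    table = pd.DataFrame(
        {str(r.character): [b in r.branch_changes for b in branches] for r in results},
        index=pd.Index(branches, name="branch"),
    )
    table["n_changes"] = table.sum(axis=1)
    return table
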