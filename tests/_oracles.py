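"""Independent brute-force oracles used to check the fast implementations.

Everything here is written naively on purpose — exhaustive enumeration and
direct recounting — and shares no code with the package's algorithms.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive likelihood / marginal posteriors on small trees


def enumerate_likelihood(tree, column, model):
    """Σ over all internal-state assignments of the joint column probability.

    Returns (total likelihood, {internal node label: posterior vector}).
    Gapped tips contribute nothing (their emission sums to 1).
    """
    k = model.k
    internal = [i for i in range(tree.n_nodes) if not tree.nodes[i].is_tip]
    tips = [i for i in range(tree.n_nodes) if tree.nodes[i].is_tip]
    pmats = {
        i: model.transition_matrix(tree.nodes[i].length)
        for i in range(tree.n_nodes)
        if tree.nodes[i].parent is not None
    }
    state_index = {s: i for i, s in enumerate(model.states)}
    total = 0.0
    marg = {i: np.zeros(k) for i in internal}
    for assignment in product(range(k), repeat=len(internal)):
        states = dict(zip(internal, assignment))
        prob = model.frequencies[states[tree.root]]
        for i in internal:
            parent = tree.nodes[i].parent
            if parent is not None:
                prob *= pmats[i][states[parent], states[i]]
        for i in tips:
            ch = column.get(tree.nodes[i].label, "-")
            if ch in state_index:
                prob *= pmats[i][states[tree.nodes[i].parent], state_index[ch]]
        total += prob
        for i in internal:
            marg[i][states[i]] += prob
    posteriors = {tree.label_of(i): marg[i] / total for i in internal}
    return total, posteriors


# ---------------------------------------------------------------------------
# naive NG86 recount


_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def naive_codon_sites(codon):
    """(nonsyn, syn) site counts by explicit enumeration of the 9 changes."""
    syn = 0.0
    for pos, base in enumerate(codon):
        for other in "ACGT":
            if other != base:
                mutant = codon[:pos] + other + codon[pos + 1 :]
                if CODE[mutant] == CODE[codon]:
                    syn += 1.0 / 3.0
    return 3.0 - syn, syn


def naive_path_counts(codon_a, codon_b):
    """(Nd, Sd) averaged over stop-free shortest paths; None if all blocked."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    tallies = []
    for order in permutations(positions):
        cur = codon_a
        nd = sd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODE[nxt] == "*":
                ok = False
                break
            if CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            tallies.append((nd, sd))
    if not tallies:
        return None
    return (
        sum(t[0] for t in tallies) / len(tallies),
        sum(t[1] for t in tallies) / len(tallies),
    )


# ---------------------------------------------------------------------------
# exhaustive parsimony


def exhaustive_parsimony(tree, states):
    """Minimum change count over all internal (and '?') state assignments."""
    internal = [i for i in range(tree.n_nodes) if not tree.nodes[i].is_tip]
    free_tips = [
        i
        for i in range(tree.n_nodes)
        if tree.nodes[i].is_tip and str(states[tree.nodes[i].label]) == "?"
    ]
    fixed = {
        i: int(str(states[tree.nodes[i].label]))
        for i in range(tree.n_nodes)
        if tree.nodes[i].is_tip and str(states[tree.nodes[i].label]) != "?"
    }
    slots = internal + free_tips
    best = None
    for assignment in product((0, 1), repeat=len(slots)):
        full = dict(fixed)
        full.update(dict(zip(slots, assignment)))
        changes = sum(
            1
            for i in range(tree.n_nodes)
            if tree.nodes[i].parent is not None and full[i] != full[tree.nodes[i].parent]
        )
        if best is None or changes < best:
            best = changes
    return best


# ---------------------------------------------------------------------------
# random rooted trees


def random_tree_newick(n_tips, rng, max_branch=0.4):
    """Random binary rooted tree by sequential joins; labels t1..tn."""
    nodes = [f"t{i + 1}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la = rng.uniform(0.01, max_branch)
        lb = rng.uniform(0.01, max_branch)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return nodes[0] + ";"
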