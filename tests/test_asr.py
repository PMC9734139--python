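import math

import numpy as np
import pytest

from cladescan.alignments import AMINO_ACIDS, ProteinAlignment
from cladescan.asr import (
    AncestralPosterior,
    SubstitutionModel,
    empirical_frequencies,
    map_sequences,
    marginal_posteriors,
    site_log_likelihood,
)
from cladescan.phylo import Phylogeny
from cladescan.simulate import simulate_alignment

from _oracles import enumerate_likelihood, random_tree_newick


def test_zero_branch_identical_tips_log_likelihood():
    """With no time for substitutions, both tips 'A' force the root and the
    column likelihood is just the equilibrium frequency 1/20."""
    tree = Phylogeny.from_newick("(a:0,b:0);")
    model = SubstitutionModel.poisson()
    ll = site_log_likelihood(tree, {"a": "A", "b": "A"}, model)
    assert ll == pytest.approx(math.log(1 / 20), abs=1e-12)
    post = marginal_posteriors(tree, ProteinAlignment({"a": "A", "b": "A"}), model)
    root = tree.label_of(tree.root)
    assert post.probability(root, 1, "A") == pytest.approx(1.0, abs=1e-12)


def test_three_tip_likelihood_matches_enumeration():
    tree = Phylogeny.from_newick("((a:0.1,b:0.2):0.05,c:0.3);")
    model = SubstitutionModel.poisson()
    column = {"a": "A", "b": "C", "c": "A"}
    expected, _ = enumerate_likelihood(tree, column, model)
    assert site_log_likelihood(tree, column, model) == pytest.approx(
        math.log(expected), abs=1e-10
    )


def test_all_gap_column_contributes_zero():
    tree = Phylogeny.from_newick("(a:0.1,b:0.1);")
    model = SubstitutionModel.poisson()
    with pytest.warns(UserWarning, match="all-gap"):
        assert site_log_likelihood(tree, {"a": "-", "b": "-"}, model) == 0.0


def test_four_tip_posteriors_match_enumeration():
    tree = Phylogeny.from_newick("((a:0.12,b:0.3):0.08,(c:0.2,d:0.05):0.15);")
    model = SubstitutionModel.poisson()
    aln = ProteinAlignment({"a": "AC", "b": "AD", "c": "CC", "d": "AC"})
    post = marginal_posteriors(tree, aln, model)
    for site in (1, 2):
        column = {t: aln[t][site - 1] for t in aln.taxa}
        _, expected = enumerate_likelihood(tree, column, model)
        for node, vec in expected.items():
            assert np.allclose(post.vector(node, site), vec, atol=1e-10)


@pytest.mark.parametrize("n_tips", [3, 4, 5])
def test_random_tree_posteriors_match_enumeration(n_tips, rng):
    """Seeded random trees with gaps and non-uniform frequencies: the
    up-down recursion must agree with exhaustive enumeration."""
    freqs = rng.dirichlet(np.full(20, 5.0))
    model = SubstitutionModel.poisson(freqs)
    for _ in range(3):
        tree = Phylogeny.from_newick(random_tree_newick(n_tips, rng))
        residues = [AMINO_ACIDS[i] for i in rng.integers(20, size=n_tips)]
        if n_tips >= 4:
            residues[0] = "-"  # exercise missing data
        aln = ProteinAlignment(
            {f"t{i + 1}": residues[i] for i in range(n_tips)}
        )
        post = marginal_posteriors(tree, aln, model)
        column = {t: aln[t][0] for t in aln.taxa}
        _, expected = enumerate_likelihood(tree, column, model)
        for node, vec in expected.items():
            assert np.allclose(post.vector(node, 1), vec, atol=1e-10)


def test_long_branches_revert_to_equilibrium():
    tree = Phylogeny.from_newick("((a:1000,b:1000):1000,c:1000);")
    freqs = np.linspace(1, 2, 20)
    freqs = freqs / freqs.sum()
    model = SubstitutionModel.poisson(freqs)
    aln = ProteinAlignment({"a": "A", "b": "W", "c": "C"})
    post = marginal_posteriors(tree, aln, model)
    root = tree.label_of(tree.root)
    assert np.allclose(post.vector(root, 1), freqs, atol=1e-6)


def test_rerooting_leaves_likelihood_unchanged():
    """Sliding the root along a branch of a reversible model keeps the total
    likelihood (the pulley principle)."""
    model = SubstitutionModel.poisson()
    column = {"a": "A", "b": "C", "c": "D"}
    t1 = Phylogeny.from_newick("((a:0.1,b:0.2):0.15,c:0.3);")
    t2 = Phylogeny.from_newick("((a:0.1,b:0.2):0.05,c:0.4);")
    t3 = Phylogeny.from_newick("(a:0.05,(b:0.2,c:0.45):0.05);")
    lls = [site_log_likelihood(t, column, model) for t in (t1, t2, t3)]
    assert lls[0] == pytest.approx(lls[1], abs=1e-10)
    assert lls[0] == pytest.approx(lls[2], abs=1e-10)


def test_map_tie_breaks_alphabetically():
    vec = np.zeros((1, 1, 20))
    a, t = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("T")
    vec[0, 0, a] = vec[0, 0, t] = 0.5
    post = AncestralPosterior(
        states=AMINO_ACIDS, node_labels=["n"], probabilities=vec,
        unsupported=np.array([False]),
    )
    assert post.map_state("n", 1) == "A"


def test_all_gap_column_yields_unsupported_gap_state():
    tree = Phylogeny.from_newick("(a:0.1,b:0.1);")
    aln = ProteinAlignment({"a": "A-", "b": "C-"})
    post = marginal_posteriors(tree, aln, SubstitutionModel.poisson())
    root = tree.label_of(tree.root)
    assert post.map_state(root, 2) == "-"
    assert map_sequences(post)[root][1] == "-"


@pytest.mark.parametrize(
    "branch_length,floor",
    [
        # a substitution on either root-adjacent branch leaves a likelihood
        # near-tie for the root state, so ~half those sites are irreducible
        # MAP errors; the recovery floor tracks that bound per height
        (0.005, 0.99),
        (0.02, 0.95),
    ],
)
def test_root_states_recovered_on_long_simulated_alignments(branch_length, floor):
    """MAP root sequences recover the truth on long simulated alignments,
    up to the irreducible error set by root-adjacent substitutions."""
    from cladescan.simulate import default_tree

    tree = default_tree(equal_branch_length=branch_length)
    aln, truth = simulate_alignment(tree=tree, length=2000, seed=7)
    model = SubstitutionModel.poisson(empirical_frequencies(aln))
    post = marginal_posteriors(tree, aln, model)
    root = tree.label_of(tree.root)
    recovered = sum(
        post.map_state(root, i + 1) == truth["root_sequence"][i] for i in range(2000)
    )
    assert recovered / 2000 >= floor
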