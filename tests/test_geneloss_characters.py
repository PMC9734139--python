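import numpy as np
import pandas as pd
import pytest

from cladescan.characters import cooccurrence_report, fitch_parsimony
from cladescan.geneloss import call_gene_loss
from cladescan.phylo import Phylogeny
from cladescan.simulate import default_tree, simulate_orthogroups

from _oracles import exhaustive_parsimony, random_tree_newick


@pytest.fixture
def loss_tree():
    return Phylogeny.from_newick(
        "(((f1:1,f2:1):1,(s1:1,s2:1):1):1,(o1:1,o2:1):1);", focal=["f1", "f2"]
    )


def _matrix(rows, species):
    return pd.DataFrame(rows, columns=species).set_index(pd.Index([f"fam{i}" for i in range(len(rows))], name="family"))


class TestGeneLoss:
    species = ["f1", "f2", "s1", "s2", "o1", "o2"]

    def test_absent_in_focal_present_in_sister_is_lost(self, loss_tree):
        m = _matrix([[0, 0, 1, 2, 0, 0]], self.species)
        assert call_gene_loss(m, loss_tree) == ["fam0"]

    def test_any_focal_copy_blocks_loss(self, loss_tree):
        m = _matrix([[0, 1, 1, 1, 0, 0]], self.species)
        assert call_gene_loss(m, loss_tree) == []

    def test_presence_only_outside_sister_is_not_loss(self, loss_tree):
        """Background presence does not substitute for the sister lineage:
        without a sister homolog the ancestral presence is uncertified."""
        m = _matrix([[0, 0, 0, 0, 3, 0]], self.species)
        assert call_gene_loss(m, loss_tree) == []

    def test_all_zero_family_excluded(self, loss_tree):
        m = _matrix([[0, 0, 0, 0, 0, 0], [0, 0, 1, 0, 0, 0]], self.species)
        assert call_gene_loss(m, loss_tree) == ["fam1"]

    def test_require_all_sister_flag(self, loss_tree):
        m = _matrix([[0, 0, 1, 0, 0, 0]], self.species)
        assert call_gene_loss(m, loss_tree) == ["fam0"]
        assert call_gene_loss(m, loss_tree, require_all_sister=True) == []

    def test_invariant_to_column_order(self, loss_tree):
        m = _matrix([[0, 0, 1, 2, 1, 1], [1, 0, 1, 1, 0, 0]], self.species)
        shuffled = m[list(reversed(self.species))]
        assert call_gene_loss(m, loss_tree) == call_gene_loss(shuffled, loss_tree)

    def test_adding_focal_copy_only_removes_calls(self, loss_tree):
        m = _matrix([[0, 0, 1, 2, 1, 1]], self.species)
        assert call_gene_loss(m, loss_tree) == ["fam0"]
        m2 = m.copy()
        m2.loc["fam0", "f1"] = 1
        assert call_gene_loss(m2, loss_tree) == []

    def test_planted_losses_recovered_exactly(self):
        """Deterministic rule: sensitivity and specificity both 1 on the
        generator's planted-loss matrices."""
        tree = default_tree()
        matrix, lost_truth = simulate_orthogroups(tree, n_families=200, n_losses=25, seed=5)
        called = call_gene_loss(matrix, tree)
        assert sorted(called) == lost_truth


class TestFitchParsimony:
    def test_two_tip_conflict(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        res = fitch_parsimony(tree, {"a": 0, "b": 1})
        assert res.changes == 1
        assert res.root_states == {0, 1}

    def test_constant_character_no_changes(self):
        tree = Phylogeny.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        res = fitch_parsimony(tree, {t: 1 for t in "abcd"})
        assert res.changes == 0
        assert res.branch_changes == {}

    def test_two_independent_gains_placed_on_clade_stems(self):
        tree = Phylogeny.from_newick(
            "(((a:1,b:1)A:1,(c:1,d:1)B:1)AB:1,((e:1,f:1)C:1,(g:1,h:1)D:1)CD:1);"
        )
        states = {"a": 1, "b": 1, "c": 0, "d": 0, "e": 1, "f": 1, "g": 0, "h": 0}
        res = fitch_parsimony(tree, states)
        assert res.changes == 2
        assert set(res.branch_changes) == {"A", "C"}
        assert all(chg == (0, 1) for chg in res.branch_changes.values())

    def test_missing_states_resolve_without_extra_changes(self):
        tree = Phylogeny.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        res = fitch_parsimony(tree, {"a": 1, "b": "?", "c": 0, "d": 0})
        assert res.changes == 1

    def test_all_missing_rejected(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="every tip"):
            fitch_parsimony(tree, {"a": "?", "b": "?"})

    def test_matches_exhaustive_minimum_on_random_trees(self, rng):
        """50 seeded random characters on trees of up to 8 tips: the change
        count must equal the exhaustive-search minimum, and the explicit
        placement must realise it."""
        for rep in range(50):
            n_tips = int(rng.integers(4, 9))
            tree = Phylogeny.from_newick(random_tree_newick(n_tips, rng))
            states = {
                f"t{i + 1}": rng.choice(["0", "1", "1", "0", "?"]) for i in range(n_tips)
            }
            if all(v == "?" for v in states.values()):
                states["t1"] = "1"
            res = fitch_parsimony(tree, states)
            assert res.changes == exhaustive_parsimony(tree, states)
            assert len(res.branch_changes) == res.changes


class TestCooccurrence:
    def test_characters_changing_on_same_stem_cooccur(self, study_tree):
        chars = pd.DataFrame(
            {
                t: [
                    "1" if t in study_tree.focal_clade else "0",
                    "1" if t in study_tree.focal_clade else "0",
                    "1" if t == "outgroup" else "0",
                ]
                for t in study_tree.tip_labels
            },
            index=pd.Index(["tlx1_replacement", "asplenia", "unrelated"], name="character"),
        )
        table = cooccurrence_report(study_tree, chars)
        stem = study_tree.label_of(study_tree.focal_stem)
        assert table.loc[stem, "tlx1_replacement"]
        assert table.loc[stem, "asplenia"]
        assert table.loc[stem, "n_changes"] == 2
        assert not table.loc[stem, "unrelated"]

    def test_disjoint_changes_do_not_cooccur(self, study_tree):
        chars = pd.DataFrame(
            {
                t: [
                    "1" if t in study_tree.focal_clade else "0",
                    "1" if t == "outgroup" else "0",
                ]
                for t in study_tree.tip_labels
            },
            index=pd.Index(["c1", "c2"], name="character"),
        )
        table = cooccurrence_report(study_tree, chars)
        assert (table["n_changes"] < 2).all()

    def test_two_clade_cooccurrence_mirrors_convergent_traits(self):
        """Twenty-taxon tree with two derived clades: asplenia-like and
        pouch-like characters change together on both clade stems."""
        clade_a = [f"h{i}" for i in range(1, 5)]
        clade_b = [f"s{i}" for i in range(1, 5)]
        others = [f"o{i}" for i in range(1, 13)]
        # non-derived lineages interleave between the two derived clades, so
        # parsimony is forced to place two independent gains on their stems
        newick = (
            "((((" + ",".join(f"{t}:1" for t in clade_a) + ")HIP:1,("
            + ",".join(f"{t}:1" for t in others[:3]) + "):1):1,(("
            + ",".join(f"{t}:1" for t in clade_b) + ")SYN:1,("
            + ",".join(f"{t}:1" for t in others[3:6]) + "):1):1):1,("
            + ",".join(f"{t}:1" for t in others[6:]) + "):1);"
        )
        tree = Phylogeny.from_newick(newick)
        derived = set(clade_a) | set(clade_b)
        chars = pd.DataFrame(
            {t: ["1" if t in derived else "0"] * 2 for t in tree.tip_labels},
            index=pd.Index(["asplenia", "closed_pouch"], name="character"),
        )
        table = cooccurrence_report(tree, chars)
        assert set(table.index[table["n_changes"] >= 2]) == {"HIP", "SYN"}
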