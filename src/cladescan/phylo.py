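"""Rooted phylogenies with a designated focal clade.

The tree model is deliberately small: labelled nodes with parent links and
non-negative branch lengths, plus the focal/background/sister partition of
the tips that every downstream scan (lineage-specific mutations, gene loss,
branch-rate tests) relies on.  The *focal clade* is the set of tips under
study (e.g. the seahorses); the *sister lineage* is the tip set of the other
child of the focal MRCA's parent; everything outside the focal clade is
*background*.

Newick parsing is delegated to :mod:`dendropy`; the parsed tree is converted
into this module's array-backed representation, which is what the pruning
and parsimony algorithms traverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = ["CladeError", "Phylogeny", "read_tree"]


class CladeError(ValueError):
    """Raised when the requested focal tip set is not monophyletic."""


@dataclass
class _Node:
    label: str
    parent: int | None
    length: float
    children: list[int] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """A rooted tree with unique node labels and a focal-clade annotation.

    Nodes are stored in a flat list indexed by integer id; ``root`` is always
    id 0.  ``focal_clade`` and ``sister_lineage`` are tip-label sets; both are
    empty when no focal clade was requested.
    """

    nodes: list[_Node]
    focal_clade: frozenset[str] = frozenset()
    sister_lineage: frozenset[str] = frozenset()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, focal: Iterable[str] | None = None) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
            case_sensitive_taxon_labels=True,
        )
        nodes: list[_Node] = []
        index: dict[int, int] = {}
        counter = 0
        for dnode in tree.preorder_node_iter():
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            else:
                counter += 1
                label = f"node{counter}"
            parent = index[id(dnode.parent_node)] if dnode.parent_node is not None else None
            length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
            if length < 0:
                raise ValueError(f"negative branch length on {label!r}")
            idx = len(nodes)
            index[id(dnode)] = idx
            nodes.append(_Node(label=label, parent=parent, length=length))
            if parent is not None:
                nodes[parent].children.append(idx)
        labels = [n.label for n in nodes]
        if len(set(labels)) != len(labels):
            seen: set[str] = set()
            dup = next(l for l in labels if l in seen or seen.add(l))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate node label {dup!r}")
        phy = cls(nodes=nodes)
        if focal is not None:
            phy = phy.with_focal_clade(focal)
        return phy

    def with_focal_clade(self, focal: Iterable[str]) -> "Phylogeny":
        focal = frozenset(focal)
        tipset = set(self.tip_labels)
        unknown = focal - tipset
        if unknown:
            raise KeyError(f"focal tips not in tree: {sorted(unknown)}")
        if not focal:
            raise ValueError("focal clade must be non-empty")
        mrca = self.mrca(focal)
        under = set(self.tip_labels_under(mrca))
        intruders = under - focal
        if intruders:
            raise CladeError(
                f"focal set is not monophyletic; MRCA also contains {sorted(intruders)}"
            )
        sister: frozenset[str] = frozenset()
        parent = self.nodes[mrca].parent
        if parent is not None:
            sister_tips: set[str] = set()
            for child in self.nodes[parent].children:
                if child != mrca:
                    sister_tips.update(self.tip_labels_under(child))
            sister = frozenset(sister_tips)
        return Phylogeny(nodes=self.nodes, focal_clade=focal, sister_lineage=sister)

    # -- basic queries ---------------------------------------------------
    @property
    def root(self) -> int:
        return 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.nodes if n.is_tip]

    @property
    def background(self) -> frozenset[str]:
        return frozenset(self.tip_labels) - self.focal_clade

    def label_of(self, idx: int) -> str:
        return self.nodes[idx].label

    def index_of(self, label: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.label == label:
                return i
        raise KeyError(label)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            idx = stack.pop()
            order.append(idx)
            stack.extend(self.nodes[idx].children)
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def tip_labels_under(self, idx: int) -> list[str]:
        out: list[str] = []
        stack = [idx]
        while stack:
            i = stack.pop()
            node = self.nodes[i]
            if node.is_tip:
                out.append(node.label)
            else:
                stack.extend(node.children)
        return out

    def mrca(self, labels: Iterable[str]) -> int:
        targets = set(labels)
        want = {self.index_of(l) for l in targets}
        # count, per node, how many target tips its subtree holds
        counts = [0] * self.n_nodes
        for idx in self.postorder():
            node = self.nodes[idx]
            if node.is_tip:
                counts[idx] = 1 if idx in want else 0
            else:
                counts[idx] = sum(counts[c] for c in node.children)
        n = len(want)
        for idx in self.postorder():
            if counts[idx] == n:
                return idx
        raise KeyError(f"tips not found: {sorted(targets)}")

    @property
    def focal_mrca(self) -> int:
        if not self.focal_clade:
            raise ValueError("no focal clade set")
        return self.mrca(self.focal_clade)

    def branches(self) -> list[int]:
        """Every non-root node id; a node identifies the branch above it."""
        return [i for i in range(self.n_nodes) if i != self.root]

    @property
    def focal_stem(self) -> int:
        """Branch id (child-node id) of the focal clade's stem branch."""
        return self.focal_mrca

    @property
    def sister_stem(self) -> int:
        if not self.sister_lineage:
            raise ValueError("focal MRCA is the root; no sister lineage")
        return self.mrca(self.sister_lineage)

    def to_newick(self) -> str:
        def render(idx: int) -> str:
            node = self.nodes[idx]
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")" + node.label
            if node.parent is None:
                return core
            return f"{core}:{node.length:g}"

        return render(self.root) + ";"


def read_tree(path: str | Path, focal: Sequence[str] | None = None) -> Phylogeny:
    """Read a rooted Newick tree, optionally annotating a focal clade.

    The focal set must be monophyletic; its sister lineage is derived as the
    tip set of the other child(ren) of the focal MRCA's parent.
    """
    text = Path(path).read_text()
    return Phylogeny.from_newick(text, focal=focal)
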