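"""Marginal ancestral state reconstruction by the pruning algorithm.

For every internal node and alignment column the reconstruction gives the
posterior probability of each state given the observed column,

    P(node = a | column)  ∝  inside_a(node) · outside_a(node),

computed by the standard up–down (inside–outside) recursion over the rooted
tree under a time-reversible substitution model.  These posteriors are what
the lineage-specific-mutation filter thresholds at 0.95.

The machinery is alphabet-generic: the same code reconstructs amino acids
under a Poisson(+F) model and nucleotides under Jukes–Cantor, which is how
ancestral codon sequences for branch-wise dN are obtained.

Numerical notes
---------------
* Gaps are missing data: a gapped tip contributes an all-ones partial
  likelihood, never a 21st state.
* Partial likelihoods are rescaled per node and site (max-norm), with the
  log-scalers accumulated, so long trees cannot underflow.
* P(t) = exp(Qt) is computed once per distinct branch length through the
  symmetric eigendecomposition of the reversible generator and cached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alignments import AMINO_ACIDS, GAP, NUCLEOTIDES, ProteinAlignment
from .phylo import Phylogeny

__all__ = [
    "SubstitutionModel",
    "AncestralPosterior",
    "empirical_frequencies",
    "site_log_likelihood",
    "marginal_posteriors",
    "map_sequences",
]


@dataclass
class SubstitutionModel:
    """Reversible substitution model Q_ij = s_ij π_j, scaled to rate 1.

    ``exchangeability`` is a symmetric non-negative matrix with an ignored
    diagonal; ``frequencies`` the equilibrium distribution π.  The generator
    is normalised so one unit of branch length equals one expected
    substitution per site at equilibrium.
    """

    states: str
    exchangeability: np.ndarray
    frequencies: np.ndarray
    _cache: dict[float, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        k = len(self.states)
        self.exchangeability = np.asarray(self.exchangeability, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeability.shape != (k, k):
            raise ValueError("exchangeability shape mismatch")
        if not np.allclose(self.exchangeability, self.exchangeability.T):
            raise ValueError("exchangeability must be symmetric")
        if np.any(self.exchangeability < 0) or np.any(self.frequencies <= 0):
            raise ValueError("exchangeabilities must be >= 0 and frequencies > 0")
        self.frequencies = self.frequencies / self.frequencies.sum()
        q = self.exchangeability * self.frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -float(np.dot(self.frequencies, np.diag(q)))
        if rate <= 0:
            raise ValueError("degenerate model: zero total rate")
        self.q = q / rate
        # symmetric form for the eigendecomposition
        sqrt_pi = np.sqrt(self.frequencies)
        b = (sqrt_pi[:, None] * self.q) / sqrt_pi[None, :]
        self._eigval, self._eigvec = np.linalg.eigh((b + b.T) / 2.0)
        self._left = self._eigvec / sqrt_pi[:, None]
        self._right = self._eigvec * sqrt_pi[:, None]

    @property
    def k(self) -> int:
        return len(self.states)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Row-stochastic P(t) = exp(Qt), cached per branch length."""
        if t < 0:
            raise ValueError("negative branch length")
        p = self._cache.get(t)
        if p is None:
            p = (self._left * np.exp(self._eigval * t)) @ self._right.T
            np.clip(p, 0.0, None, out=p)
            p /= p.sum(axis=1, keepdims=True)
            self._cache[t] = p
        return p

    # -- constructors ----------------------------------------------------
    @classmethod
    def poisson(cls, frequencies: np.ndarray | None = None, states: str = AMINO_ACIDS) -> "SubstitutionModel":
        """Uniform exchangeabilities; Poisson+F when frequencies are given."""
        k = len(states)
        if frequencies is None:
            frequencies = np.full(k, 1.0 / k)
        return cls(states=states, exchangeability=np.ones((k, k)), frequencies=np.asarray(frequencies))

    @classmethod
    def jc_nucleotide(cls) -> "SubstitutionModel":
        return cls.poisson(states=NUCLEOTIDES)


def empirical_frequencies(alignment, states: str = AMINO_ACIDS, pseudocount: float = 1.0) -> np.ndarray:
    """State frequencies across an alignment with an additive pseudocount."""
    counts = np.full(len(states), pseudocount, dtype=float)
    idx = {s: i for i, s in enumerate(states)}
    for seq in alignment.sequences.values():
        for ch in seq:
            if ch != GAP:
                counts[idx[ch]] += 1
    return counts / counts.sum()


def _tip_partials(tree: Phylogeny, columns: np.ndarray, model: SubstitutionModel) -> np.ndarray:
    """Partial-likelihood array, shape (n_nodes, n_sites, k); tips filled."""
    n_sites = columns.shape[1]
    partial = np.ones((tree.n_nodes, n_sites, model.k))
    for i, node in enumerate(tree.nodes):
        if node.is_tip:
            states = columns[_tip_row(tree, node.label)]
            observed = states >= 0
            partial[i, observed, :] = 0.0
            partial[i, observed, states[observed]] = 1.0
    return partial


def _tip_row(tree: Phylogeny, label: str) -> int:
    return tree.tip_labels.index(label)


def _encode(tree: Phylogeny, alignment, model: SubstitutionModel) -> np.ndarray:
    """Columns as int codes per tip row; gap/missing = -1."""
    tips = tree.tip_labels
    extra = set(alignment.taxa) - set(tips)
    if extra:
        raise KeyError(f"alignment taxa absent from tree: {sorted(extra)}")
    idx = {s: i for i, s in enumerate(model.states)}
    codes = np.full((len(tips), alignment.length), -1, dtype=int)
    for row, taxon in enumerate(tips):
        if taxon in alignment.sequences:
            seq = alignment.sequences[taxon]
            codes[row] = [idx.get(ch, -1) for ch in seq]
    return codes


def _upward(tree: Phylogeny, columns: np.ndarray, model: SubstitutionModel):
    """Inside pass; returns (partials, per-site log scalers, messages).

    ``messages[i]`` is the child-to-parent message of node i:
    M_i(a) = Σ_b P_i(a,b) L_i(b), where P_i is the transition matrix of the
    branch above node i.
    """
    partial = _tip_partials(tree, columns, model)
    n_sites = columns.shape[1]
    log_scale = np.zeros(n_sites)
    messages: list[np.ndarray | None] = [None] * tree.n_nodes
    for i in tree.postorder():
        node = tree.nodes[i]
        if not node.is_tip:
            for c in node.children:
                partial[i] *= messages[c]
            peak = partial[i].max(axis=1)
            safe = peak > 0
            if not np.all(safe):
                raise FloatingPointError("zero column likelihood")
            partial[i] /= peak[:, None]
            log_scale += np.log(peak)
        if node.parent is not None:
            p = model.transition_matrix(node.length)
            messages[i] = partial[i] @ p.T
    return partial, log_scale, messages


def site_log_likelihood(tree: Phylogeny, column: Mapping[str, str], model: SubstitutionModel) -> float:
    """Log-likelihood of one alignment column under the model.

    An all-gap column carries no information and contributes 0 (with a
    warning).
    """
    idx = {s: i for i, s in enumerate(model.states)}
    codes = np.full((len(tree.tip_labels), 1), -1, dtype=int)
    for row, taxon in enumerate(tree.tip_labels):
        if taxon in column:
            codes[row, 0] = idx.get(column[taxon], -1)
    if np.all(codes < 0):
        warnings.warn("all-gap column: log-likelihood contribution is 0")
        return 0.0
    partial, log_scale, _ = _upward(tree, codes, model)
    like = float(partial[tree.root, 0] @ model.frequencies)
    return float(np.log(like) + log_scale[0])


@dataclass
class AncestralPosterior:
    """Per-(internal node, site) posterior distributions over states.

    ``probabilities`` has shape (n_internal, n_sites, k); rows sum to 1.
    All-gap columns are flagged in ``unsupported`` and given the MAP state
    ``'-'``.
    """

    states: str
    node_labels: list[str]
    probabilities: np.ndarray
    unsupported: np.ndarray  # bool per site: column was entirely gaps

    def __post_init__(self) -> None:
        self._row = {label: i for i, label in enumerate(self.node_labels)}

    @property
    def n_sites(self) -> int:
        return self.probabilities.shape[1]

    def vector(self, node: str, site: int) -> np.ndarray:
        """Posterior state vector at 1-based ``site``."""
        return self.probabilities[self._row[node], site - 1]

    def probability(self, node: str, site: int, state: str) -> float:
        return float(self.vector(node, site)[self.states.index(state)])

    def map_state(self, node: str, site: int) -> str:
        if self.unsupported[site - 1]:
            return GAP
        v = self.vector(node, site)
        # ties broken by fixed alphabetical state order (argmax takes first)
        return self.states[int(np.argmax(v))]

    def map_probability(self, node: str, site: int) -> float:
        return float(self.vector(node, site).max())

    def to_frame(self):
        import pandas as pd

        rows = []
        for node in self.node_labels:
            for site in range(1, self.n_sites + 1):
                rows.append(
                    {
                        "node": node,
                        "site": site,
                        "map_state": self.map_state(node, site),
                        "map_prob": self.map_probability(node, site),
                    }
                )
        return pd.DataFrame(rows)


def marginal_posteriors(tree: Phylogeny, alignment, model: SubstitutionModel) -> AncestralPosterior:
    """Posterior state distributions for every internal node and column.

    Implements the inside–outside recursion: the inside (upward) pass gives
    L_i(a) = P(data below i | i = a); the outside (downward) pass propagates
    O_i(a) = P(data elsewhere, i = a); their normalised product is the
    marginal posterior.
    """
    columns = _encode(tree, alignment, model)
    all_gap = np.all(columns < 0, axis=0)
    partial, _, messages = _upward(tree, columns, model)
    n_sites = columns.shape[1]

    outside = np.zeros_like(partial)
    outside[tree.root] = model.frequencies[None, :]
    for u in tree.preorder():
        node = tree.nodes[u]
        if node.is_tip:
            continue
        for v in node.children:
            other = outside[u].copy()
            for s in node.children:
                if s != v:
                    other *= messages[s]
            p = model.transition_matrix(tree.nodes[v].length)
            outside[v] = other @ p
    internal = [i for i in range(tree.n_nodes) if not tree.nodes[i].is_tip]
    probs = np.empty((len(internal), n_sites, model.k))
    for row, i in enumerate(internal):
        joint = outside[i] * partial[i]
        total = joint.sum(axis=1, keepdims=True)
        if np.any(~np.isfinite(total)) or np.any(total <= 0):
            raise FloatingPointError("non-finite posterior normaliser")
        probs[row] = joint / total
    return AncestralPosterior(
        states=model.states,
        node_labels=[tree.label_of(i) for i in internal],
        probabilities=probs,
        unsupported=all_gap,
    )


def map_sequences(post: AncestralPosterior) -> dict[str, str]:
    """Maximum-a-posteriori sequence per internal node.

    Ties take the alphabetically first state; all-gap columns yield ``'-'``.
    """
    out = {}
    for node in post.node_labels:
        out[node] = "".join(post.map_state(node, s) for s in range(1, post.n_sites + 1))
    return out
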