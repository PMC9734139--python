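"""Seeded generators for every input the pipeline consumes.

Each generator emulates one of the study-style inputs — protein alignments
evolved along the species tree with an optional planted clade-wide
substitution and garbled windows, codon alignments with an elevated
nonsynonymous rate on the focal stem, orthogroup copy-number matrices with
planted losses, family annotation tables with a planted enriched term, and
Poisson-mixture k-mer depth histograms — and returns the dataset together
with a machine-readable truth table, so every stage of the pipeline can be
exercised and scored without external downloads.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; the same seed reproduces outputs exactly.

The default tree mirrors the study's setting: 13 tips with a four-tip
focal clade (the "seahorses"), a three-tip sister lineage (the
"pipefishes") and six further background fishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignments import AMINO_ACIDS, CodonAlignment, GAP, ProteinAlignment
from .asr import SubstitutionModel
from .codon import GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from .genomesize import KmerHistogram
from .phylo import Phylogeny
from .rates import BranchRateTable

__all__ = [
    "DEFAULT_TREE_NEWICK",
    "DEFAULT_FOCAL_CLADE",
    "default_tree",
    "simulate_alignment",
    "simulate_codon_alignment",
    "simulate_orthogroups",
    "simulate_annotations",
    "simulate_histogram",
]

DEFAULT_FOCAL_CLADE = ("seahorse1", "seahorse2", "seahorse3", "seahorse4")
DEFAULT_SISTER = ("pipefish1", "pipefish2", "pipefish3")

DEFAULT_TREE_NEWICK = (
    "((((((seahorse1:0.02,seahorse2:0.02):0.02,(seahorse3:0.02,seahorse4:0.02):0.02):0.03,"
    "(pipefish1:0.03,(pipefish2:0.02,pipefish3:0.02):0.02):0.02):0.03,"
    "(seadragon1:0.04,seadragon2:0.04):0.03):0.03,"
    "(stickleback:0.05,(medaka:0.04,zebrafish:0.04):0.02):0.03):0.02,"
    "outgroup:0.08);"
)


def default_tree(equal_branch_length: float | None = None) -> Phylogeny:
    """The bundled 13-taxon tree with its focal clade annotated.

    ``equal_branch_length`` overrides every branch length with one value —
    the configuration used for null-calibration simulations, where the
    branches must be exchangeable.
    """
    tree = Phylogeny.from_newick(DEFAULT_TREE_NEWICK, focal=DEFAULT_FOCAL_CLADE)
    if equal_branch_length is not None:
        for node in tree.nodes:
            if node.parent is not None:
                node.length = float(equal_branch_length)
    return tree


# ---------------------------------------------------------------------------
# protein alignments with a planted lineage-specific substitution


def _evolve_states(tree: Phylogeny, model: SubstitutionModel, n_sites: int, rng) -> dict[int, np.ndarray]:
    """Site-independent evolution along the tree; integer state arrays."""
    states: dict[int, np.ndarray] = {}
    k = model.k
    for idx in tree.preorder():
        node = tree.nodes[idx]
        if node.parent is None:
            states[idx] = rng.choice(k, size=n_sites, p=model.frequencies)
        else:
            p = model.transition_matrix(node.length)
            parent = states[node.parent]
            u = rng.random(n_sites)
            cdf = np.cumsum(p, axis=1)
            states[idx] = (u[:, None] > cdf[parent]).sum(axis=1)
    return states


def simulate_alignment(
    tree: Phylogeny | None = None,
    length: int = 300,
    seed: int = 0,
    model: SubstitutionModel | None = None,
    planted: tuple[int, str, str] | None = None,
    garble: tuple[list[int], list[str], float] | None = None,
) -> tuple[ProteinAlignment, dict]:
    """Protein alignment evolved along the tree, with optional planting.

    ``planted = (column, from_residue, to_residue)`` forces the clade-wide
    substitution pattern at a 1-based column: every focal tip carries the
    derived residue, every background tip the ancestral one (the site is
    frozen in both partitions).  ``garble = (columns, taxa, intensity)``
    corrupts alignment quality by replacing each listed cell with a
    uniformly random residue with probability ``intensity``.

    Returns the alignment and a truth dict with the planted site and the
    true root sequence.
    """
    if tree is None:
        tree = default_tree()
    if model is None:
        model = SubstitutionModel.poisson()
    rng = np.random.default_rng(seed)
    states = _evolve_states(tree, model, length, rng)
    seqs = {
        tree.label_of(i): "".join(model.states[s] for s in states[i])
        for i in range(tree.n_nodes)
        if tree.nodes[i].is_tip
    }
    truth: dict = {
        "root_sequence": "".join(model.states[s] for s in states[tree.root]),
        "planted": None,
        "garbled_columns": [],
    }
    if planted is not None:
        column, from_res, to_res = planted
        if from_res == to_res:
            raise ValueError("planted residue equals the ancestral residue")
        if not 1 <= column <= length:
            raise ValueError(f"planted column {column} outside 1..{length}")
        for taxon in seqs:
            res = to_res if taxon in tree.focal_clade else from_res
            seqs[taxon] = seqs[taxon][: column - 1] + res + seqs[taxon][column:]
        truth["planted"] = {"column": column, "from": from_res, "to": to_res}
    if garble is not None:
        columns, taxa, intensity = garble
        for taxon in taxa:
            seq = list(seqs[taxon])
            for col in columns:
                if rng.random() < intensity:
                    seq[col - 1] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
            seqs[taxon] = "".join(seq)
        truth["garbled_columns"] = sorted(columns)
    return ProteinAlignment(seqs), truth


# ---------------------------------------------------------------------------
# codon alignments with a focal-stem nonsynonymous rate shift

_SYN_NEIGHBORS: dict[str, list[str]] = {}
_NONSYN_NEIGHBORS: dict[str, list[str]] = {}


def _codon_neighbors(codon: str) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous) single-nucleotide sense neighbours."""
    syn = _SYN_NEIGHBORS.get(codon)
    if syn is None:
        aa = GENETIC_CODE[codon]
        syn, nonsyn = [], []
        for pos in range(3):
            for b in "ACGT":
                if b != codon[pos]:
                    nxt = codon[:pos] + b + codon[pos + 1 :]
                    if nxt not in STOP_CODONS:
                        (syn if GENETIC_CODE[nxt] == aa else nonsyn).append(nxt)
        _SYN_NEIGHBORS[codon] = syn
        _NONSYN_NEIGHBORS[codon] = nonsyn
    return _SYN_NEIGHBORS[codon], _NONSYN_NEIGHBORS[codon]


def _evolve_codon(codon: str, t: float, omega: float, rng) -> tuple[str, int, int]:
    """Gillespie simulation of one codon along one branch.

    Per-neighbour rate is 1/3 for synonymous and omega/3 for nonsynonymous
    changes, so a neutral (omega = 1) branch accumulates one expected
    substitution per nucleotide site per unit branch length.  Returns the
    final codon and the realised (nonsyn, syn) event counts.
    """
    n_events = s_events = 0
    clock = 0.0
    while True:
        syn, nonsyn = _codon_neighbors(codon)
        syn_rate = len(syn) / 3.0
        nonsyn_rate = omega * len(nonsyn) / 3.0
        total = syn_rate + nonsyn_rate
        if total <= 0:
            break
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            break
        if rng.random() * total < syn_rate:
            codon = syn[int(rng.integers(len(syn)))]
            s_events += 1
        else:
            codon = nonsyn[int(rng.integers(len(nonsyn)))]
            n_events += 1
    return codon, n_events, s_events


def simulate_codon_alignment(
    tree: Phylogeny | None = None,
    n_codons: int = 300,
    seed: int = 0,
    omega: float = 0.5,
    focal_multiplier: float = 1.0,
    gene: str = "",
) -> tuple[CodonAlignment, BranchRateTable]:
    """Codon alignment evolved under an MG-style process with truth dN.

    ``omega`` scales nonsynonymous relative to synonymous rates everywhere;
    ``focal_multiplier`` additionally multiplies the nonsynonymous rate on
    the focal stem branch.  The truth table records realised per-branch dN
    (nonsynonymous events per nonsynonymous site, taking the coding-average
    three-quarters of positions as nonsynonymous).
    """
    if tree is None:
        tree = default_tree(equal_branch_length=0.05)
    if focal_multiplier < 0:
        raise ValueError("focal multiplier must be >= 0")
    rng = np.random.default_rng(seed)
    focal_stem = tree.focal_stem
    root_codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    codons: dict[int, list[str]] = {tree.root: root_codons}
    n_counts: dict[str, int] = {}
    for idx in tree.preorder():
        node = tree.nodes[idx]
        if node.parent is None:
            continue
        parent_codons = codons[node.parent]
        w = omega * (focal_multiplier if idx == focal_stem else 1.0)
        out = []
        n_total = 0
        for c in parent_codons:
            c2, ne, _ = _evolve_codon(c, node.length, w, rng)
            out.append(c2)
            n_total += ne
        codons[idx] = out
        n_counts[node.label] = n_total
    nonsyn_sites = 0.75 * 3 * n_codons
    table = BranchRateTable(
        gene=gene,
        dn={label: count / nonsyn_sites for label, count in n_counts.items()},
        focal_branch=tree.label_of(focal_stem),
        sister_branch=tree.label_of(tree.sister_stem) if tree.sister_lineage else None,
    )
    seqs = {
        tree.label_of(i): "".join(codons[i])
        for i in range(tree.n_nodes)
        if tree.nodes[i].is_tip
    }
    return CodonAlignment(seqs), table


# ---------------------------------------------------------------------------
# orthogroup matrices, annotation tables, k-mer histograms


def simulate_orthogroups(
    tree: Phylogeny | None = None,
    n_families: int = 100,
    n_losses: int = 10,
    seed: int = 0,
    mean_copies: float = 1.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Copy-number matrix with planted focal-clade losses.

    Planted families have zero copies in every focal species and at least
    one copy in a sister species; every non-planted family is guaranteed at
    least one focal copy so the loss rule recovers exactly the planted set.
    Returns (matrix, list of lost family ids).
    """
    if tree is None:
        tree = default_tree()
    if n_losses > n_families:
        raise ValueError("more losses than families")
    rng = np.random.default_rng(seed)
    species = tree.tip_labels
    focal = sorted(tree.focal_clade)
    sister = sorted(tree.sister_lineage)
    counts = rng.poisson(mean_copies, size=(n_families, len(species)))
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"fam{i + 1:04d}" for i in range(n_families)], name="family"),
        columns=species,
    )
    lost = list(df.index[rng.choice(n_families, size=n_losses, replace=False)])
    for fam in df.index:
        if fam in lost:
            df.loc[fam, focal] = 0
            if (df.loc[fam, sister] == 0).all():
                df.loc[fam, sister[int(rng.integers(len(sister)))]] = 1
        elif (df.loc[fam, focal] == 0).all():
            df.loc[fam, focal[int(rng.integers(len(focal)))]] = 1
    return df, sorted(lost)


def simulate_annotations(
    n_families: int = 200,
    n_terms: int = 20,
    members_per_family: int = 8,
    foreground_size: int = 30,
    planted_term: str | None = "T01",
    effect: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Long-format family/member/term table with a planted enriched term.

    Each member draws one or two terms uniformly; in foreground families the
    planted term is additionally assigned to each member with probability
    ``effect`` (``effect = 0`` or ``planted_term = None`` gives a null
    dataset).  Returns the table and a truth dict naming the foreground
    families and the planted term.
    """
    rng = np.random.default_rng(seed)
    terms = [f"T{i + 1:02d}" for i in range(n_terms)]
    if planted_term is not None and planted_term not in terms:
        raise ValueError(f"planted term {planted_term!r} not among generated terms")
    families = [f"fam{i + 1:04d}" for i in range(n_families)]
    foreground = sorted(rng.choice(families, size=foreground_size, replace=False))
    rows = []
    for fam in families:
        boost = planted_term is not None and fam in foreground
        for m in range(members_per_family):
            member = f"{fam}_m{m + 1}"
            k = 1 + int(rng.random() < 0.5)
            assigned = list(rng.choice(terms, size=k, replace=False))
            if boost and rng.random() < effect and planted_term not in assigned:
                assigned.append(planted_term)
            for t in assigned:
                rows.append({"family": fam, "member": member, "term": t})
    table = pd.DataFrame(rows)
    truth = {"foreground": foreground, "planted_term": planted_term, "effect": effect}
    return table, truth


def simulate_histogram(
    genome_size: int = 1_000_000,
    coverage: float = 30.0,
    error_fraction: float = 0.2,
    seed: int = 0,
    k: int = 19,
) -> tuple[KmerHistogram, dict]:
    """Poisson k-mer depth histogram with a depth-1 error spike.

    Each of ``genome_size`` distinct k-mers receives Poisson(``coverage``)
    occurrences; ``error_fraction``·genome_size additional error k-mers are
    placed at depth 1.  Returns the histogram and the truth dict.
    """
    rng = np.random.default_rng(seed)
    depths = rng.poisson(coverage, size=int(genome_size))
    depths = depths[depths > 0]
    hist = np.bincount(depths)
    hist[1] += int(error_fraction * genome_size)
    nz = np.nonzero(hist)[0]
    nz = nz[nz > 0]
    return (
        KmerHistogram(depths=nz, counts=hist[nz].astype(float), k=k),
        {"genome_size": int(genome_size), "coverage": coverage, "error_fraction": error_fraction},
    )
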