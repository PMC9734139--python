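"""Detection of lineage-specific mutated sites (LSMs).

A lineage-specific mutated site is an alignment column where every focal
tip (e.g. every seahorse) carries one residue and every background tip
carries a different, shared residue — the pattern behind the seahorse
tlx1 A208T replacement.  Raw candidates are filtered twice:

1. *Ancestral support*: the focal residue at the focal clade's MRCA and the
   background residue at that MRCA's parent must both have marginal
   posterior probability >= 0.95, certifying that the substitution occurred
   on the focal stem branch rather than being an artefact of sparse data.
2. *Alignment quality*: mean pairwise sequence similarity over the
   10-residue window centred on the site must be >= 0.7 and the minimum
   pairwise similarity >= 0.35; windows below either bound are "poorly
   aligned fragments" and their candidates are discarded.

Both thresholds are strict in the rejecting direction: mean < 0.7 or
min < 0.35 rejects; the boundary values 0.7/0.35 and posterior exactly
0.95 pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .alignments import GAP, ProteinAlignment, aa_to_cds_position
from .asr import AncestralPosterior, SubstitutionModel, empirical_frequencies, marginal_posteriors
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "LsmCall",
    "detect_candidate_sites",
    "pairwise_window_similarity",
    "alignment_quality_filter",
    "scan_gene",
    "scan_alignment",
]

DEFAULT_P_MIN = 0.95
DEFAULT_MEAN_THRESHOLD = 0.7
DEFAULT_MIN_THRESHOLD = 0.35
DEFAULT_WINDOW = 10


@dataclass
class LsmCall:
    """One candidate lineage-specific mutated site with its filter verdicts."""

    gene: str
    column: int  # 1-based alignment column
    focal_residue: str
    background_residue: str
    posterior_focal: float
    posterior_background: float
    window_mean_similarity: float
    window_min_similarity: float
    verdict: str  # pass | fail_posterior | fail_alignment_quality

    @property
    def cds_position(self) -> int:
        """First-nucleotide coordinate of the mutated codon (1-based)."""
        return aa_to_cds_position(self.column)


def detect_candidate_sites(
    alignment: ProteinAlignment, tree: Phylogeny
) -> list[tuple[int, str, str]]:
    """Columns where focal and background tips are invariant but different.

    Returns (column, focal_residue, background_residue) triples.  Any gap in
    either partition disqualifies the column; so does any within-partition
    polymorphism ("all other background species" is read strictly).
    """
    focal = sorted(tree.focal_clade)
    background = sorted(set(alignment.taxa) & tree.background)
    missing = set(focal) - set(alignment.taxa)
    if missing:
        raise KeyError(f"focal taxa missing from alignment: {sorted(missing)}")
    if not background:
        raise ValueError("no background taxa in alignment")
    out: list[tuple[int, str, str]] = []
    for col in range(1, alignment.length + 1):
        f_res = {alignment[t][col - 1] for t in focal}
        if len(f_res) != 1 or GAP in f_res:
            continue
        b_res = {alignment[t][col - 1] for t in background}
        if len(b_res) != 1 or GAP in b_res:
            continue
        x, y = f_res.pop(), b_res.pop()
        if x != y:
            out.append((col, x, y))
    return out


def pairwise_window_similarity(
    alignment: ProteinAlignment, column: int, window: int = DEFAULT_WINDOW
) -> tuple[float, float]:
    """Mean and minimum pairwise similarity in the window around a column.

    The even-length window spans columns [column-4, column+5] for the default
    width of 10, truncated at the alignment ends.  For each unordered taxon
    pair, similarity is the fraction of identical residues over the columns
    where both sequences are ungapped; a pair with no comparable column
    contributes 0.
    """
    if not 1 <= column <= alignment.length:
        raise IndexError(f"column {column} outside 1..{alignment.length}")
    half = window // 2
    lo = max(1, column - (half - 1))
    hi = min(alignment.length, column + half)
    sims: list[float] = []
    for a, b in combinations(alignment.taxa, 2):
        sa, sb = alignment[a], alignment[b]
        compared = identical = 0
        for c in range(lo - 1, hi):
            if sa[c] != GAP and sb[c] != GAP:
                compared += 1
                if sa[c] == sb[c]:
                    identical += 1
        if compared == 0:
            logger.warning("no comparable window columns for pair (%s, %s)", a, b)
            sims.append(0.0)
        else:
            sims.append(identical / compared)
    return sum(sims) / len(sims), min(sims)


def alignment_quality_filter(
    mean: float,
    minimum: float,
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
    min_threshold: float = DEFAULT_MIN_THRESHOLD,
) -> str:
    """Classify a window as ``retained`` or ``poorly_aligned``.

    Poorly aligned iff mean < 0.7 or minimum < 0.35 (strict inequalities, so
    the boundary values themselves are retained).
    """
    if minimum < min_threshold or mean < mean_threshold:
        return "poorly_aligned"
    return "retained"


def _background_posterior(
    tree: Phylogeny,
    alignment: ProteinAlignment,
    posteriors: AncestralPosterior,
    column: int,
    residue: str,
) -> float:
    """Support for the ancestral (background) residue above the focal stem.

    Normally the posterior of the background residue at the focal MRCA's
    parent.  When the focal MRCA is the root there is no parent; the check
    falls back to the minimum support across the root's non-focal children
    (observed tips count as probability 1 when they match).
    """
    mrca = tree.focal_mrca
    parent = tree.nodes[mrca].parent
    if parent is not None:
        return posteriors.probability(tree.label_of(parent), column, residue)
    logger.warning("focal MRCA is the root; using outgroup-side children for the ancestral check")
    supports = []
    for child in tree.nodes[tree.root].children:
        if child == mrca:
            continue
        node = tree.nodes[child]
        if node.is_tip:
            supports.append(1.0 if alignment[node.label][column - 1] == residue else 0.0)
        else:
            supports.append(posteriors.probability(node.label, column, residue))
    return min(supports) if supports else 0.0


def scan_gene(
    alignment: ProteinAlignment,
    tree: Phylogeny,
    posteriors: AncestralPosterior,
    gene: str = "",
    p_min: float = DEFAULT_P_MIN,
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
    min_threshold: float = DEFAULT_MIN_THRESHOLD,
    window: int = DEFAULT_WINDOW,
) -> list[LsmCall]:
    """Full LSM scan of one gene: candidates, posterior and quality filters.

    ``verdict`` is ``pass`` only when the focal residue at the focal MRCA and
    the background residue at its parent both reach ``p_min`` and the
    surrounding window is retained by the similarity filter.
    """
    calls: list[LsmCall] = []
    mrca_label = tree.label_of(tree.focal_mrca)
    for column, focal_res, background_res in detect_candidate_sites(alignment, tree):
        p_focal = posteriors.probability(mrca_label, column, focal_res)
        p_background = _background_posterior(tree, alignment, posteriors, column, background_res)
        mean_sim, min_sim = pairwise_window_similarity(alignment, column, window)
        if p_focal < p_min or p_background < p_min:
            verdict = "fail_posterior"
        elif alignment_quality_filter(mean_sim, min_sim, mean_threshold, min_threshold) == "poorly_aligned":
            verdict = "fail_alignment_quality"
        else:
            verdict = "pass"
        calls.append(
            LsmCall(
                gene=gene,
                column=column,
                focal_residue=focal_res,
                background_residue=background_res,
                posterior_focal=p_focal,
                posterior_background=p_background,
                window_mean_similarity=mean_sim,
                window_min_similarity=min_sim,
                verdict=verdict,
            )
        )
    return calls


def scan_alignment(
    alignment: ProteinAlignment,
    tree: Phylogeny,
    gene: str = "",
    model: SubstitutionModel | None = None,
    **kwargs,
) -> list[LsmCall]:
    """Convenience wrapper: reconstruct ancestral states, then scan.

    The default model is Poisson with frequencies estimated from the
    alignment itself.
    """
    if model is None:
        model = SubstitutionModel.poisson(empirical_frequencies(alignment))
    post = marginal_posteriors(tree, alignment, model)
    return scan_gene(alignment, tree, post, gene=gene, **kwargs)
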