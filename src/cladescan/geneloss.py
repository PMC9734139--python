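"""Gene-loss calling from orthogroup copy-number tables.

The rule is deliberately simple and deterministic: a gene family counts as
*lost* in the focal clade when no focal species retains a homolog while the
closest sister lineage still has one — presence elsewhere in the background
does not qualify, because only the sister lineage certifies that the gene
was present in the focal clade's immediate ancestor.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = ["read_orthogroup_matrix", "call_gene_loss"]


def read_orthogroup_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with a ``family`` column and one integer column per species."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "family" not in df.columns:
        raise ValueError("orthogroup table needs a 'family' column")
    df = df.set_index("family")
    if (df < 0).any().any():
        raise ValueError("copy numbers must be non-negative")
    return df.astype(int)


def call_gene_loss(
    matrix: pd.DataFrame, tree: Phylogeny, require_all_sister: bool = False
) -> list[str]:
    """Family ids lost in the focal clade.

    Lost iff copy number is 0 in every focal species and >= 1 in at least
    one sister-lineage species (all sister species when
    ``require_all_sister``).  Families with zero counts everywhere are
    unobservable and excluded with a warning.
    """
    focal = sorted(tree.focal_clade)
    sister = sorted(tree.sister_lineage)
    if not sister:
        raise ValueError("tree has no sister lineage for the focal clade")
    missing = (set(focal) | set(sister)) - set(matrix.columns)
    if missing:
        raise KeyError(f"species missing from matrix: {sorted(missing)}")
    lost: list[str] = []
    for family, row in matrix.iterrows():
        if (row == 0).all():
            logger.warning("family %s has zero copies everywhere; excluded", family)
            continue
        if (row[focal] != 0).any():
            continue
        sister_present = (row[sister] >= 1).all() if require_all_sister else (row[sister] >= 1).any()
        if sister_present:
            lost.append(str(family))
    return lost
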