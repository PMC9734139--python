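"""Fractional annotation weighting of gene families and weighted enrichment.

Gene families carry whole-family functional annotations derived from their
members.  When strictly more than 90% of a family's members share an
identical annotation set, the family is treated as single-function: weight
1 is split equally among that set's terms.  Otherwise every annotation
instance counts ("annotated times", duplicates included) and each term
receives the fraction of instances carrying it.  Either way the weights of
a family sum to exactly 1, so a family never contributes more than one
unit to any term tally.

Because the weights are fractional, the usual hypergeometric enrichment
test does not apply; over-representation of a term in a foreground set of
families (e.g. the significantly contracted ones) is instead assessed by a
seeded permutation test on the weighted term sums.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .rates import fdr_bh

logger = logging.getLogger(__name__)

__all__ = [
    "assign_family_weights",
    "build_annotation_weights",
    "read_annotation_table",
    "weighted_term_enrichment",
]

SINGLE_FUNCTION_FRACTION = 0.9  # strictly more than this share must agree


def assign_family_weights(members: list[tuple[str, list[str]]]) -> dict[str, float]:
    """Term weights for one family from its members' annotations.

    ``members`` is a list of (member id, term list); members with empty term
    lists are allowed but count toward the >90% denominator.  Raises when no
    member is annotated.
    """
    if not members:
        raise ValueError("family has no members")
    annotated = [(m, terms) for m, terms in members if terms]
    if not annotated:
        raise ValueError("family has no annotated member")
    # single-function rule: > 90% of ALL members share an identical term set
    sets = Counter(frozenset(terms) for _, terms in annotated)
    top_set, top_count = sets.most_common(1)[0]
    if top_count / len(members) > SINGLE_FUNCTION_FRACTION:
        share = 1.0 / len(top_set)
        return {term: share for term in sorted(top_set)}
    counts = Counter()
    for _, terms in annotated:
        counts.update(terms)  # duplicates are distinct annotation instances
    total = sum(counts.values())
    return {term: counts[term] / total for term in sorted(counts)}


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Long-format TSV: family, member, term (one row per annotation)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"family", "member", "term"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    return df


def build_annotation_weights(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-family weight vectors from a long-format annotation table.

    Families without any annotated member are skipped with a warning.
    A member can appear with an empty/NA term to record it as unannotated.
    """
    weights: dict[str, dict[str, float]] = {}
    for family, sub in table.groupby("family", sort=False):
        members: dict[str, list[str]] = {}
        for row in sub.itertuples():
            members.setdefault(str(row.member), [])
            if isinstance(row.term, str) and row.term:
                members[str(row.member)].append(row.term)
        try:
            weights[str(family)] = assign_family_weights(list(members.items()))
        except ValueError:
            logger.warning("family %s has no annotated member; skipped", family)
    return weights


def weighted_term_enrichment(
    foreground: set[str],
    weights: dict[str, dict[str, float]],
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for term over-representation in a family set.

    The statistic per term is the summed weight over foreground families;
    the null distribution resamples foreground sets of the same size
    uniformly from all weighted families.  p-values use the add-one
    estimator p = (1 + #{null >= observed}) / (1 + n_perm), so they are
    bounded below by 1/(n_perm+1); BH adjustment is applied across terms.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    families = sorted(weights)
    unknown = set(foreground) - set(families)
    if unknown:
        raise KeyError(f"foreground families without weights: {sorted(unknown)}")
    terms = sorted({t for w in weights.values() for t in w})
    mat = np.zeros((len(families), len(terms)))
    t_idx = {t: j for j, t in enumerate(terms)}
    for i, fam in enumerate(families):
        for t, w in weights[fam].items():
            mat[i, t_idx[t]] = w
    fg_rows = np.array([i for i, f in enumerate(families) if f in foreground])
    observed = mat[fg_rows].sum(axis=0)
    rng = np.random.default_rng(seed)
    k = len(fg_rows)
    exceed = np.zeros(len(terms), dtype=int)
    # ties count as exceedances; the epsilon guards against summation-order
    # rounding when a permuted set reproduces the observed weight exactly
    for _ in range(n_perm):
        draw = rng.choice(len(families), size=k, replace=False)
        exceed += mat[draw].sum(axis=0) >= observed - 1e-9
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "term": terms,
            "observed_weight": observed,
            "p_value": p,
            "fdr_adjusted_p": fdr_bh(p),
        }
    )
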