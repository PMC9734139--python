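"""Branch-wise dN tables, the rapid-evolution test, and the selection
decision layer.

A gene is *rapidly evolving* when the nonsynonymous rate on the focal stem
branch is significantly above the rest of the tree (FDR-corrected p < 0.05)
AND the focal stem dN exceeds the sister lineage's stem dN.  Per-branch dN
comes either from an imported table (e.g. a free-ratio codeml fit) or from
the internal surrogate: NG86 dN between the maximum-a-posteriori ancestral
nucleotide sequences at the two endpoints of each branch.

The positive-selection decision layer consumes log-likelihood pairs of the
branch-site alternative/null models: 2Δln L is referred to a χ² with one
degree of freedom and the p-values are Benjamini–Hochberg adjusted; genes
with adjusted p < 0.05 are flagged.

Test form
---------
The default statistic treats the focal branch's dN as a new observation
from the background branches' distribution:

    t = (dN_focal − mean(dN_bg)) / (s_bg · sqrt(1 + 1/n)),   df = n − 1,

two-sided.  This "prediction" form is calibrated under exchangeability of
branches (its null rejection rate is the nominal level).  The literal
one-sample form with the focal value as the hypothesised population mean
(``method="popmean"``) is also provided but is strongly anticonservative,
since the focal dN is itself a random draw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignments import CodonAlignment
from .asr import SubstitutionModel, map_sequences, marginal_posteriors
from .codon import ng86_dnds
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "BranchRateTable",
    "RegResult",
    "branch_dn_table",
    "read_branch_dn_tables",
    "reg_test",
    "reg_analysis",
    "fdr_bh",
    "branch_site_decision",
    "psg_decide",
]


@dataclass
class BranchRateTable:
    """Per-branch dN for one gene; branches are named by their child node."""

    gene: str
    dn: dict[str, float | None]
    focal_branch: str
    sister_branch: str | None = None

    def __post_init__(self) -> None:
        if self.focal_branch not in self.dn:
            raise KeyError(f"focal branch {self.focal_branch!r} not in table")
        if self.sister_branch is not None and self.sister_branch not in self.dn:
            raise KeyError(f"sister branch {self.sister_branch!r} not in table")

    def background_values(self) -> list[float]:
        return [
            v
            for b, v in self.dn.items()
            if b != self.focal_branch and v is not None and not math.isnan(v)
        ]


@dataclass
class RegResult:
    gene: str
    p_value: float | None
    focal_dn: float | None
    sister_dn: float | None
    background_dn_mean: float | None
    fdr_adjusted_p: float | None = None
    is_reg: bool = False


def branch_dn_table(
    codon_alignment: CodonAlignment, tree: Phylogeny, posteriors=None
) -> BranchRateTable:
    """Per-branch dN from MAP ancestral nucleotide sequences.

    Ancestral sequences are reconstructed per nucleotide column under
    Jukes–Cantor (``posteriors`` may supply a precomputed reconstruction);
    each branch's dN is the NG86 estimate between its endpoint sequences,
    with tips using their observed sequences.  Saturated or undefined
    branches are recorded as missing.
    """
    if posteriors is None:
        posteriors = marginal_posteriors(tree, codon_alignment, SubstitutionModel.jc_nucleotide())
    anc = map_sequences(posteriors)
    seqs: dict[str, str] = dict(anc)
    for taxon in codon_alignment.taxa:
        seqs[taxon] = codon_alignment[taxon]
    dn: dict[str, float | None] = {}
    for idx in tree.branches():
        node = tree.nodes[idx]
        child_label = node.label
        parent_label = tree.label_of(node.parent)
        a, b = seqs.get(parent_label), seqs.get(child_label)
        if a is None or b is None:
            dn[child_label] = None
            continue
        est = ng86_dnds(a, b)
        if est.dn is None or est.saturated_n:
            logger.warning("branch %s: dN saturated/undefined; recorded missing", child_label)
            dn[child_label] = None
        else:
            dn[child_label] = est.dn
    return BranchRateTable(
        gene="",
        dn=dn,
        focal_branch=tree.label_of(tree.focal_stem),
        sister_branch=tree.label_of(tree.sister_stem) if tree.sister_lineage else None,
    )


def read_branch_dn_tables(
    path: str | Path, focal_branch: str, sister_branch: str | None = None
) -> list[BranchRateTable]:
    """Import externally computed branch dN (TSV: gene, branch, dN)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "branch", "dN"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)}, got {list(df.columns)}")
    tables = []
    for gene, sub in df.groupby("gene", sort=False):
        dn = {str(r.branch): (None if pd.isna(r.dN) else float(r.dN)) for r in sub.itertuples()}
        tables.append(
            BranchRateTable(gene=str(gene), dn=dn, focal_branch=focal_branch, sister_branch=sister_branch)
        )
    return tables


def reg_test(table: BranchRateTable, method: str = "prediction") -> RegResult:
    """Test whether the focal branch's dN stands out from the background.

    Requires at least three non-missing background values; a missing focal
    dN skips the test.  Degenerate zero-variance backgrounds yield p = 1
    when the focal value equals the mean and p = 0 otherwise (warned).
    """
    focal = table.dn.get(table.focal_branch)
    sister = table.dn.get(table.sister_branch) if table.sister_branch else None
    bg = table.background_values()
    if focal is None or math.isnan(focal):
        logger.warning("gene %s: focal dN missing; test skipped", table.gene)
        return RegResult(table.gene, None, None, sister, float(np.mean(bg)) if bg else None)
    if len(bg) < 3:
        raise ValueError(f"gene {table.gene}: need >= 3 background branch dN values, have {len(bg)}")
    bg_arr = np.asarray(bg, dtype=float)
    mean = float(bg_arr.mean())
    sd = float(bg_arr.std(ddof=1))
    n = len(bg_arr)
    if sd == 0.0:
        logger.warning("gene %s: zero background variance", table.gene)
        p = 1.0 if focal == mean else 0.0
    elif method == "prediction":
        t = (focal - mean) / (sd * math.sqrt(1.0 + 1.0 / n))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    elif method == "popmean":
        p = float(stats.ttest_1samp(bg_arr, popmean=focal).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RegResult(table.gene, p, focal, sister, mean)


def reg_analysis(
    tables: list[BranchRateTable], alpha: float = 0.05, method: str = "prediction"
) -> pd.DataFrame:
    """Per-gene REG decision: BH-adjust the p-values, then require both
    adjusted p < alpha and focal dN > sister dN."""
    results = [reg_test(t, method=method) for t in tables]
    tested = [r for r in results if r.p_value is not None]
    if tested:
        adj = fdr_bh([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.fdr_adjusted_p = float(a)
            r.is_reg = bool(
                a < alpha
                and r.sister_dn is not None
                and r.focal_dn is not None
                and r.focal_dn > r.sister_dn
            )
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "p_value": [r.p_value for r in results],
            "fdr_adjusted_p": [r.fdr_adjusted_p for r in results],
            "focal_dN": [r.focal_dn for r in results],
            "sister_dN": [r.sister_dn for r in results],
            "background_dN_mean": [r.background_dn_mean for r in results],
            "is_reg": [r.is_reg for r in results],
        }
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def branch_site_decision(lnl_null: float, lnl_alt: float, tolerance: float = 1e-6) -> float:
    """χ²(1) p-value of the branch-site likelihood-ratio statistic.

    The statistic is 2(ln L_alt − ln L_null); tiny negative values within
    ``tolerance`` are clamped to 0 (p = 1), larger ones indicate a
    non-converged fit and are rejected.
    """
    delta = lnl_alt - lnl_null
    if delta < -tolerance:
        raise ValueError(
            f"alternative log-likelihood below null by {-delta:.3g}: fit did not converge"
        )
    stat = max(0.0, 2.0 * delta)
    return float(stats.chi2.sf(stat, df=1))


def psg_decide(lnl_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Positive-selection flags from a table with columns gene, lnL0, lnL1.

    Applies the χ²(1) test per gene and BH adjustment across genes; a gene
    is flagged when its adjusted p-value is below ``alpha``.
    """
    required = {"gene", "lnL0", "lnL1"}
    if not required.issubset(lnl_table.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    p = [branch_site_decision(r.lnL0, r.lnL1) for r in lnl_table.itertuples()]
    adj = fdr_bh(p)
    return pd.DataFrame(
        {
            "gene": lnl_table["gene"].to_numpy(),
            "p_value": p,
            "fdr_adjusted_p": adj,
            "is_psg": adj < alpha,
        }
    )
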