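"""Nei–Gojobori (NG86) counting of synonymous and nonsynonymous change.

The estimator used for per-branch dN: synonymous/nonsynonymous *site*
counts per codon are the fractions of the nine possible point changes that
preserve the amino acid; *differences* between two codons are classified
along every shortest substitution path (paths through stop codons are
excluded and the remainder reweighted equally); proportions are corrected
with the Jukes–Cantor formula d = -(3/4)·ln(1 - 4p/3), which diverges
("saturation") at p >= 3/4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

from .alignments import GAP

logger = logging.getLogger(__name__)

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "translate_codon",
    "codon_sites",
    "ng86_counts",
    "ng86_dnds",
    "DnDsEstimate",
]

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} not allowed")


_sites_cache: dict[str, tuple[float, float]] = {}


def codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon; sum is 3.

    Per position, the synonymous fraction is the share of the three possible
    point changes that preserve the amino acid; changes to stop codons count
    as nonsynonymous.
    """
    cached = _sites_cache.get(codon)
    if cached is not None:
        return cached
    _check_codon(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = sum(
            1
            for b in "ACGT"
            if b != codon[pos] and GENETIC_CODE[codon[:pos] + b + codon[pos + 1 :]] == aa
        )
        s += syn / 3.0
    result = (3.0 - s, s)
    _sites_cache[codon] = result
    return result


@dataclass(frozen=True)
class CodonPairCounts:
    n_sites_a: float
    s_sites_a: float
    n_sites_b: float
    s_sites_b: float
    nd: float  # nonsynonymous differences, path-averaged
    sd: float  # synonymous differences, path-averaged

    @property
    def n_sites(self) -> float:
        """Nonsynonymous sites averaged between the two codons."""
        return (self.n_sites_a + self.n_sites_b) / 2.0

    @property
    def s_sites(self) -> float:
        return (self.s_sites_a + self.s_sites_b) / 2.0


_pair_cache: dict[tuple[str, str], CodonPairCounts | None] = {}


def ng86_counts(codon_a: str, codon_b: str) -> CodonPairCounts | None:
    """Site and difference counts for one codon pair.

    Differences are averaged over all shortest substitution paths between
    the codons, with paths visiting a stop codon excluded and the remaining
    paths reweighted equally.  Returns ``None`` in the degenerate case where
    every path is blocked by a stop codon (the pair is then skipped
    upstream).
    """
    key = (codon_a, codon_b)
    if key in _pair_cache:
        return _pair_cache[key]
    _check_codon(codon_a)
    _check_codon(codon_b)
    na, sa = codon_sites(codon_a)
    nb, sb = codon_sites(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    nd = sd = 0.0
    if diff_positions:
        valid_paths = 0
        path_nd: list[float] = []
        path_sd: list[float] = []
        for order in permutations(diff_positions):
            current = codon_a
            step_n = step_s = 0.0
            blocked = False
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if nxt in STOP_CODONS:
                    blocked = True
                    break
                if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                    step_s += 1.0
                else:
                    step_n += 1.0
                current = nxt
            if not blocked:
                valid_paths += 1
                path_nd.append(step_n)
                path_sd.append(step_s)
        if valid_paths == 0:
            _pair_cache[key] = None
            return None
        nd = sum(path_nd) / valid_paths
        sd = sum(path_sd) / valid_paths
    result = CodonPairCounts(na, sa, nb, sb, nd, sd)
    _pair_cache[key] = result
    return result


@dataclass
class DnDsEstimate:
    """Pairwise NG86 summary between two codon sequences."""

    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float | None
    ps: float | None
    dn: float | None
    ds: float | None
    saturated_n: bool
    saturated_s: bool
    n_codons_compared: int

    @property
    def omega(self) -> float | None:
        if self.dn is None or self.ds is None or self.ds == 0:
            return None
        return self.dn / self.ds


def _jc(p: float) -> tuple[float | None, bool]:
    if p >= 0.75:
        return None, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86_dnds(seq_a: str, seq_b: str) -> DnDsEstimate:
    """NG86 dN/dS between two equal-length codon-aligned sequences.

    Codon pairs containing a gap or a stop codon (or blocked entirely by
    stop-codon paths) are skipped.  Site counts are averaged between the two
    sequences; the estimate is symmetric in its arguments.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3 != 0:
        raise ValueError("length not divisible by 3")
    n_sites = s_sites = nd = sd = 0.0
    compared = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if GAP in ca or GAP in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            logger.warning("skipping stop codon pair (%s, %s) at codon %d", ca, cb, i // 3 + 1)
            continue
        counts = ng86_counts(ca, cb)
        if counts is None:
            logger.warning("all paths blocked for pair (%s, %s); skipped", ca, cb)
            continue
        compared += 1
        n_sites += counts.n_sites
        s_sites += counts.s_sites
        nd += counts.nd
        sd += counts.sd
    pn = nd / n_sites if n_sites > 0 else None
    if s_sites > 0:
        ps = sd / s_sites
    else:
        ps = None
        logger.warning("no synonymous sites; dS undefined")
    dn, sat_n = _jc(pn) if pn is not None else (None, False)
    ds, sat_s = _jc(ps) if ps is not None else (None, False)
    return DnDsEstimate(
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        dn=dn,
        ds=ds,
        saturated_n=sat_n,
        saturated_s=sat_s,
        n_codons_compared=compared,
    )
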