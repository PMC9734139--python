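"""Genome-size estimation from a k-mer depth histogram.

With K_num the total number of retained k-mer occurrences and K_depth the
modal (peak) k-mer depth, genome size is estimated as

    Genome Size = K_num / K_depth.

Sequencing-error k-mers pile up at very low depth; they are excluded by
truncating the histogram at the first local minimum before the main peak
(or at an explicit user cutoff).  Heterozygous-peak folding is not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["KmerHistogram", "GenomeSizeEstimate", "estimate_genome_size"]


@dataclass
class KmerHistogram:
    """Depth -> count of distinct k-mers observed at that depth."""

    depths: np.ndarray
    counts: np.ndarray
    k: int = 19

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.counts.shape:
            raise ValueError("depths and counts must be 1-D and equal length")
        if np.any(self.depths <= 0):
            raise ValueError("depths must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        order = np.argsort(self.depths)
        self.depths = self.depths[order]
        self.counts = self.counts[order]
        if len(np.unique(self.depths)) != len(self.depths):
            raise ValueError("duplicate depths")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = 19) -> "KmerHistogram":
        """Two-column (depth, count) TSV, jellyfish/KMC histo compatible."""
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] != 2:
            raise ValueError("expected two columns: depth, count")
        return cls(depths=data[:, 0].astype(int), counts=data[:, 1], k=k)


@dataclass
class GenomeSizeEstimate:
    genome_size: float  # bp
    k_num: float  # total retained k-mer occurrences
    k_depth: int  # modal depth of the retained histogram
    error_cutoff: int  # depths below this were excluded


def _auto_cutoff(depths: np.ndarray, counts: np.ndarray) -> int:
    """Depth of the first local minimum separating the error spike from the
    coverage peak; the minimum depth when the histogram has no error spike."""
    if len(counts) < 3 or counts[1] >= counts[0]:
        return int(depths[0])  # no descending error region at the start
    for i in range(1, len(counts) - 1):
        if counts[i + 1] > counts[i]:
            return int(depths[i])
        if counts[i] > counts[i - 1]:
            break
    raise ValueError(
        "no local minimum found between error and coverage peaks; "
        "pass an explicit error_cutoff"
    )


def estimate_genome_size(
    hist: KmerHistogram, error_cutoff: int | str = "auto"
) -> GenomeSizeEstimate:
    """Estimate genome size as K_num / K_depth after error-peak exclusion.

    ``error_cutoff`` keeps only depths >= the cutoff; ``"auto"`` places it
    at the first local minimum of the histogram.  K_depth is the modal
    retained depth (smallest depth on a tie); K_num sums depth x count over
    the retained depths.
    """
    if isinstance(error_cutoff, str):
        if error_cutoff != "auto":
            raise ValueError(f"unknown cutoff {error_cutoff!r}")
        cutoff = _auto_cutoff(hist.depths, hist.counts)
    else:
        cutoff = int(error_cutoff)
    keep = hist.depths >= cutoff
    if not np.any(keep) or hist.counts[keep].sum() == 0:
        raise ValueError("no k-mers retained above the error cutoff")
    depths = hist.depths[keep]
    counts = hist.counts[keep]
    k_depth = int(depths[int(np.argmax(counts))])
    k_num = float(np.dot(depths, counts))
    return GenomeSizeEstimate(
        genome_size=k_num / k_depth, k_num=k_num, k_depth=k_depth, error_cutoff=cutoff
    )
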