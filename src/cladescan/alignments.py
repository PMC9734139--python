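"""Gapped alignments and the 1-based coordinate conventions.

Two container types cover the pipeline's sequence inputs: a protein
alignment (20 amino-acid alphabet plus ``-``) and a codon-aligned
nucleotide alignment whose length is a multiple of three, with gaps in
whole-codon triplets.  All column/residue coordinates are 1-based and
closed, matching the convention in which residue 208 of a coding sequence
starts at nucleotide 622.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"
GAP = "-"

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "GAP",
    "AlignmentError",
    "ProteinAlignment",
    "CodonAlignment",
    "read_alignment",
    "write_alignment",
    "aa_to_cds_position",
]


class AlignmentError(ValueError):
    pass


def aa_to_cds_position(residue_index: int) -> int:
    """First nucleotide position (1-based) of the codon for a residue.

    Residue 208 maps to nucleotide 622, residue 207 to 619: the coordinate
    arithmetic behind reading an amino-acid replacement off as a point
    mutation in the coding sequence.
    """
    if residue_index < 1:
        raise ValueError(f"residue index must be >= 1, got {residue_index}")
    return 3 * (residue_index - 1) + 1


@dataclass
class _BaseAlignment:
    sequences: dict[str, str]  # insertion-ordered: taxon -> gapped sequence

    _alphabet = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        allowed = set(self._alphabet) | {GAP}
        for taxon, seq in self.sequences.items():
            for pos, ch in enumerate(seq, start=1):
                if ch not in allowed:
                    raise AlignmentError(
                        f"illegal symbol {ch!r} at {taxon} position {pos}"
                    )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, taxon: str) -> str:
        return self.sequences[taxon]

    def column(self, col: int) -> dict[str, str]:
        """Residues of 1-based column ``col``, keyed by taxon."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return {t: s[col - 1] for t, s in self.sequences.items()}

    def columns(self) -> Iterator[dict[str, str]]:
        for col in range(1, self.length + 1):
            yield self.column(col)


class ProteinAlignment(_BaseAlignment):
    _alphabet = AMINO_ACIDS


class CodonAlignment(_BaseAlignment):
    _alphabet = NUCLEOTIDES

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.length % 3 != 0:
            raise AlignmentError(
                f"codon alignment length {self.length} not divisible by 3"
            )
        for taxon, seq in self.sequences.items():
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if GAP in codon and codon != GAP * 3:
                    raise AlignmentError(
                        f"partial-codon gap {codon!r} at {taxon} codon {i // 3 + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, taxon: str, codon_index: int) -> str:
        """1-based codon ``codon_index`` of ``taxon``."""
        start = 3 * (codon_index - 1)
        return self.sequences[taxon][start : start + 3]


def read_alignment(path: str | Path, alphabet: str = "protein"):
    """Read an aligned FASTA file.

    ``alphabet`` selects the container: ``"protein"`` yields a
    :class:`ProteinAlignment`, ``"nucleotide"`` a :class:`CodonAlignment`.
    Header uniqueness, equal lengths and the alphabet are all validated.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate FASTA header {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if alphabet == "protein":
        return ProteinAlignment(records)
    if alphabet == "nucleotide":
        return CodonAlignment(records)
    raise ValueError(f"unknown alphabet {alphabet!r}")


def write_alignment(alignment: _BaseAlignment, path: str | Path) -> None:
    """Write canonical single-line-per-sequence FASTA, preserving order."""
    with open(path, "w") as fh:
        for taxon, seq in alignment.sequences.items():
            fh.write(f">{taxon}\n{seq}\n")
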