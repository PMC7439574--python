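"""Amplicon references and in-silico bisulfite conversion.

Coordinates are 0-based, half-open throughout; a CpG site is pinned to the
offset of its C on the top (reference) strand. ``OT``/``OB`` denote the
original top / original bottom strand of bisulfite-converted DNA: on OT,
unmethylated cytosines read as T; an OB read, brought into top-strand
orientation, shows G→A conversion instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from Bio.Seq import Seq

__all__ = ["Strand", "Amplicon", "find_cpg_sites", "bisulfite_convert", "reverse_complement"]

_VALID = set("ACGTN")


class Strand(str, Enum):
    OT = "OT"  # original top
    OB = "OB"  # original bottom


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def find_cpg_sites(sequence: str) -> list[int]:
    """0-based offsets of the C of every CG dinucleotide, left to right."""
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


@dataclass(frozen=True)
class Amplicon:
    """A targeted bisulfite amplicon: unconverted top-strand reference plus the
    ordered top-strand C offsets of its CpG sites."""

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        for p in self.cpg_positions:
            if self.sequence[p : p + 2] != "CG":
                raise ValueError(f"position {p} of {self.name!r} is not a CpG cytosine")
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValueError("cpg_positions must be strictly increasing")

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "Amplicon":
        seq = sequence.upper()
        return cls(name=name, sequence=seq, cpg_positions=tuple(find_cpg_sites(seq)))

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def bisulfite_convert(
    sequence: str,
    strand: Strand | str = Strand.OT,
    methylated_positions: Iterable[int] = (),
) -> str:
    """In-silico bisulfite conversion of one molecule.

    ``methylated_positions`` are top-strand CpG C offsets whose cytosine (on
    the requested strand) is methylated and therefore protected from
    conversion. OT: every other C becomes T, returned in top-strand
    orientation. OB: the reverse complement is converted the same way (the
    protected base is the bottom-strand C pairing with the top-strand G at
    offset+1) and returned in read-strand (bottom 5'→3') orientation.
    """
    strand = Strand(strand)
    seq = sequence.upper()
    meth = set(methylated_positions)
    cpgs = set(find_cpg_sites(seq))
    bad = meth - cpgs
    if bad:
        raise ValueError(f"methylated positions not CpG cytosines: {sorted(bad)}")

    if strand is Strand.OT:
        protected = meth
        chars = list(seq)
    else:
        chars = list(reverse_complement(seq))
        n = len(chars)
        # bottom-strand C sits opposite the top-strand G at p+1
        protected = {n - 2 - p for p in meth}
    return "".join(
        "T" if c == "C" and i not in protected else c for i, c in enumerate(chars)
    )
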