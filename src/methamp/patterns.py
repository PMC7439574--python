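"""Per-read CpG methylation patterns (epialleles) and their statistics.

Each sequenced molecule yields one methylation state per amplicon CpG:
M (methylated), U (unmethylated) or N (uncallable — sequencing error at the
CpG base, or CpG not covered by the read). A sample's epiallele composition
is summarised as a pattern-frequency table (pattern count / total retained
reads), optionally agglomerated into groups of similar patterns, plus
per-CpG mean methylation and a three-way read classification
(fully unmethylated / stochastic / fully methylated).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align import AlignedRead
from .amplicon import Amplicon, Strand

__all__ = [
    "MethRead",
    "PatternTable",
    "ReadClassSummary",
    "call_pattern",
    "pattern_table",
    "group_patterns",
    "per_cpg_methylation",
    "classify_reads",
]


@dataclass(frozen=True)
class MethRead:
    read_id: str
    states: str  # one of M/U/N per amplicon CpG, in amplicon order
    strand: Strand
    alignment_score: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.states) - set("MUN")
        if bad:
            raise ValueError(f"invalid methylation states: {sorted(bad)}")

    @property
    def complete(self) -> bool:
        return "N" not in self.states


@dataclass
class PatternTable:
    """Epiallele pattern -> (count, frequency) for one sample.

    Frequencies are normalised over retained (N-free, unless configured
    otherwise) reads; ``n_discarded`` tallies reads dropped for containing N.
    """

    counts: dict[str, int]
    total_reads: int
    n_discarded: int = 0
    grouped: bool = False

    @property
    def frequencies(self) -> dict[str, float]:
        return {p: c / self.total_reads for p, c in self.counts.items()}


@dataclass(frozen=True)
class ReadClassSummary:
    frac_fully_unmethylated: float
    frac_fully_methylated: float
    frac_stochastic: float
    n_reads: int


def call_pattern(alignment: AlignedRead, amplicon: Amplicon) -> MethRead:
    """Call M/U/N at every amplicon CpG from one aligned read.

    OT reads report the CpG cytosine (C -> M, T -> U); OB reads report the
    complementary strand via the CpG guanine in top-strand orientation
    (G -> M, A -> U). Anything else, including an uncovered CpG, is N.
    """
    states = []
    for p in amplicon.cpg_positions:
        if alignment.strand is Strand.OT:
            base = alignment.ref_bases.get(p)
            state = {"C": "M", "T": "U"}.get(base, "N")
        else:
            base = alignment.ref_bases.get(p + 1)
            state = {"G": "M", "A": "U"}.get(base, "N")
        states.append(state)
    return MethRead(
        read_id=alignment.read_id,
        states="".join(states),
        strand=alignment.strand,
        alignment_score=alignment.score,
    )


def pattern_table(reads: Iterable[MethRead], drop_incomplete: bool = True) -> PatternTable:
    """Exact pattern counts and frequencies over a sample's reads.

    Reads containing N are excluded (and tallied) when ``drop_incomplete``,
    matching how complete epiallele patterns are displayed; raises if no read
    survives.
    """
    counts: Counter[str] = Counter()
    discarded = 0
    for read in reads:
        if drop_incomplete and not read.complete:
            discarded += 1
            continue
        counts[read.states] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads retained for the pattern table")
    return PatternTable(counts=dict(counts), total_reads=total, n_discarded=discarded)


def group_patterns(
    table: PatternTable, max_hamming: int = 1, top_k: int = 20
) -> PatternTable:
    """Greedy agglomeration of similar patterns.

    Ungrouped patterns are visited in descending frequency (ties broken by
    pattern string); each visited pattern seeds a group that absorbs every
    remaining ungrouped pattern within Hamming distance ``max_hamming``.
    Groups beyond ``top_k`` are pooled into an ``"other"`` bucket. Total
    counts are conserved, so grouped frequencies still sum to 1.
    """
    if not table.counts:
        raise ValueError("empty pattern table")
    order = sorted(table.counts, key=lambda p: (-table.counts[p], p))
    remaining = list(order)
    groups: dict[str, int] = {}
    while remaining:
        seed = remaining.pop(0)
        members = [seed] + [p for p in remaining if _hamming(seed, p) <= max_hamming]
        for p in members[1:]:
            remaining.remove(p)
        groups[seed] = sum(table.counts[p] for p in members)

    if len(groups) > top_k:
        keep = sorted(groups, key=lambda p: (-groups[p], p))[:top_k]
        other = sum(c for p, c in groups.items() if p not in keep)
        groups = {p: groups[p] for p in keep}
        groups["other"] = other

    return PatternTable(
        counts=groups,
        total_reads=table.total_reads,
        n_discarded=table.n_discarded,
        grouped=True,
    )


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("patterns differ in length")
    return sum(x != y for x, y in zip(a, b))


def per_cpg_methylation(reads: Sequence[MethRead]) -> np.ndarray:
    """Mean methylation M/(M+U) per CpG over all reads with a call there.

    N states are excluded per CpG rather than per read, so incomplete reads
    still contribute. CpGs with zero calls come back as NaN.
    """
    if not reads:
        raise ValueError("no reads")
    n_cpgs = len(reads[0].states)
    m = np.zeros(n_cpgs)
    called = np.zeros(n_cpgs)
    for read in reads:
        if len(read.states) != n_cpgs:
            raise ValueError("reads from different amplicons")
        for i, s in enumerate(read.states):
            if s == "M":
                m[i] += 1
                called[i] += 1
            elif s == "U":
                called[i] += 1
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, m / np.maximum(called, 1), np.nan)


def classify_reads(reads: Iterable[MethRead]) -> ReadClassSummary:
    """Three-way classification of complete reads: all-U, all-M, or stochastic
    (any mixed pattern). Reads with N are ignored; raises if none remain."""
    n_u = n_m = n_s = 0
    for read in reads:
        if not read.complete:
            continue
        if set(read.states) == {"U"}:
            n_u += 1
        elif set(read.states) == {"M"}:
            n_m += 1
        else:
            n_s += 1
    total = n_u + n_m + n_s
    if total == 0:
        raise ValueError("no complete reads to classify")
    return ReadClassSummary(
        frac_fully_unmethylated=n_u / total,
        frac_fully_methylated=n_m / total,
        frac_stochastic=n_s / total,
        n_reads=total,
    )
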