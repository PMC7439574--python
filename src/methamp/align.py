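"""Bisulfite-aware pairwise alignment of amplicon reads.

Reads are aligned against the unconverted top-strand reference with an
asymmetric substitution matrix that treats bisulfite conversion as a match:
a read T opposite any reference C (OT strand), or — after bringing the read
into top-strand orientation — a read A opposite any reference G (OB strand).
Alignment is global in the read and free at the reference ends, which fits
short amplicons where every read should span (part of) the target; both
strands are tried and the better-scoring one is kept (ties go to OT).

This is an amplicon-scale stand-in for a genome-wide bisulfite aligner: no
indexing, and reads with heavy indel structure are simply rejected by the
score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .amplicon import Amplicon, Strand, reverse_complement

__all__ = ["AlignedRead", "align_read"]

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -2.0


@dataclass
class AlignedRead:
    """One read's placement on the amplicon.

    ``ref_bases`` maps reference offsets to the read base observed there (in
    top-strand orientation for both strands, so OB methylation is read off
    the G of each CpG). ``score``/``max_score`` allow fraction-of-maximum
    filtering; ``accepted`` reflects the threshold used at alignment time.
    """

    read_id: str
    strand: Strand
    offset: int
    score: float
    max_score: float
    ref_bases: dict[int, str]
    accepted: bool


def _matrix(strand: Strand) -> substitution_matrices.Array:
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                m[a, b] = 0.0
            elif a == b:
                m[a, b] = MATCH
            else:
                m[a, b] = MISMATCH
    if strand is Strand.OT:
        m["C", "T"] = MATCH  # unmethylated C reads as T
    else:
        m["G", "A"] = MATCH  # bottom-strand conversion seen as G->A on top
    return m


@lru_cache(maxsize=4)
def _aligner(strand: Strand) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(strand)
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # reference overhang is free (end gaps in the read row of the alignment)
    try:
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.query_end_gap_score = 0.0
    return aligner


def align_read(
    read: str,
    amplicon: Amplicon,
    *,
    read_id: str = "",
    min_score_frac: float = 0.8,
    min_read_length: int = 20,
) -> AlignedRead:
    """Align one read to the amplicon on both bisulfite strands.

    Returns the better-strand alignment; ``accepted`` is False when the score
    falls below ``min_score_frac`` of the maximum attainable for the read
    length (such reads are reported, never raised on).
    """
    read = read.upper()
    if len(read) < min_read_length:
        raise ValueError(f"read shorter than {min_read_length} bases")

    best: tuple[float, Strand, Align.Alignment] | None = None
    for strand in (Strand.OT, Strand.OB):
        query = read if strand is Strand.OT else reverse_complement(read)
        alignment = next(iter(_aligner(strand).align(amplicon.sequence, query)))
        if best is None or alignment.score > best[0]:
            best = (alignment.score, strand, alignment)

    score, strand, alignment = best
    ref_bases: dict[int, str] = {}
    query = str(alignment.query)
    for (t0, t1), (q0, _) in zip(*alignment.aligned):
        for k in range(t1 - t0):
            ref_bases[t0 + k] = query[q0 + k]
    offset = min(ref_bases) if ref_bases else 0
    max_score = MATCH * len(read)
    return AlignedRead(
        read_id=read_id,
        strand=strand,
        offset=offset,
        score=float(score),
        max_score=max_score,
        ref_bases=ref_bases,
        accepted=score >= min_score_frac * max_score,
    )
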