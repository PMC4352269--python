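"""Splice-site quality control and score filtering.

Every internal junction of a candidate annotation must carry the
canonical GT-AG donor/acceptor motif on the annotation strand (CT..AC on
the genomic forward strand for minus annotations; ~98.7% of eukaryotic
junctions are GT-AG).  Non-canonical junctions get a bounded rescue:
donor and acceptor boundaries may each shift by up to ``max_shift``
(default 10) bp, smallest total displacement first, with the adjoining
exon edges moved in lockstep so exon+intron length is conserved.
Annotations with an unrescuable junction are retained but flagged "N".

Scores are filtered strictly: only annotations scoring *more than* the
threshold (default 80) survive.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation_io import CandidateAnnotation, GenomeSequence

__all__ = [
    "Junction",
    "junctions_of",
    "is_canonical",
    "rescue_junction",
    "apply_quality_control",
    "filter_by_score",
]

log = logging.getLogger(__name__)

MIN_INTRON = 4  # room for both dinucleotide motifs


@dataclass(frozen=True)
class Junction:
    """One intron of an annotation: the interval [donor_pos, acceptor_pos).

    ``donor_pos``/``acceptor_pos`` are the genomic start/end of the
    intron; for minus-strand annotations the biological donor and
    acceptor roles are swapped, which :func:`is_canonical` accounts for.
    """

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.donor_pos >= self.acceptor_pos:
            raise ValueError("donor_pos must be < acceptor_pos")

    @property
    def length(self) -> int:
        return self.acceptor_pos - self.donor_pos


def junctions_of(annotation: CandidateAnnotation) -> list[Junction]:
    """Internal junctions of an annotation, in genomic order."""
    out = []
    for (_, left_end), (right_start, _) in zip(
        annotation.blocks, annotation.blocks[1:]
    ):
        out.append(
            Junction(annotation.chrom, left_end, right_start, annotation.strand)
        )
    return out


def is_canonical(genome: GenomeSequence, j: Junction) -> bool:
    """True iff the intron reads GT..AG on the annotation strand."""
    if j.length < MIN_INTRON:
        return False
    head = genome.fetch(j.chrom, j.donor_pos, j.donor_pos + 2)
    tail = genome.fetch(j.chrom, j.acceptor_pos - 2, j.acceptor_pos)
    if j.strand == "+":
        return head == "GT" and tail == "AG"
    return head == "CT" and tail == "AC"


@functools.lru_cache(maxsize=None)
def _shift_candidates(max_shift: int) -> tuple[tuple[int, int], ...]:
    """Donor/acceptor displacement pairs, smallest total displacement
    first; deterministic within ties."""
    pairs = [
        (dd, da)
        for dd in range(-max_shift, max_shift + 1)
        for da in range(-max_shift, max_shift + 1)
    ]
    pairs.sort(key=lambda p: (abs(p[0]) + abs(p[1]), abs(p[0]), abs(p[1]), p[0], p[1]))
    return tuple(pairs)


def rescue_junction(
    genome: GenomeSequence, j: Junction, max_shift: int = 10
) -> Optional[tuple[Junction, tuple[int, int]]]:
    """Search for a canonical junction within bounded boundary shifts.

    Donor and acceptor may shift independently by up to ``max_shift``
    bp; candidates are explored in order of increasing total
    displacement and the first canonical one wins.  Returns the rescued
    junction and the (donor, acceptor) shifts used — ``(0, 0)`` for an
    already-canonical junction — or ``None`` if no canonical pair is in
    range.  Candidates shrinking the intron below 4 bp or leaving the
    chromosome are discarded, not errors.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    chrom_len = genome.length(j.chrom)
    for dd, da in _shift_candidates(max_shift):
        donor = j.donor_pos + dd
        acceptor = j.acceptor_pos + da
        if acceptor - donor < MIN_INTRON:
            continue
        if donor < 0 or acceptor > chrom_len:
            continue
        cand = Junction(j.chrom, donor, acceptor, j.strand)
        if is_canonical(genome, cand):
            return cand, (dd, da)
    return None


def apply_quality_control(
    genome: GenomeSequence,
    annotation: CandidateAnnotation,
    max_shift: int = 10,
) -> CandidateAnnotation:
    """Check every internal junction, applying rescue shifts to the
    adjoining exon blocks; flag the annotation "N" if any junction stays
    non-canonical.  Idempotent, and the rescue never changes the score:
    the score is a property of the alignment path, not of the adjusted
    coordinates.  Single-exon annotations are canonical vacuously.
    """
    blocks = list(annotation.blocks)
    flag = "canonical"
    for idx in range(len(blocks) - 1):
        j = Junction(annotation.chrom, blocks[idx][1], blocks[idx + 1][0], annotation.strand)
        rescue = rescue_junction(genome, j, max_shift)
        if rescue is None:
            flag = "N"
            continue
        nj, (dd, da) = rescue
        if (dd, da) == (0, 0):
            continue
        new_left = (blocks[idx][0], nj.donor_pos)
        new_right = (nj.acceptor_pos, blocks[idx + 1][1])
        left_floor = blocks[idx - 1][1] if idx > 0 else 0
        right_ceil = blocks[idx + 2][0] if idx + 2 < len(blocks) else genome.length(j.chrom)
        valid = (
            new_left[0] < new_left[1]
            and new_right[0] < new_right[1]
            and new_left[0] >= left_floor
            and new_right[1] <= right_ceil
        )
        if not valid:
            log.warning(
                "%s: rescue shift (%d,%d) would break block invariants; flagged",
                annotation.transcript_id,
                dd,
                da,
            )
            flag = "N"
            continue
        log.info(
            "%s: junction rescued with donor/acceptor shift (%d,%d)",
            annotation.transcript_id,
            dd,
            da,
        )
        blocks[idx], blocks[idx + 1] = new_left, new_right
    return annotation.with_blocks(blocks, flag)


def filter_by_score(
    annotations: Sequence[CandidateAnnotation], min_score: float = 80.0
) -> list[CandidateAnnotation]:
    """Keep annotations scoring strictly more than ``min_score``;
    input order is preserved."""
    return [a for a in annotations if a.score > min_score]
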