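"""Tabular alignment parsing and per-transcript decision stages.

Consumes the standard 12-column tab-separated alignment table
(qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore).  Query ids encode exon identity as
``transcriptID|exonIndex|exonLength`` so each row is self-contained.

Subject coordinates are converted from 1-based inclusive to 0-based
half-open; an inverted subject interval (sstart > send) marks a
minus-strand hit and is normalized so target_start < target_end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

from .annotation_io import SourceTranscript

__all__ = [
    "AlignmentParseError",
    "StageError",
    "AlignmentHit",
    "Stage",
    "parse_alignment_table",
    "group_hits_by_transcript",
    "build_stages",
]

log = logging.getLogger(__name__)

N_COLUMNS = 12


class AlignmentParseError(Exception):
    """Malformed alignment table row; message names the line number."""


class StageError(Exception):
    """Hits inconsistent with the transcript they claim to belong to."""


@dataclass(frozen=True)
class AlignmentHit:
    """One similar region of one source exon on the target genome."""

    transcript_id: str
    exon_index: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    evalue: float
    align_length: int
    exon_length: int
    pident: float = 100.0  # parsed but unused by the cost model

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise AlignmentParseError(
                f"{self.transcript_id}|{self.exon_index}: empty target interval"
            )
        if self.evalue < 0:
            raise AlignmentParseError(
                f"{self.transcript_id}|{self.exon_index}: negative E-value"
            )
        if self.align_length < 1:
            raise AlignmentParseError(
                f"{self.transcript_id}|{self.exon_index}: align_length < 1"
            )

    @property
    def span(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True)
class Stage:
    """All retained hits of one exon.  The implicit skip state always
    exists, so an empty ``hits`` list means the stage is skip-only."""

    exon_index: int
    hits: tuple[AlignmentHit, ...]

    def __post_init__(self) -> None:
        for h in self.hits:
            if h.exon_index != self.exon_index:
                raise StageError(
                    f"hit for exon {h.exon_index} placed in stage {self.exon_index}"
                )


def _parse_qseqid(qseqid: str) -> tuple[str, int, int]:
    parts = qseqid.rsplit("|", 2)
    if len(parts) != 3:
        raise ValueError(f"qseqid {qseqid!r} not in transcriptID|exonIndex|exonLength form")
    return parts[0], int(parts[1]), int(parts[2])


def parse_alignment_table(
    stream: Union[str, IO[str]], strict: bool = True
) -> list[AlignmentHit]:
    """Parse a 12-column alignment table into hits.

    In strict mode (default) any malformed line raises
    :class:`AlignmentParseError` with its line number; otherwise bad
    lines are dropped with a logged warning.
    """
    close = None
    if isinstance(stream, str):
        stream = close = open(stream)
    hits: list[AlignmentHit] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != N_COLUMNS:
                msg = f"line {lineno}: expected {N_COLUMNS} columns, got {len(fields)}"
                if strict:
                    raise AlignmentParseError(msg)
                log.warning("%s; line dropped", msg)
                continue
            try:
                tid, exon_index, exon_length = _parse_qseqid(fields[0])
                pident = float(fields[2])
                align_length = int(fields[3])
                sstart = int(fields[8])
                send = int(fields[9])
                evalue = float(fields[10])
                if sstart <= send:
                    strand, start, end = "+", sstart - 1, send
                else:
                    strand, start, end = "-", send - 1, sstart
                hit = AlignmentHit(
                    transcript_id=tid,
                    exon_index=exon_index,
                    target_chrom=fields[1],
                    target_start=start,
                    target_end=end,
                    strand=strand,
                    evalue=evalue,
                    align_length=align_length,
                    exon_length=exon_length,
                    pident=pident,
                )
            except (ValueError, AlignmentParseError) as exc:
                msg = f"line {lineno}: {exc}"
                if strict:
                    raise AlignmentParseError(msg) from None
                log.warning("%s; line dropped", msg)
                continue
            hits.append(hit)
    finally:
        if close is not None:
            close.close()
    return hits


def group_hits_by_transcript(
    hits: Iterable[AlignmentHit],
) -> dict[str, list[AlignmentHit]]:
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.transcript_id, []).append(h)
    return grouped


def build_stages(
    transcript: SourceTranscript,
    hits: Sequence[AlignmentHit],
    max_hits_per_exon: int = 500,
    max_evalue: Optional[float] = None,
) -> list[Stage]:
    """Assemble exactly N stages (one per exon) from a transcript's hits.

    Hits within a stage are ordered by ascending E-value, ties broken by
    smaller target_start, and capped at ``max_hits_per_exon`` (best-E
    first).  A repeat-rich exon can align to tens of thousands of
    regions, so the cap bounds the DP width.  Exons with no surviving
    hits yield an empty, skip-only stage.
    """
    if max_hits_per_exon < 1:
        raise ValueError("max_hits_per_exon must be >= 1")
    n = transcript.n_exons
    per_exon: dict[int, list[AlignmentHit]] = {i: [] for i in range(1, n + 1)}
    for h in hits:
        if h.transcript_id != transcript.transcript_id:
            raise StageError(
                f"hit for {h.transcript_id} given to {transcript.transcript_id}"
            )
        if h.exon_index not in per_exon:
            raise StageError(
                f"{transcript.transcript_id}: exon index {h.exon_index} outside 1..{n}"
            )
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        per_exon[h.exon_index].append(h)
    stages = []
    for i in range(1, n + 1):
        ranked = sorted(per_exon[i], key=lambda h: (h.evalue, h.target_start))
        stages.append(Stage(i, tuple(ranked[:max_hits_per_exon])))
    return stages
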