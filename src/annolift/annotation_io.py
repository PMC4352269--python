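"""Gene-model and genome I/O.

Readers for genePred and GTF annotations and FASTA genomes, strand-aware
exon sequence extraction, and writers for the final annotation table
(genePred plus ``score`` and ``flag`` columns) and transcript FASTA.

Coordinate convention: everything in memory is 0-based half-open.
genePred is natively 0-based half-open; GTF input is converted from
1-based inclusive on read.  Exons are stored in ascending genomic order
regardless of strand; transcription order is derived where needed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AnnotationError",
    "AnnotationParseError",
    "CoordinateError",
    "SourceExon",
    "SourceTranscript",
    "GenomeSequence",
    "CandidateAnnotation",
    "read_source_annotations",
    "extract_exon_sequences",
    "write_genepred",
    "write_annotation_table",
    "write_transcript_fasta",
    "reverse_complement",
]

log = logging.getLogger(__name__)

GENEPRED_COLUMNS = (
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)


class AnnotationError(Exception):
    """Base class for annotation handling problems."""


class AnnotationParseError(AnnotationError):
    """Malformed annotation input; message names the offending line."""


class CoordinateError(AnnotationError):
    """A requested interval falls outside its chromosome."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class SourceExon:
    """One exon of a source transcript, in genomic (ascending) order.

    ``index`` is the 1-based ordinal of the exon within the transcript,
    counted in ascending genomic order independent of strand.
    """

    index: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"exon {self.index}: start {self.start} must be < end {self.end}"
            )
        if self.index < 1:
            raise AnnotationError(f"exon index must be >= 1, got {self.index}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SourceTranscript:
    """An annotated transcript of the source species.

    Exons are non-overlapping and sorted by genomic start.  Supplies the
    exon lengths and inter-exon (intron) distances consumed by the cost
    model.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[SourceExon, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise AnnotationError(
                    f"{self.transcript_id}: exon on {exon.chrom}, transcript on {self.chrom}"
                )
            if exon.start < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tx_start(self) -> int:
        return self.exons[0].start

    @property
    def tx_end(self) -> int:
        return self.exons[-1].end

    def intron_length(self, i: int) -> int:
        """Genomic distance between exon ``i`` and exon ``i+1`` (1-based)."""
        if not 1 <= i < self.n_exons:
            raise IndexError(f"no intron after exon {i} of {self.n_exons}")
        return self.exons[i].start - self.exons[i - 1].end

    def span_between(self, i: int, j: int) -> int:
        """Genomic distance from the end of exon ``i`` to the start of exon
        ``j`` (1-based, i < j).  Sums any skipped introns and exons."""
        if not 1 <= i < j <= self.n_exons:
            raise IndexError(f"bad exon pair ({i}, {j}) for N={self.n_exons}")
        return self.exons[j - 1].start - self.exons[i - 1].end


class GenomeSequence:
    """In-memory genome: uppercase sequence slices keyed by chromosome."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, source: Union[str, IO[str]]) -> "GenomeSequence":
        records = SeqIO.parse(source, "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.length(chrom)
        if not (0 <= start <= end <= n):
            raise CoordinateError(
                f"[{start}, {end}) outside {chrom} (length {n})"
            )
        return self._seqs[chrom][start:end]

    def to_fasta(self, out: IO[str], width: int = 60) -> None:
        for name in self._seqs:
            out.write(f">{name}\n")
            seq = self._seqs[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class CandidateAnnotation:
    """A transcript model assembled on the target genome.

    ``blocks`` are sorted, non-overlapping, 0-based half-open exon
    intervals.  ``canonical_flag`` is ``"canonical"`` or ``"N"`` (at
    least one splice junction remained non-canonical after rescue).
    ``skipped_exons`` lists 1-based source exon ordinals omitted from
    the model.
    """

    transcript_id: str
    source_transcript_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    score: float
    canonical_flag: str = "canonical"
    skipped_exons: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise AnnotationError(f"{self.transcript_id}: annotation has no blocks")
        if self.canonical_flag not in ("canonical", "N"):
            raise AnnotationError(
                f"{self.transcript_id}: bad flag {self.canonical_flag!r}"
            )
        prev_end = -1
        for start, end in self.blocks:
            if start >= end:
                raise AnnotationError(f"{self.transcript_id}: empty block [{start},{end})")
            if start < prev_end:
                raise AnnotationError(f"{self.transcript_id}: blocks overlap/unsorted")
            prev_end = end

    @property
    def tx_start(self) -> int:
        return self.blocks[0][0]

    @property
    def tx_end(self) -> int:
        return self.blocks[-1][1]

    def with_blocks(self, blocks, flag=None) -> "CandidateAnnotation":
        return replace(
            self,
            blocks=tuple(blocks),
            canonical_flag=self.canonical_flag if flag is None else flag,
        )


# ---------------------------------------------------------------------------
# readers


def _as_lines(stream: Union[str, IO[str]]) -> tuple[Iterable[str], Optional[IO[str]]]:
    if isinstance(stream, str):
        handle = open(stream)
        return handle, handle
    return stream, None


def read_source_annotations(
    stream: Union[str, IO[str]], format: str = "genepred"
) -> list[SourceTranscript]:
    """Read transcripts from a genePred table or a GTF file.

    Exons come back sorted by genomic start with 0-based half-open
    coordinates.  Transcripts declaring zero exons are rejected with a
    warning.  Malformed lines raise :class:`AnnotationParseError` naming
    the line number.
    """
    if format == "genepred":
        return _read_genepred(stream)
    if format == "gtf":
        return _read_gtf(stream)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_genepred(stream: Union[str, IO[str]]) -> list[SourceTranscript]:
    lines, handle = _as_lines(stream)
    transcripts: list[SourceTranscript] = []
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise AnnotationParseError(
                    f"line {lineno}: expected >=10 genePred columns, got {len(fields)}"
                )
            name, chrom, strand = fields[0], fields[1], fields[2]
            try:
                exon_count = int(fields[7])
                starts = [int(x) for x in fields[8].rstrip(",").split(",") if x != ""]
                ends = [int(x) for x in fields[9].rstrip(",").split(",") if x != ""]
            except ValueError as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from None
            if exon_count == 0 or not starts:
                log.warning("line %d: transcript %s has zero exons; skipped", lineno, name)
                continue
            if len(starts) != len(ends) or len(starts) != exon_count:
                raise AnnotationParseError(
                    f"line {lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            pairs = sorted(zip(starts, ends))
            # extended genePred carries name2 (gene symbol) in column 12
            gene_id = fields[11] if len(fields) >= 12 and fields[11] else name
            try:
                exons = tuple(
                    SourceExon(i, chrom, s, e) for i, (s, e) in enumerate(pairs, 1)
                )
                transcripts.append(
                    SourceTranscript(name, gene_id, chrom, strand, exons)
                )
            except AnnotationError as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from None
    finally:
        if handle is not None:
            handle.close()
    return transcripts


def _read_gtf(stream: Union[str, IO[str]]) -> list[SourceTranscript]:
    import gffutils

    if isinstance(stream, str):
        with open(stream) as fh:
            data = fh.read()
    else:
        data = stream.read()
    if not data.strip():
        return []
    try:
        db = gffutils.create_db(
            data,
            dbfn=":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types for bad input
        raise AnnotationParseError(f"unparseable GTF: {exc}") from None

    grouped: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise AnnotationParseError(
                f"exon at {feat.seqid}:{feat.start} lacks transcript_id"
            )
        grouped.setdefault(tid, []).append(feat)

    transcripts = []
    for tid in grouped:
        feats = sorted(grouped[tid], key=lambda f: f.start)
        gene = feats[0].attributes.get("gene_id", [tid])[0]
        chrom, strand = feats[0].seqid, feats[0].strand
        # GTF is 1-based inclusive
        exons = tuple(
            SourceExon(i, chrom, f.start - 1, f.end)
            for i, f in enumerate(feats, 1)
        )
        transcripts.append(SourceTranscript(tid, gene, chrom, strand, exons))
    return transcripts


def extract_exon_sequences(
    genome: GenomeSequence, transcript: SourceTranscript
) -> list[str]:
    """Per-exon transcription-sense sequences, in stored (ascending) exon
    order.  Minus-strand exons are reverse-complemented individually, so
    each returned string reads in mRNA sense."""
    seqs = []
    for exon in transcript.exons:
        seq = genome.fetch(exon.chrom, exon.start, exon.end)
        if transcript.strand == "-":
            seq = reverse_complement(seq)
        seqs.append(seq)
    return seqs


# ---------------------------------------------------------------------------
# writers


def write_genepred(transcripts: Sequence[SourceTranscript], out: IO[str]) -> int:
    """Write source transcripts as a plain 12-column genePred table."""
    n = 0
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.tx_start, t.transcript_id)):
        starts = ",".join(str(e.start) for e in t.exons) + ","
        ends = ",".join(str(e.end) for e in t.exons) + ","
        row = [
            t.transcript_id,
            t.chrom,
            t.strand,
            str(t.tx_start),
            str(t.tx_end),
            str(t.tx_end),
            str(t.tx_end),
            str(t.n_exons),
            starts,
            ends,
            "0",
            t.gene_id,
        ]
        out.write("\t".join(row) + "\n")
        n += 1
    return n


def write_annotation_table(
    annotations: Sequence[CandidateAnnotation],
    out: IO[str],
    header: bool = True,
) -> int:
    """Write candidate annotations as genePred plus ``score`` and ``flag``.

    No coding region is inferred, so cdsStart = cdsEnd = txEnd.  Rows are
    sorted by (chrom, txStart, name); the flag column is ``N`` for
    non-canonical annotations and empty otherwise.  Returns the row count.
    """
    if header:
        out.write("#" + "\t".join(GENEPRED_COLUMNS + ("score", "flag")) + "\n")
    n = 0
    ordered = sorted(
        annotations, key=lambda a: (a.chrom, a.tx_start, a.transcript_id)
    )
    for a in ordered:
        starts = ",".join(str(s) for s, _ in a.blocks) + ","
        ends = ",".join(str(e) for _, e in a.blocks) + ","
        row = [
            a.transcript_id,
            a.chrom,
            a.strand,
            str(a.tx_start),
            str(a.tx_end),
            str(a.tx_end),
            str(a.tx_end),
            str(len(a.blocks)),
            starts,
            ends,
            f"{a.score:.4f}",
            "N" if a.canonical_flag == "N" else "",
        ]
        out.write("\t".join(row) + "\n")
        n += 1
    return n


def write_transcript_fasta(
    genome: GenomeSequence,
    annotations: Sequence[CandidateAnnotation],
    out: IO[str],
    width: int = 60,
) -> int:
    """Write one FASTA record per annotation.

    The sequence is the concatenation of the exon-block slices, reverse
    complemented as a whole for minus-strand annotations (mRNA sense).
    """
    n = 0
    ordered = sorted(
        annotations, key=lambda a: (a.chrom, a.tx_start, a.transcript_id)
    )
    for a in ordered:
        seq = "".join(genome.fetch(a.chrom, s, e) for s, e in a.blocks)
        if a.strand == "-":
            seq = reverse_complement(seq)
        out.write(
            f">{a.transcript_id} src={a.source_transcript_id} "
            f"score={a.score:.4f} flag={a.canonical_flag}\n"
        )
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
        n += 1
    return n
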