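"""Seeded synthetic test worlds.

Generates a source genome with planted multi-exon genes (every intron
canonical GT-AG), a mutated target genome with a truth map of where each
exon really lies, and a simulated 12-column alignment table — so the
whole pipeline runs hermetically, with no external genomes or aligner.

Design notes:

* Substitutions may land anywhere except the four splice-motif bases of
  each intron (those are under strong purifying selection in real
  genomes and protecting them keeps the truth map meaningful).
* Indels are restricted to non-exonic sequence, so every surviving exon
  maps to a target interval of identical length.
* Segmental-duplication copies of exons (plus flanks) are appended to
  target chromosomes and reported as decoy hits with slightly worse
  E-values; the solver must out-reason them via position relationships.
* ``misassembly=True`` deletes the 2 bp acceptor dinucleotide of one
  intron in the target while the source intron carries a second AG two
  bases upstream, producing a junction that is recoverable only by a
  2 bp acceptor shift.

All randomness flows from ``FixtureSpec.seed``; identical specs yield
byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import IO, NamedTuple, Optional

import numpy as np

from .annotation_io import (
    GenomeSequence,
    SourceExon,
    SourceTranscript,
    extract_exon_sequences,
    reverse_complement,
    write_genepred,
)

__all__ = [
    "FixtureSpec",
    "SourceWorld",
    "TargetWorld",
    "TruthExon",
    "Decoy",
    "make_source_world",
    "derive_target_genome",
    "simulate_alignment_table",
    "preset_spec",
    "write_world",
    "PRESETS",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 30_000
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (60, 150)
    intron_length: tuple[int, int] = (80, 400)
    intergenic_gap: tuple[int, int] = (200, 500)
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    n_segmental_duplications: int = 0
    skip_exon_prob: float = 0.0
    n_noise_hits: int = 0
    misassembly: bool = False

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate, self.skip_exon_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must be in [0, 1], got {rate}")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo < 1 or hi < lo:
                raise ValueError("length/count ranges must be positive and ordered")
        if self.chrom_length < 1 or self.n_chroms < 1:
            raise ValueError("genome dimensions must be positive")


class SourceWorld(NamedTuple):
    genome: GenomeSequence
    transcripts: list[SourceTranscript]


@dataclass(frozen=True)
class TruthExon:
    chrom: str
    start: int
    end: int
    strand: str
    deleted: bool = False


@dataclass(frozen=True)
class Decoy:
    transcript_id: str
    exon_index: int
    chrom: str
    start: int
    end: int
    strand: str


class TargetWorld(NamedTuple):
    genome: GenomeSequence
    truth: dict[tuple[str, int], TruthExon]
    decoys: list[Decoy]
    misassembly: Optional[dict]


PRESETS: dict[str, dict] = {
    "identity": {},
    "default": dict(
        exons_per_gene=(5, 8),
        chrom_length=40_000,
        substitution_rate=0.025,
        indel_rate=0.0005,
        n_segmental_duplications=3,
        skip_exon_prob=0.01,
        n_noise_hits=20,
    ),
    "misassembly": dict(misassembly=True),
    "repeats": dict(substitution_rate=0.01, n_segmental_duplications=6),
}


def preset_spec(name: str, seed: int = 1, **overrides) -> FixtureSpec:
    try:
        kwargs = dict(PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs.update(overrides)
    return FixtureSpec(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# source world


def _plant_motifs(seq: list[str], intron_start: int, intron_end: int, strand: str) -> None:
    motif5, motif3 = ("GT", "AG") if strand == "+" else ("CT", "AC")
    seq[intron_start] = motif5[0]
    seq[intron_start + 1] = motif5[1]
    seq[intron_end - 2] = motif3[0]
    seq[intron_end - 1] = motif3[1]


def _misassembly_site(transcripts: list[SourceTranscript]) -> Optional[tuple[str, int]]:
    """The engineered junction: first intron of the first plus-strand
    multi-exon transcript.  Deterministic, derived from the gene list."""
    for t in transcripts:
        if t.strand == "+" and t.n_exons >= 2:
            return t.transcript_id, 1
    return None


def make_source_world(spec: FixtureSpec) -> SourceWorld:
    """Random genome with planted, fully GT-AG-canonical multi-exon genes."""
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_seqs = {
        name: list(rng.choice(BASES, size=spec.chrom_length)) for name in chrom_names
    }
    cursors = {name: 0 for name in chrom_names}
    transcripts: list[SourceTranscript] = []

    for g in range(spec.n_genes):
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = rng.integers(
            spec.exon_length[0], spec.exon_length[1] + 1, size=n_ex
        )
        intron_lens = rng.integers(
            spec.intron_length[0], spec.intron_length[1] + 1, size=max(n_ex - 1, 0)
        )
        gap = int(rng.integers(spec.intergenic_gap[0], spec.intergenic_gap[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        footprint = int(exon_lens.sum() + intron_lens.sum())

        chrom = None
        for name in chrom_names:  # first chromosome with room
            if cursors[name] + gap + footprint <= spec.chrom_length:
                chrom = name
                break
        if chrom is None:
            raise ValueError(
                f"gene {g}: genome too small for n_genes={spec.n_genes}; "
                "increase chrom_length or n_chroms"
            )
        pos = cursors[chrom] + gap
        seq = chrom_seqs[chrom]
        exons = []
        for i in range(n_ex):
            start = pos
            pos += int(exon_lens[i])
            exons.append(SourceExon(i + 1, chrom, start, pos))
            if i < n_ex - 1:
                intron_start = pos
                pos += int(intron_lens[i])
                _plant_motifs(seq, intron_start, pos, strand)
        cursors[chrom] = pos
        transcripts.append(
            SourceTranscript(
                transcript_id=f"tx{g:03d}",
                gene_id=f"gene{g:03d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )

    if spec.misassembly:
        site = _misassembly_site(transcripts)
        if site is None:
            raise ValueError("misassembly mode needs a plus-strand multi-exon gene")
        tid, junction = site
        t = next(x for x in transcripts if x.transcript_id == tid)
        intron_end = t.exons[junction].start
        # second in-frame AG two bases upstream of the true acceptor: the
        # target will lose the true AG, making the upstream one the only
        # canonical acceptor, exactly 2 bp away
        seq = chrom_seqs[t.chrom]
        for offset, base in zip(range(-6, 0), "AGTTAG"):
            seq[intron_end + offset] = base

    genome = GenomeSequence({name: "".join(chrom_seqs[name]) for name in chrom_names})
    return SourceWorld(genome, transcripts)


# ---------------------------------------------------------------------------
# target world


def _protected_positions(transcripts: list[SourceTranscript], chrom: str) -> set[int]:
    """Splice-motif bases: exempt from substitutions and indels."""
    protected: set[int] = set()
    for t in transcripts:
        if t.chrom != chrom:
            continue
        for left, right in zip(t.exons, t.exons[1:]):
            protected.update((left.end, left.end + 1, right.start - 2, right.start - 1))
    return protected


def _exonic_positions(transcripts: list[SourceTranscript], chrom: str) -> set[int]:
    exonic: set[int] = set()
    for t in transcripts:
        if t.chrom != chrom:
            continue
        for e in t.exons:
            exonic.update(range(e.start, e.end))
    return exonic


def derive_target_genome(world: SourceWorld, spec: FixtureSpec) -> TargetWorld:
    """Mutated copy of the source genome plus a truth map.

    Applies whole-exon deletions (``skip_exon_prob``), point
    substitutions, short non-exonic indels, the optional engineered
    2 bp acceptor deletion, and appends segmental-duplication decoys.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genome, transcripts = world

    mis_info: Optional[dict] = None
    mis_delete: dict[str, set[int]] = {}
    if spec.misassembly:
        tid, junction = _misassembly_site(transcripts)  # type: ignore[misc]
        t = next(x for x in transcripts if x.transcript_id == tid)
        intron_end = t.exons[junction].start
        mis_delete.setdefault(t.chrom, set()).update({intron_end - 2, intron_end - 1})
        mis_info = {
            "transcript_id": tid,
            "junction_after_exon": junction,
            "expected_shift": 2,
        }

    deleted_exons: set[tuple[str, int]] = set()
    for t in transcripts:
        for e in t.exons:
            if spec.skip_exon_prob > 0 and rng.random() < spec.skip_exon_prob:
                deleted_exons.add((t.transcript_id, e.index))

    target_seqs: dict[str, str] = {}
    maps: dict[str, np.ndarray] = {}
    for chrom in genome.chroms:
        src = genome.fetch(chrom, 0, genome.length(chrom))
        n = len(src)
        protected = _protected_positions(transcripts, chrom)
        exonic = _exonic_positions(transcripts, chrom)

        delete = np.zeros(n, dtype=bool)
        for t in transcripts:
            if t.chrom != chrom:
                continue
            for e in t.exons:
                if (t.transcript_id, e.index) in deleted_exons:
                    delete[e.start : e.end] = True
        for pos in mis_delete.get(chrom, ()):
            delete[pos] = True

        sub_base: dict[int, str] = {}
        if spec.substitution_rate > 0:
            for pos in np.nonzero(rng.random(n) < spec.substitution_rate)[0]:
                pos = int(pos)
                if pos in protected or delete[pos]:
                    continue
                alternatives = [b for b in "ACGT" if b != src[pos]]
                sub_base[pos] = alternatives[int(rng.integers(0, 3))]

        insert_after: dict[int, str] = {}
        if spec.indel_rate > 0:
            for pos in np.nonzero(rng.random(n) < spec.indel_rate)[0]:
                pos = int(pos)
                if pos in exonic or pos in protected or delete[pos]:
                    continue
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    insert_after[pos] = "".join(rng.choice(BASES, size=size))
                else:
                    span = range(pos, min(pos + size, n))
                    if any(p in exonic or p in protected for p in span):
                        continue
                    delete[pos : pos + size] = True

        out: list[str] = []
        tmap = np.empty(n + 1, dtype=np.int64)
        for p in range(n):
            tmap[p] = len(out)
            if delete[p]:
                continue
            out.append(sub_base.get(p, src[p]))
            if p in insert_after:
                out.extend(insert_after[p])
        tmap[n] = len(out)
        target_seqs[chrom] = "".join(out)
        maps[chrom] = tmap

    truth: dict[tuple[str, int], TruthExon] = {}
    for t in transcripts:
        tmap = maps[t.chrom]
        for e in t.exons:
            key = (t.transcript_id, e.index)
            if key in deleted_exons:
                truth[key] = TruthExon(t.chrom, -1, -1, t.strand, deleted=True)
            else:
                truth[key] = TruthExon(
                    t.chrom, int(tmap[e.start]), int(tmap[e.end]), t.strand
                )

    decoys: list[Decoy] = []
    if spec.n_segmental_duplications > 0:
        flank = 20
        candidates = [
            (t, e)
            for t in transcripts
            for e in t.exons
            if (t.transcript_id, e.index) not in deleted_exons
        ]
        picks = rng.choice(len(candidates), size=spec.n_segmental_duplications, replace=False)
        for idx in sorted(int(i) for i in picks):
            t, e = candidates[idx]
            lo = max(0, e.start - flank)
            hi = min(genome.length(t.chrom), e.end + flank)
            segment = list(genome.fetch(t.chrom, lo, hi))
            for p in np.nonzero(rng.random(len(segment)) < 0.02)[0]:
                p = int(p)
                alternatives = [b for b in "ACGT" if b != segment[p]]
                segment[p] = alternatives[int(rng.integers(0, 3))]
            dest = genome.chroms[int(rng.integers(0, len(genome.chroms)))]
            spacer = "".join(rng.choice(BASES, size=50))
            offset = len(target_seqs[dest]) + len(spacer)
            target_seqs[dest] = target_seqs[dest] + spacer + "".join(segment)
            decoys.append(
                Decoy(
                    t.transcript_id,
                    e.index,
                    dest,
                    offset + (e.start - lo),
                    offset + (e.start - lo) + e.length,
                    t.strand,
                )
            )

    return TargetWorld(GenomeSequence(target_seqs), truth, decoys, mis_info)


# ---------------------------------------------------------------------------
# simulated alignments


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _row(
    qseqid: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    qlen: int,
    mismatch: int,
    evalue: float,
) -> str:
    # subject coordinates back to 1-based inclusive; minus hits inverted
    if strand == "+":
        sstart, send = start + 1, end
    else:
        sstart, send = end, start + 1
    length = end - start
    pident = 100.0 * (1 - mismatch / max(length, 1))
    fields = [
        qseqid,
        chrom,
        f"{pident:.2f}",
        str(qlen),
        str(mismatch),
        "0",
        "1",
        str(qlen),
        str(sstart),
        str(send),
        f"{evalue:g}",
        f"{2.0 * length:.1f}",
    ]
    return "\t".join(fields)


def simulate_alignment_table(
    world: SourceWorld,
    target: TargetWorld,
    spec: FixtureSpec,
    out: IO[str],
) -> int:
    """Emit a 12-column alignment table for the simulated worlds.

    One truth hit (E-value 0) per surviving exon at its true target
    location, one decoy hit (E-value 1e-20) per segmental-duplication
    copy, and ``n_noise_hits`` random noise rows (E-value 1e-5).  The
    query id carries ``transcriptID|exonIndex|exonLength``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genome, transcripts = world
    n_rows = 0
    for t in transcripts:
        sense = extract_exon_sequences(genome, t)
        for e, qseq in zip(t.exons, sense):
            entry = target.truth[(t.transcript_id, e.index)]
            if entry.deleted:
                continue
            tseq = target.genome.fetch(entry.chrom, entry.start, entry.end)
            if entry.strand == "-":
                tseq = reverse_complement(tseq)
            mism = _hamming(qseq, tseq)
            out.write(
                _row(
                    f"{t.transcript_id}|{e.index}|{e.length}",
                    entry.chrom,
                    entry.start,
                    entry.end,
                    entry.strand,
                    e.length,
                    mism,
                    0.0,
                )
                + "\n"
            )
            n_rows += 1
    by_id = {t.transcript_id: t for t in transcripts}
    for d in target.decoys:
        e = by_id[d.transcript_id].exons[d.exon_index - 1]
        out.write(
            _row(
                f"{d.transcript_id}|{d.exon_index}|{e.length}",
                d.chrom,
                d.start,
                d.end,
                d.strand,
                e.length,
                int(0.02 * e.length),
                1e-20,
            )
            + "\n"
        )
        n_rows += 1
    for _ in range(spec.n_noise_hits):
        t = transcripts[int(rng.integers(0, len(transcripts)))]
        e = t.exons[int(rng.integers(0, t.n_exons))]
        chrom = target.genome.chroms[int(rng.integers(0, len(target.genome.chroms)))]
        max_start = max(target.genome.length(chrom) - e.length, 1)
        start = int(rng.integers(0, max_start))
        span = max(int(e.length * 0.6), 1)
        out.write(
            _row(
                f"{t.transcript_id}|{e.index}|{e.length}",
                chrom,
                start,
                start + span,
                "+" if rng.random() < 0.5 else "-",
                span,
                int(0.1 * span),
                1e-5,
            )
            + "\n"
        )
        n_rows += 1
    return n_rows


# ---------------------------------------------------------------------------
# on-disk worlds


def write_world(out_dir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    """Materialize a full fixture world in ``out_dir``.

    Writes source genome FASTA, source annotations (genePred), target
    genome FASTA, the simulated alignment table, the truth map (JSON)
    and the spec itself.  Returns the path of each artifact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    world = make_source_world(spec)
    target = derive_target_genome(world, spec)

    paths = {
        "source_genome": out_dir / "source.fa",
        "annotations": out_dir / "source.genepred",
        "target_genome": out_dir / "target.fa",
        "alignments": out_dir / "alignments.tsv",
        "truth": out_dir / "truth.json",
        "spec": out_dir / "fixture_spec.json",
    }
    with open(paths["source_genome"], "w") as fh:
        world.genome.to_fasta(fh)
    with open(paths["annotations"], "w") as fh:
        write_genepred(world.transcripts, fh)
    with open(paths["target_genome"], "w") as fh:
        target.genome.to_fasta(fh)
    with open(paths["alignments"], "w") as fh:
        simulate_alignment_table(world, target, spec, fh)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "truth": {
                    f"{tid}|{idx}": asdict(entry)
                    for (tid, idx), entry in sorted(target.truth.items())
                },
                "decoys": [asdict(d) for d in target.decoys],
                "misassembly": target.misassembly,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
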