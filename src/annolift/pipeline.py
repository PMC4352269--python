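"""End-to-end orchestration: stages -> solve -> assemble -> QC -> filter.

Each transcript is an independent unit of work, so the run can be
parallelized per transcript; the final outputs are sorted
deterministically, making results independent of worker count and of
processing order.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from .annotation_io import (
    CandidateAnnotation,
    GenomeSequence,
    SourceTranscript,
    read_source_annotations,
    write_annotation_table,
    write_transcript_fasta,
)
from .blast_io import AlignmentHit, build_stages, group_hits_by_transcript, parse_alignment_table
from .cost_model import CostParams
from .pathfinder import assemble_annotation, solve
from .quality_control import apply_quality_control, filter_by_score

__all__ = ["RunConfig", "RunSummary", "annotate", "validate", "read_chrom_map"]

log = logging.getLogger(__name__)

ANNOTATION_TABLE = "annotations.genepred"
TRANSCRIPT_FASTA = "transcripts.fa"
SUMMARY_JSON = "summary.json"


@dataclass
class RunConfig:
    annotations: Path
    source_genome: Path
    alignments: Path
    target_genome: Path
    out_dir: Path
    annotation_format: str = "genepred"
    cost: CostParams = field(default_factory=CostParams)
    min_score: float = 80.0
    max_splice_shift: int = 10
    max_hits_per_exon: int = 500
    max_evalue: Optional[float] = None
    chrom_map: Optional[dict[str, str]] = None
    workers: int = 1
    write_header: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_score <= 100:
            raise ValueError("min_score must be in [0, 100]")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass
class RunSummary:
    """Per-run accounting.  ``attempted == feasible + infeasible`` and
    ``written == feasible - low_score`` always hold."""

    attempted: int = 0
    feasible: int = 0
    infeasible: int = 0
    low_score: int = 0
    flagged_n: int = 0
    written: int = 0
    reasons: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def read_chrom_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source chromosome -> target chromosome."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"chrom map line {lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping


# worker-process globals, installed once per pool via _init_worker
_WORKER_STATE: dict = {}


def _init_worker(
    target_genome: GenomeSequence,
    cost: CostParams,
    max_hits_per_exon: int,
    max_evalue: Optional[float],
    max_splice_shift: int,
) -> None:
    _WORKER_STATE.update(
        target_genome=target_genome,
        cost=cost,
        max_hits_per_exon=max_hits_per_exon,
        max_evalue=max_evalue,
        max_splice_shift=max_splice_shift,
    )


def _process_one(
    task: tuple[SourceTranscript, list[AlignmentHit], Optional[str]],
) -> tuple[str, Optional[CandidateAnnotation], str]:
    """Run one transcript through stages -> solve -> assemble -> QC."""
    transcript, hits, fixed_chrom = task
    s = _WORKER_STATE
    stages = build_stages(
        transcript, hits, s["max_hits_per_exon"], s["max_evalue"]
    )
    result = solve(stages, transcript, s["cost"], fixed_chrom)
    annotation = assemble_annotation(result, transcript)
    if annotation is None:
        return transcript.transcript_id, None, "infeasible"
    annotation = apply_quality_control(
        s["target_genome"], annotation, s["max_splice_shift"]
    )
    reason = "flagged_n" if annotation.canonical_flag == "N" else "ok"
    return transcript.transcript_id, annotation, reason


def annotate(config: RunConfig) -> RunSummary:
    """Run the full pipeline and write the annotation table, transcript
    FASTA and a JSON summary into ``config.out_dir``."""
    transcripts = read_source_annotations(
        str(config.annotations), config.annotation_format
    )
    target_genome = GenomeSequence.from_fasta(str(config.target_genome))
    hits = parse_alignment_table(str(config.alignments), strict=False)
    grouped = group_hits_by_transcript(hits)

    known = {t.transcript_id for t in transcripts}
    for tid in sorted(set(grouped) - known):
        log.warning("alignment table references unknown transcript %s; skipped", tid)

    tasks = []
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        fixed = config.chrom_map.get(t.chrom) if config.chrom_map else None
        tasks.append((t, grouped.get(t.transcript_id, []), fixed))

    init_args = (
        target_genome,
        config.cost,
        config.max_hits_per_exon,
        config.max_evalue,
        config.max_splice_shift,
    )
    if config.workers == 1:
        _init_worker(*init_args)
        outcomes = [_process_one(task) for task in tasks]
    else:
        with ProcessPoolExecutor(
            max_workers=config.workers,
            initializer=_init_worker,
            initargs=init_args,
        ) as pool:
            outcomes = list(pool.map(_process_one, tasks, chunksize=8))

    summary = RunSummary()
    annotations: list[CandidateAnnotation] = []
    for tid, annotation, reason in outcomes:
        summary.attempted += 1
        if annotation is None:
            summary.infeasible += 1
            summary.reasons[tid] = reason
            continue
        summary.feasible += 1
        annotations.append(annotation)
        summary.reasons[tid] = reason

    kept = filter_by_score(annotations, config.min_score)
    kept_ids = {a.transcript_id for a in kept}
    for a in annotations:
        if a.transcript_id not in kept_ids:
            summary.low_score += 1
            summary.reasons[a.transcript_id] = "low_score"
    summary.flagged_n = sum(1 for a in kept if a.canonical_flag == "N")
    summary.written = len(kept)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / ANNOTATION_TABLE, "w") as fh:
        write_annotation_table(kept, fh, header=config.write_header)
    with open(out_dir / TRANSCRIPT_FASTA, "w") as fh:
        write_transcript_fasta(target_genome, kept, fh)
    with open(out_dir / SUMMARY_JSON, "w") as fh:
        fh.write(summary.to_json())
    return summary


def validate(config: RunConfig) -> list[str]:
    """Dry-run diagnostics: formats, id cross-references, coordinate
    bounds.  Writes nothing; an empty list means a consistent world."""
    diagnostics: list[str] = []
    transcripts: list[SourceTranscript] = []
    source_genome = target_genome = None
    hits: list[AlignmentHit] = []

    try:
        transcripts = read_source_annotations(
            str(config.annotations), config.annotation_format
        )
    except Exception as exc:
        diagnostics.append(f"annotations: {exc}")
    try:
        source_genome = GenomeSequence.from_fasta(str(config.source_genome))
    except Exception as exc:
        diagnostics.append(f"source genome: {exc}")
    try:
        target_genome = GenomeSequence.from_fasta(str(config.target_genome))
    except Exception as exc:
        diagnostics.append(f"target genome: {exc}")
    try:
        hits = parse_alignment_table(str(config.alignments), strict=True)
    except Exception as exc:
        diagnostics.append(f"alignments: {exc}")

    if source_genome is not None:
        for t in transcripts:
            if t.chrom not in source_genome:
                diagnostics.append(
                    f"transcript {t.transcript_id}: chromosome {t.chrom} not in source genome"
                )
            elif t.tx_end > source_genome.length(t.chrom):
                diagnostics.append(
                    f"transcript {t.transcript_id}: exon end {t.tx_end} beyond "
                    f"{t.chrom} length {source_genome.length(t.chrom)}"
                )
    known = {t.transcript_id for t in transcripts}
    by_id = {t.transcript_id: t for t in transcripts}
    for h in hits:
        if h.transcript_id not in known:
            diagnostics.append(
                f"alignment references unknown transcript {h.transcript_id}"
            )
            continue
        if not 1 <= h.exon_index <= by_id[h.transcript_id].n_exons:
            diagnostics.append(
                f"alignment for {h.transcript_id} references exon {h.exon_index} "
                f"outside 1..{by_id[h.transcript_id].n_exons}"
            )
        if target_genome is not None:
            if h.target_chrom not in target_genome:
                diagnostics.append(
                    f"alignment for {h.transcript_id}|{h.exon_index}: chromosome "
                    f"{h.target_chrom} not in target genome"
                )
            elif h.target_end > target_genome.length(h.target_chrom):
                diagnostics.append(
                    f"alignment for {h.transcript_id}|{h.exon_index}: end "
                    f"{h.target_end} beyond {h.target_chrom}"
                )
    return diagnostics
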