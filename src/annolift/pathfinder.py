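"""Stage-wise shortest-path solver and annotation assembly.

Chooses one state (alignment hit or skip) per exon stage so that the
sum of one-step costs is minimal, normalizes the total into a 0-100
score, and turns the winning combination into a candidate annotation on
the target genome.  A brute-force enumerator with identical tie rules
serves as an independent oracle for testing.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation_io import CandidateAnnotation, SourceTranscript
from .blast_io import AlignmentHit, Stage
from .cost_model import CostParams, terminal_cost, transition_cost

__all__ = [
    "DPResult",
    "solve",
    "brute_force",
    "normalize_score",
    "assemble_annotation",
    "BruteForceGuardError",
]

log = logging.getLogger(__name__)

INF = math.inf

# tie-break key entry for a skipped stage: sorts after every real hit
_SKIP_KEY = (INF, INF)

#: brute_force refuses instances with more state combinations than this
BRUTE_FORCE_GUARD = 10**6


class BruteForceGuardError(Exception):
    pass


@dataclass(frozen=True)
class DPResult:
    """Shortest-path solution for one transcript.

    ``chosen_state_per_stage`` holds one entry per stage: the retained
    :class:`AlignmentHit` or ``None`` for skip.  All-skip solutions carry
    no coordinates and are marked infeasible.
    """

    chosen_state_per_stage: tuple[Optional[AlignmentHit], ...]
    f_star: float
    score: float
    feasible: bool

    @property
    def n_skips(self) -> int:
        return sum(1 for s in self.chosen_state_per_stage if s is None)

    @property
    def retained(self) -> tuple[AlignmentHit, ...]:
        return tuple(h for h in self.chosen_state_per_stage if h is not None)


def normalize_score(f_star: float, n: int) -> float:
    """(1 - f*/N) * 100; the optimal score for one transcript is 100."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return (1.0 - f_star / n) * 100.0


def _filtered_hits(
    stages: Sequence[Stage], fixed_chrom: Optional[str]
) -> list[list[AlignmentHit]]:
    if fixed_chrom is None:
        return [list(s.hits) for s in stages]
    return [[h for h in s.hits if h.target_chrom == fixed_chrom] for s in stages]


def _infeasible(n: int) -> DPResult:
    return DPResult((None,) * n, INF, -INF, False)


def _result(
    choices: tuple[Optional[int], ...],
    hitlists: Sequence[Sequence[AlignmentHit]],
    cost: float,
    n: int,
) -> DPResult:
    states = tuple(
        hitlists[i][k] if k is not None else None for i, k in enumerate(choices)
    )
    return DPResult(states, cost, normalize_score(cost, n), True)


def solve(
    stages: Sequence[Stage],
    transcript: SourceTranscript,
    params: CostParams | None = None,
    fixed_chrom: Optional[str] = None,
) -> DPResult:
    """Minimum-total-cost assignment of one state per stage.

    The recursion walks retained hits in stage order; skipped stages in
    between contribute the flat penalty K and defer the left hit's
    transition term until the next retained hit, where the bridged
    source span (skipped introns plus exons) is known.  ``fixed_chrom``
    restricts every stage to hits on that chromosome.

    Ties are broken deterministically: fewest skips, then leftmost
    target_start per stage, then hit input order.  Cost terms are summed
    strictly in stage order so results are bit-reproducible and match
    :func:`brute_force` exactly.
    """
    params = params or CostParams()
    n = len(stages)
    if n == 0:
        raise ValueError("stages must be non-empty")
    if n != transcript.n_exons:
        raise ValueError(
            f"{transcript.transcript_id}: {n} stages for {transcript.n_exons} exons"
        )
    hitlists = _filtered_hits(stages, fixed_chrom)
    if not any(hitlists):
        return _infeasible(n)

    k = params.K
    # label per (stage, hit): cost of all stage terms strictly before this
    # stage, plus bookkeeping for tie-breaks; this stage's own term is
    # charged when the label is extended (or finalized).
    # label = (cost, skips, key, choices)
    labels: dict[tuple[int, int], tuple] = {}

    def consider(slot, cand):
        cur = labels.get(slot)
        if cur is None or cand[:3] < cur[:3]:
            labels[slot] = cand

    for j in range(n):
        for kk, h in enumerate(hitlists[j]):
            cost = 0.0
            for _ in range(j):  # leading skipped stages, charged in order
                cost += k
            key = (_SKIP_KEY,) * j + ((h.target_start, kk),)
            consider((j, kk), (cost, j, key, (None,) * j + (kk,)))

    for i in range(n):
        for ki, a in enumerate(hitlists[i]):
            label = labels.get((i, ki))
            if label is None:
                continue
            cost_i, skips_i, key_i, choices_i = label
            for j in range(i + 1, n):
                span = transcript.span_between(i + 1, j + 1)
                bridged = j > i + 1
                for kj, b in enumerate(hitlists[j]):
                    step = transition_cost(
                        a, b, span, params, transcript.strand, bridged=bridged
                    )
                    if not math.isfinite(step):
                        continue
                    cost = cost_i + step
                    for _ in range(j - i - 1):  # intervening skips, in order
                        cost += k
                    key = key_i + (_SKIP_KEY,) * (j - i - 1) + ((b.target_start, kj),)
                    choices = choices_i + (None,) * (j - i - 1) + (kj,)
                    consider((j, kj), (cost, skips_i + j - i - 1, key, choices))

    best = None
    for (i, ki), (cost, skips, key, choices) in labels.items():
        total = cost + terminal_cost(hitlists[i][ki], params)
        for _ in range(n - 1 - i):  # trailing skipped stages
            total += k
        cand = (
            total,
            skips + (n - 1 - i),
            key + (_SKIP_KEY,) * (n - 1 - i),
            choices + (None,) * (n - 1 - i),
        )
        if math.isfinite(total) and (best is None or cand[:3] < best[:3]):
            best = cand
    if best is None:
        return _infeasible(n)
    return _result(best[3], hitlists, best[0], n)


def brute_force(
    stages: Sequence[Stage],
    transcript: SourceTranscript,
    params: CostParams | None = None,
    fixed_chrom: Optional[str] = None,
) -> DPResult:
    """Exhaustive oracle: enumerate every state combination.

    Shares the cost functions and tie rules with :func:`solve` but none
    of its recursion; refuses instances with more than
    ``BRUTE_FORCE_GUARD`` combinations.
    """
    params = params or CostParams()
    n = len(stages)
    if n == 0:
        raise ValueError("stages must be non-empty")
    hitlists = _filtered_hits(stages, fixed_chrom)
    n_combos = math.prod(len(h) + 1 for h in hitlists)
    if n_combos > BRUTE_FORCE_GUARD:
        raise BruteForceGuardError(
            f"{n_combos} combinations exceed guard {BRUTE_FORCE_GUARD}"
        )
    if not any(hitlists):
        return _infeasible(n)

    k = params.K
    best = None
    for combo in itertools.product(*(range(-1, len(h)) for h in hitlists)):
        retained = [(i, c) for i, c in enumerate(combo) if c >= 0]
        if not retained:
            continue  # all-skip: infeasible by decree
        cost = 0.0
        key = []
        feasible = True
        pos = 0  # index into retained
        for i, c in enumerate(combo):
            if c < 0:
                cost += k
                key.append(_SKIP_KEY)
                continue
            a = hitlists[i][c]
            key.append((a.target_start, c))
            pos += 1
            if pos < len(retained):
                jj, cj = retained[pos]
                b = hitlists[jj][cj]
                step = transition_cost(
                    a,
                    b,
                    transcript.span_between(i + 1, jj + 1),
                    params,
                    transcript.strand,
                    bridged=jj > i + 1,
                )
                if not math.isfinite(step):
                    feasible = False
                    break
                cost += step
            else:
                cost += terminal_cost(a, params)
        if not feasible:
            continue
        skips = n - len(retained)
        cand = (cost, skips, tuple(key), tuple(c if c >= 0 else None for c in combo))
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None:
        return _infeasible(n)
    return _result(best[3], hitlists, best[0], n)


def assemble_annotation(
    result: DPResult,
    transcript: SourceTranscript,
    name: Optional[str] = None,
) -> Optional[CandidateAnnotation]:
    """Turn a feasible path into a candidate annotation.

    Exon blocks are the target intervals of the retained hits, sorted by
    start.  All retained hits share one chromosome and orientation (a
    finite path guarantees it); since the aligned queries are
    transcription-sense sequences, the hit orientation *is* the
    annotation strand.  Returns ``None`` for infeasible results.
    """
    if not result.feasible:
        log.info("%s: infeasible path, transcript dropped", transcript.transcript_id)
        return None
    hits = result.retained
    chroms = {h.target_chrom for h in hits}
    strands = {h.strand for h in hits}
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError(
            f"{transcript.transcript_id}: retained hits span {chroms}/{strands}"
        )
    blocks = sorted((h.target_start, h.target_end) for h in hits)
    cleaned: list[tuple[int, int]] = []
    for start, end in blocks:
        if cleaned and start < cleaned[-1][1]:
            # small permitted overlaps between consecutive hits: clip the
            # earlier block so the table invariant (disjoint blocks) holds
            prev_start, _ = cleaned[-1]
            log.warning(
                "%s: overlapping blocks clipped at %d", transcript.transcript_id, start
            )
            if prev_start >= start:
                continue  # fully contained; drop the later block
            cleaned[-1] = (prev_start, start)
        cleaned.append((start, end))
    skipped = tuple(
        i + 1 for i, h in enumerate(result.chosen_state_per_stage) if h is None
    )
    return CandidateAnnotation(
        transcript_id=name or transcript.transcript_id,
        source_transcript_id=transcript.transcript_id,
        chrom=chroms.pop(),
        strand=strands.pop(),
        blocks=tuple(cleaned),
        score=result.score,
        canonical_flag="canonical",
        skipped_exons=skipped,
    )
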