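"""One-step cost of the stage-wise shortest-path model.

The transition cost between the chosen states of consecutive exon stages
combines three ingredients:

* a chromosome feasibility term (0 if both hits share a chromosome,
  infinite otherwise);
* a strand feasibility term (0 if both hits share an orientation,
  infinite otherwise);
* an alignment/position term ``1 - Align * Rela`` where
  ``Align = (align_length / exon_length) * exp(-evalue)`` measures the
  quality of the left hit and ``Rela = min(|d_src|, |d_tgt|) /
  max(|d_src|, |d_tgt|)`` compares the inter-exon distance on the source
  genome with the gap between the two hits on the target genome.

Skipping a stage costs the flat penalty ``K`` (default 0.95): always
cheaper than an infeasible stage, never cheaper than a good alignment.
All finite costs lie in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotation_io import SourceTranscript
from .blast_io import AlignmentHit

__all__ = [
    "SKIP",
    "END",
    "CostParams",
    "chr_dist",
    "strand_cost",
    "align_quality",
    "rela",
    "align_rela",
    "target_gap",
    "transition_cost",
    "terminal_cost",
    "one_step_cost",
]

INF = math.inf


class _Sentinel:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return f"<{self._name}>"


#: The per-stage skip state (no acceptable alignment for this exon).
SKIP = _Sentinel("skip")
#: The terminal pseudo-stage after the last exon.
END = _Sentinel("end")


@dataclass(frozen=True)
class CostParams:
    """Tunables of the cost model.

    K
        Penalty for skipping a stage.  Must be in (0, 1].
    skip_rela_policy
        How the distance-ratio term is computed across skipped stages:
        ``"bridge"`` compares the target gap against the source genomic
        span from the last retained exon's end to the next retained
        exon's start; ``"unit"`` takes the ratio as 1 across skips.
    clamp_align
        Clamp the alignment-quality factor at 1 (gapped alignments can
        report align_length > exon_length).
    max_overlap_frac
        Two consecutive retained hits overlapping by more than this
        fraction of either hit are vetoed with an infinite cost.
    """

    K: float = 0.95
    skip_rela_policy: str = "bridge"
    clamp_align: bool = True
    max_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.K <= 1:
            raise ValueError(f"K must be in (0, 1], got {self.K}")
        if self.skip_rela_policy not in ("bridge", "unit"):
            raise ValueError(f"bad skip_rela_policy {self.skip_rela_policy!r}")
        if not 0 <= self.max_overlap_frac <= 1:
            raise ValueError("max_overlap_frac must be in [0, 1]")


def chr_dist(a: AlignmentHit, b: AlignmentHit) -> float:
    """0 if the two hits share a target chromosome, else infinity."""
    return 0.0 if a.target_chrom == b.target_chrom else INF


def strand_cost(a: AlignmentHit, b: AlignmentHit) -> float:
    """0 if the two hits share an orientation, else infinity."""
    return 0.0 if a.strand == b.strand else INF


def align_quality(a: AlignmentHit, params: CostParams | None = None) -> float:
    """(align_length / exon_length) * exp(-evalue), in [0, 1]."""
    params = params or CostParams()
    if a.exon_length <= 0:
        raise ValueError(f"exon_length must be >= 1, got {a.exon_length}")
    q = (a.align_length / a.exon_length) * math.exp(-a.evalue)
    if params.clamp_align:
        q = min(q, 1.0)
    return q


def rela(dist_source: float, dist_target: float) -> float:
    """min/max ratio of two absolute distances, in [0, 1].

    Degenerate limits: 0/0 -> 1 (adjacent in both genomes); exactly one
    zero -> 0.  Inputs must already be absolute values.
    """
    if dist_source < 0 or dist_target < 0:
        raise ValueError("distances must be absolute (non-negative)")
    if dist_source == 0 and dist_target == 0:
        return 1.0
    if dist_source == 0 or dist_target == 0:
        return 0.0
    return min(dist_source, dist_target) / max(dist_source, dist_target)


def target_gap(a: AlignmentHit, b: AlignmentHit, ascending: bool) -> int:
    """Signed target-genome gap between consecutive hits.

    For an ascending chain (hit strand equals source transcript strand)
    exon i+1 sits to the right of exon i on the target, so the gap runs
    from a's end to b's start; for a descending chain the roles flip.
    """
    if ascending:
        return b.target_start - a.target_end
    return a.target_start - b.target_end


def _overlap_vetoed(a: AlignmentHit, b: AlignmentHit, params: CostParams) -> bool:
    ov = min(a.target_end, b.target_end) - max(a.target_start, b.target_start)
    if ov <= 0:
        return False
    return ov > params.max_overlap_frac * a.span or ov > params.max_overlap_frac * b.span


def align_rela(
    a: AlignmentHit,
    b: AlignmentHit,
    dist_source: int,
    params: CostParams | None = None,
    *,
    ascending: bool = True,
) -> float:
    """1 - Align(a) * Rela(dist_source, dist_target), in [0, 1]."""
    params = params or CostParams()
    gap = abs(target_gap(a, b, ascending))
    return 1.0 - align_quality(a, params) * rela(abs(dist_source), gap)


def transition_cost(
    a: AlignmentHit,
    b: AlignmentHit,
    dist_source: int,
    params: CostParams,
    transcript_strand: str,
    *,
    bridged: bool = False,
) -> float:
    """Full hit-to-hit cost: feasibility terms plus the Align*Rela term.

    ``bridged`` marks a transition across one or more skipped stages;
    under the ``unit`` policy the distance ratio is then taken as 1.
    """
    c = chr_dist(a, b) + strand_cost(a, b)
    if not math.isfinite(c):
        return INF
    if _overlap_vetoed(a, b, params):
        return INF
    ascending = a.strand == transcript_strand
    if bridged and params.skip_rela_policy == "unit":
        return c + (1.0 - align_quality(a, params))
    return c + align_rela(a, b, dist_source, params, ascending=ascending)


def terminal_cost(a: AlignmentHit, params: CostParams | None = None) -> float:
    """Cost of the step from the last retained hit to the End point.

    The distance ratio has no meaning at the terminus and is taken as 1,
    leaving 1 - Align(a).  This keeps one cost term per exon so the
    normalized score spans [0, 100].
    """
    return 1.0 - align_quality(a, params or CostParams())


def one_step_cost(
    state_a,
    state_b,
    transcript: SourceTranscript,
    params: CostParams | None = None,
) -> float:
    """Cost of one stage transition.

    ``state_a`` is an :class:`AlignmentHit` or :data:`SKIP`; ``state_b``
    is a hit of the next stage, :data:`SKIP`, or :data:`END`.  A skip
    state costs the flat penalty K regardless of what follows.  A hit
    followed by a skip returns 0 here: its transition term is charged
    lazily, when the solver reaches the next retained hit (or End) and
    the bridged distances are known.
    """
    params = params or CostParams()
    if state_a is SKIP:
        return params.K
    a = state_a
    if state_b is END:
        return terminal_cost(a, params)
    if state_b is SKIP:
        return 0.0  # deferred; resolved by the solver at the next retained hit
    b = state_b
    if b.exon_index != a.exon_index + 1:
        raise ValueError(
            f"one_step_cost needs consecutive stages, got exons "
            f"{a.exon_index} -> {b.exon_index}"
        )
    dist_source = transcript.intron_length(a.exon_index)
    return transition_cost(a, b, dist_source, params, transcript.strand)
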