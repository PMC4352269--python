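"""Shared fixtures: tiny hand-built worlds and random DP instances."""

from __future__ import annotations

import io

import numpy as np
import pytest

from annolift.annotation_io import GenomeSequence, SourceExon, SourceTranscript
from annolift.blast_io import AlignmentHit, Stage
from annolift.fixtures import (
    derive_target_genome,
    make_source_world,
    preset_spec,
    simulate_alignment_table,
)


def make_hit(
    exon_index=1,
    chrom="chr1",
    start=0,
    end=100,
    strand="+",
    evalue=0.0,
    align_length=None,
    exon_length=100,
    transcript_id="tx",
):
    return AlignmentHit(
        transcript_id=transcript_id,
        exon_index=exon_index,
        target_chrom=chrom,
        target_start=start,
        target_end=end,
        strand=strand,
        evalue=evalue,
        align_length=align_length if align_length is not None else end - start,
        exon_length=exon_length,
    )


def make_transcript(exon_coords, chrom="chr1", strand="+", transcript_id="tx"):
    exons = tuple(
        SourceExon(i, chrom, s, e) for i, (s, e) in enumerate(exon_coords, 1)
    )
    return SourceTranscript(transcript_id, "gene", chrom, strand, exons)


def random_instance(rng: np.random.Generator):
    """A small random DP instance (transcript + stages) for oracle tests.

    Bounded at <=5 stages and <=4 hits per stage so brute force stays
    within its combinatorial guard.
    """
    n = int(rng.integers(1, 6))
    pos = int(rng.integers(0, 50))
    coords = []
    for _ in range(n):
        length = int(rng.integers(30, 120))
        coords.append((pos, pos + length))
        pos += length + int(rng.integers(20, 300))
    strand = "+" if rng.random() < 0.5 else "-"
    transcript = make_transcript(coords, strand=strand)
    stages = []
    for i in range(1, n + 1):
        hits = []
        for k in range(int(rng.integers(0, 5))):
            length = coords[i - 1][1] - coords[i - 1][0]
            start = int(rng.integers(0, 2000))
            span = max(int(length * rng.uniform(0.4, 1.0)), 1)
            hits.append(
                make_hit(
                    exon_index=i,
                    chrom="chr" + str(int(rng.integers(1, 3))),
                    start=start,
                    end=start + span,
                    strand="+" if rng.random() < 0.5 else "-",
                    evalue=float(rng.choice([0.0, 1e-30, 1e-5, 0.5, 2.0])),
                    align_length=span,
                    exon_length=length,
                )
            )
        hits.sort(key=lambda h: (h.evalue, h.target_start))
        stages.append(Stage(i, tuple(hits)))
    return transcript, stages


@pytest.fixture(scope="session")
def identity_world():
    spec = preset_spec("identity", seed=1)
    world = make_source_world(spec)
    target = derive_target_genome(world, spec)
    buf = io.StringIO()
    simulate_alignment_table(world, target, spec, buf)
    return spec, world, target, buf.getvalue()


@pytest.fixture(scope="session")
def misassembly_world():
    spec = preset_spec("misassembly", seed=1)
    world = make_source_world(spec)
    target = derive_target_genome(world, spec)
    buf = io.StringIO()
    simulate_alignment_table(world, target, spec, buf)
    return spec, world, target, buf.getvalue()


@pytest.fixture
def toy_genome():
    return GenomeSequence({"chr1": "ACGTTT"})
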