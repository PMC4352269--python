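import io

import pytest

from annolift.annotation_io import extract_exon_sequences
from annolift.blast_io import build_stages, group_hits_by_transcript, parse_alignment_table
from annolift.fixtures import (
    FixtureSpec,
    derive_target_genome,
    make_source_world,
    preset_spec,
    simulate_alignment_table,
    write_world,
)
from annolift.pathfinder import assemble_annotation, solve
from annolift.quality_control import Junction, apply_quality_control, filter_by_score, is_canonical


def full_pipeline(spec):
    world = make_source_world(spec)
    target = derive_target_genome(world, spec)
    buf = io.StringIO()
    simulate_alignment_table(world, target, spec, buf)
    buf.seek(0)
    grouped = group_hits_by_transcript(parse_alignment_table(buf))
    annotations = {}
    for t in world.transcripts:
        r = solve(build_stages(t, grouped.get(t.transcript_id, [])), t)
        ann = assemble_annotation(r, t)
        if ann is not None:
            ann = apply_quality_control(target.genome, ann)
            if filter_by_score([ann]):
                annotations[t.transcript_id] = ann
    return world, target, annotations


class TestSourceWorld:
    def test_counts_and_ranges(self):
        spec = FixtureSpec(seed=3, n_genes=10, exons_per_gene=(3, 6))
        world = make_source_world(spec)
        assert len(world.transcripts) == 10
        for t in world.transcripts:
            assert 3 <= t.n_exons <= 6
            for e in t.exons:
                assert spec.exon_length[0] <= e.length <= spec.exon_length[1]
            for i in range(1, t.n_exons):
                assert spec.intron_length[0] <= t.intron_length(i) <= spec.intron_length[1]

    def test_all_introns_canonical(self):
        spec = FixtureSpec(seed=5)
        world = make_source_world(spec)
        for t in world.transcripts:
            for left, right in zip(t.exons, t.exons[1:]):
                j = Junction(t.chrom, left.end, right.start, t.strand)
                assert is_canonical(world.genome, j)

    def test_deterministic_bytes(self):
        spec = FixtureSpec(seed=11)
        a = make_source_world(spec)
        b = make_source_world(spec)
        for chrom in a.genome.chroms:
            assert a.genome.fetch(chrom, 0, a.genome.length(chrom)) == b.genome.fetch(
                chrom, 0, b.genome.length(chrom)
            )
        assert a.transcripts == b.transcripts

    def test_zero_genes(self):
        world = make_source_world(FixtureSpec(seed=1, n_genes=0))
        assert world.transcripts == []
        assert len(world.genome.chroms) == 2

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_source_world(FixtureSpec(seed=1, chrom_length=500, n_chroms=1))

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(substitution_rate=1.5)


class TestTargetWorld:
    def test_identity_is_exact_copy(self, identity_world):
        _, world, target, _ = identity_world
        for chrom in world.genome.chroms:
            n = world.genome.length(chrom)
            assert target.genome.length(chrom) == n
            assert target.genome.fetch(chrom, 0, n) == world.genome.fetch(chrom, 0, n)
        for (tid, idx), entry in target.truth.items():
            assert not entry.deleted

    def test_truth_marks_deleted_exons(self):
        spec = FixtureSpec(seed=2, skip_exon_prob=1.0)
        world = make_source_world(spec)
        target = derive_target_genome(world, spec)
        assert all(e.deleted for e in target.truth.values())

    def test_truth_intervals_carry_exon_sequence(self):
        spec = preset_spec("default", seed=3)
        world = make_source_world(spec)
        target = derive_target_genome(world, spec)
        checked = 0
        for t in world.transcripts:
            for e in t.exons:
                entry = target.truth[(t.transcript_id, e.index)]
                if entry.deleted:
                    continue
                src = world.genome.fetch(t.chrom, e.start, e.end)
                tgt = target.genome.fetch(entry.chrom, entry.start, entry.end)
                assert len(tgt) == len(src)
                mismatches = sum(1 for a, b in zip(src, tgt) if a != b)
                assert mismatches <= 0.15 * len(src)
                checked += 1
        assert checked > 20

    def test_duplications_produce_decoys(self):
        spec = FixtureSpec(seed=4, n_segmental_duplications=3)
        world = make_source_world(spec)
        target = derive_target_genome(world, spec)
        assert len(target.decoys) == 3
        for d in target.decoys:
            assert target.genome.length(d.chrom) >= d.end


class TestAlignmentTable:
    def test_twelve_columns_and_convention(self, identity_world):
        _, world, _, table = identity_world
        lines = table.splitlines()
        n_exons = sum(t.n_exons for t in world.transcripts)
        assert len(lines) == n_exons  # one hit per exon, no decoys/noise
        for line in lines:
            assert len(line.split("\t")) == 12
        hits = parse_alignment_table(io.StringIO(table))
        assert len(hits) == n_exons

    def test_duplication_adds_hits(self):
        spec = FixtureSpec(seed=4, n_segmental_duplications=3)
        world = make_source_world(spec)
        target = derive_target_genome(world, spec)
        buf = io.StringIO()
        n = simulate_alignment_table(world, target, spec, buf)
        assert n == sum(t.n_exons for t in world.transcripts) + 3

    def test_truth_hits_match_query_sequences(self, identity_world):
        _, world, target, table = identity_world
        grouped = group_hits_by_transcript(parse_alignment_table(io.StringIO(table)))
        t = world.transcripts[0]
        sense = extract_exon_sequences(world.genome, t)
        for h, qseq in zip(grouped[t.transcript_id], sense):
            tseq = target.genome.fetch(h.target_chrom, h.target_start, h.target_end)
            if h.strand == "-":
                from annolift.annotation_io import reverse_complement

                tseq = reverse_complement(tseq)
            assert tseq == qseq

    def test_deterministic(self):
        spec = preset_spec("default", seed=8)

        def render():
            world = make_source_world(spec)
            target = derive_target_genome(world, spec)
            buf = io.StringIO()
            simulate_alignment_table(world, target, spec, buf)
            return buf.getvalue()

        assert render() == render()


class TestEndToEnd:
    def test_identity_recovers_everything(self, identity_world):
        spec, world, target, table = identity_world
        _, _, annotations = full_pipeline(spec)
        assert len(annotations) == len(world.transcripts)
        for t in world.transcripts:
            ann = annotations[t.transcript_id]
            assert ann.blocks == tuple((e.start, e.end) for e in t.exons)
            assert ann.score == 100.0
            assert ann.canonical_flag == "canonical"

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_default_preset_recovery_at_least_95_percent(self, seed):
        spec = preset_spec("default", seed=seed)
        world, target, annotations = full_pipeline(spec)
        total = exact = 0
        for t in world.transcripts:
            ann = annotations.get(t.transcript_id)
            blocks = set(ann.blocks) if ann else set()
            for e in t.exons:
                entry = target.truth[(t.transcript_id, e.index)]
                if entry.deleted:
                    continue
                total += 1
                exact += (entry.start, entry.end) in blocks
        assert exact / total >= 0.95

    def test_decoy_robustness(self):
        spec = preset_spec("repeats", seed=2)
        world, target, annotations = full_pipeline(spec)
        decoy_intervals = {(d.chrom, d.start, d.end) for d in target.decoys}
        for ann in annotations.values():
            for s, e in ann.blocks:
                assert (ann.chrom, s, e) not in decoy_intervals


class TestWriteWorld:
    def test_artifacts_on_disk(self, tmp_path):
        paths = write_world(tmp_path / "w", preset_spec("identity", seed=1))
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        # text-only artifacts
        for p in paths.values():
            p.read_text()

    def test_disk_determinism(self, tmp_path):
        spec = preset_spec("default", seed=6)
        a = write_world(tmp_path / "a", spec)
        b = write_world(tmp_path / "b", spec)
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()
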