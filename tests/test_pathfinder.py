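import io
import math

import numpy as np
import pytest

from annolift.blast_io import Stage, build_stages, group_hits_by_transcript, parse_alignment_table
from annolift.cost_model import SKIP, END, CostParams, one_step_cost, terminal_cost, transition_cost
from annolift.pathfinder import (
    BruteForceGuardError,
    assemble_annotation,
    brute_force,
    normalize_score,
    solve,
)

from conftest import make_hit, make_transcript, random_instance


class TestNormalizeScore:
    def test_optimal_is_100(self):
        assert normalize_score(0.0, 1) == 100.0
        assert normalize_score(0.0, 7) == 100.0

    def test_formula_limit(self):
        assert normalize_score(3.0, 3) == 0.0

    def test_fractional(self):
        assert normalize_score(0.2 * 5, 5) == pytest.approx(80.0)


class TestSolveBasics:
    def test_single_perfect_hit(self):
        t = make_transcript([(0, 100)])
        stage = Stage(1, (make_hit(),))
        r = solve([stage], t)
        assert r.feasible and r.f_star == 0.0 and r.score == 100.0

    def test_single_weak_hit_scores_below_100(self):
        t = make_transcript([(0, 100)])
        stage = Stage(1, (make_hit(align_length=50),))
        r = solve([stage], t)
        assert r.f_star == pytest.approx(0.5)
        assert r.score == pytest.approx(50.0)

    def test_skip_contributes_exactly_k(self):
        t = make_transcript([(0, 100), (200, 300), (500, 600)])
        stages = [
            Stage(1, (make_hit(exon_index=1, start=0, end=100),)),
            Stage(2, ()),
            Stage(3, (make_hit(exon_index=3, start=500, end=600),)),
        ]
        r = solve(stages, t)
        assert r.feasible
        assert r.chosen_state_per_stage[1] is None
        assert r.f_star == pytest.approx(0.95)  # bridge rela is exact, ends cost 0

    def test_all_skip_is_infeasible(self):
        t = make_transcript([(0, 100), (200, 300)])
        r = solve([Stage(1, ()), Stage(2, ())], t)
        assert not r.feasible

    def test_fixed_chrom_excludes_other_hits(self):
        t = make_transcript([(0, 100)])
        stage = Stage(1, (make_hit(chrom="chr2"),))
        assert solve([stage], t, fixed_chrom="chr1").feasible is False
        assert solve([stage], t, fixed_chrom="chr2").feasible is True

    def test_skip_wins_over_infeasible_chromosome_switch(self):
        t = make_transcript([(0, 100), (200, 300)])
        stages = [
            Stage(1, (make_hit(exon_index=1, chrom="chr1"),)),
            Stage(2, (make_hit(exon_index=2, chrom="chr2", start=200, end=300),)),
        ]
        r = solve(stages, t)
        assert r.feasible
        assert sum(s is None for s in r.chosen_state_per_stage) == 1

    def test_dominated_hit_does_not_change_f_star(self):
        t = make_transcript([(0, 100), (200, 300)])
        good = make_hit(exon_index=1, start=1000, end=1100)
        partner = make_hit(exon_index=2, start=1200, end=1300)
        base = solve([Stage(1, (good,)), Stage(2, (partner,))], t)
        dominated = make_hit(exon_index=1, start=1000, end=1100, evalue=5.0)
        more = solve([Stage(1, (good, dominated)), Stage(2, (partner,))], t)
        assert more.f_star == base.f_star
        assert more.chosen_state_per_stage[0] == good


class TestOracleEquivalence:
    def test_100_random_instances_match_exactly(self):
        rng = np.random.default_rng(20240917)
        n_feasible = 0
        for _ in range(100):
            transcript, stages = random_instance(rng)
            a = solve(stages, transcript)
            b = brute_force(stages, transcript)
            assert a.feasible == b.feasible
            if a.feasible:
                n_feasible += 1
                assert a.f_star == b.f_star  # exact float equality
                assert a.chosen_state_per_stage == b.chosen_state_per_stage
        assert n_feasible > 50  # the generator must exercise real paths

    def test_oracle_with_fixed_chrom(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            transcript, stages = random_instance(rng)
            a = solve(stages, transcript, fixed_chrom="chr1")
            b = brute_force(stages, transcript, fixed_chrom="chr1")
            assert a.feasible == b.feasible
            if a.feasible:
                assert a.f_star == b.f_star
                assert a.chosen_state_per_stage == b.chosen_state_per_stage

    def test_guard_refuses_large_instances(self):
        t = make_transcript([(i * 200, i * 200 + 100) for i in range(8)])
        stages = [
            Stage(
                i + 1,
                tuple(
                    make_hit(exon_index=i + 1, start=k * 10, end=k * 10 + 100)
                    for k in range(9)
                ),
            )
            for i in range(8)
        ]
        with pytest.raises(BruteForceGuardError):
            brute_force(stages, t)


class TestBellmanConsistency:
    def test_returned_path_cost_decomposes(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(50):
            transcript, stages = random_instance(rng)
            r = solve(stages, transcript)
            if not r.feasible:
                continue
            params = CostParams()
            retained = [
                (i, h)
                for i, h in enumerate(r.chosen_state_per_stage)
                if h is not None
            ]
            total = 0.0
            for pos, (i, h) in enumerate(retained):
                if pos + 1 < len(retained):
                    j, nxt = retained[pos + 1]
                    total += transition_cost(
                        h,
                        nxt,
                        transcript.span_between(i + 1, j + 1),
                        params,
                        transcript.strand,
                        bridged=j > i + 1,
                    )
                else:
                    total += terminal_cost(h, params)
            total += params.K * (len(stages) - len(retained))
            assert total == pytest.approx(r.f_star, abs=1e-12)
            checked += 1
        assert checked > 20

    def test_score_bounds_for_feasible_results(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            transcript, stages = random_instance(rng)
            r = solve(stages, transcript)
            if r.feasible:
                assert 0.0 <= r.score <= 100.0
                if r.score == 100.0:
                    assert r.f_star == 0.0


class TestAssemble:
    def test_identity_blocks(self, identity_world):
        _, world, _, table = identity_world
        grouped = group_hits_by_transcript(parse_alignment_table(io.StringIO(table)))
        for t in world.transcripts:
            stages = build_stages(t, grouped[t.transcript_id])
            r = solve(stages, t)
            ann = assemble_annotation(r, t)
            assert ann is not None
            assert ann.blocks == tuple((e.start, e.end) for e in t.exons)
            assert ann.strand == t.strand
            assert ann.score == 100.0
            assert ann.skipped_exons == ()

    def test_skip_recorded(self):
        t = make_transcript([(0, 100), (200, 300), (500, 600)])
        stages = [
            Stage(1, (make_hit(exon_index=1),)),
            Stage(2, ()),
            Stage(3, (make_hit(exon_index=3, start=500, end=600),)),
        ]
        ann = assemble_annotation(solve(stages, t), t)
        assert len(ann.blocks) == 2
        assert ann.skipped_exons == (2,)

    def test_minus_target_strand_for_plus_source(self):
        t = make_transcript([(0, 100), (200, 300)])
        # descending chain on the minus strand of the target
        stages = [
            Stage(1, (make_hit(exon_index=1, strand="-", start=500, end=600),)),
            Stage(2, (make_hit(exon_index=2, strand="-", start=100, end=200),)),
        ]
        r = solve(stages, t)
        assert r.feasible
        ann = assemble_annotation(r, t)
        assert ann.strand == "-"
        assert ann.blocks == ((100, 200), (500, 600))  # sorted ascending

    def test_infeasible_returns_none(self):
        t = make_transcript([(0, 100)])
        assert assemble_annotation(solve([Stage(1, ())], t), t) is None


class TestStrandSymmetry:
    def test_minus_source_identity_chain(self):
        # identity placement of a minus-strand transcript: hits on "-",
        # ascending coordinates, must score 100
        t = make_transcript([(0, 100), (200, 300)], strand="-")
        stages = [
            Stage(1, (make_hit(exon_index=1, strand="-", start=0, end=100),)),
            Stage(2, (make_hit(exon_index=2, strand="-", start=200, end=300),)),
        ]
        r = solve(stages, t)
        assert r.feasible and r.f_star == 0.0 and r.score == 100.0
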