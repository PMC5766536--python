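"""Translated seed-and-extend search, locus merging and extension."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import brute_interval_union, sw_score

from ecrtmine.scoring import ScoringScheme
from ecrtmine.search import (
    HSP,
    extend_loci,
    merge_hit_loci,
    seeded_search,
    six_frame_translate,
)
from ecrtmine.seqio import GenomeRecord
from ecrtmine.synthetic import DecayModel, generate_background, plant_insertions


def _hsp(start, end, score=50.0, frame=1, genome="g"):
    return HSP("q", genome, frame, (start, end), (0, (end - start) // 3),
               score, 1e-10)


class TestSixFrameTranslate:
    def test_standard_code_with_stop(self):
        frames = {f.frame: f.protein for f in six_frame_translate("ATGAAATGA")}
        assert frames[1] == "MK*"

    def test_reverse_strand(self):
        frames = {f.frame: f.protein for f in six_frame_translate("CAT")}
        assert frames[-1] == "M"

    def test_n_codons_become_x(self):
        frames = {f.frame: f.protein for f in six_frame_translate("ATGNNATTT")}
        assert frames[1][1] == "X"

    @given(st.integers(min_value=0, max_value=50), st.integers(0, 2**31 - 1))
    def test_frame_length_arithmetic(self, n, seed):
        seq = generate_background(n, 0.5, seed)
        for f in six_frame_translate(seq):
            off = abs(f.frame) - 1
            assert len(f.protein) == max(0, (n - off)) // 3

    def test_coordinate_map_round_trips(self):
        seq = generate_background(300, 0.5, 3)
        from ecrtmine.seqio import reverse_complement

        for f in six_frame_translate(seq):
            for aa_start, aa_end in [(0, 5), (3, 20)]:
                if aa_end > len(f.protein):
                    continue
                s, e = f.to_genome(aa_start, aa_end)
                sub = seq[s:e]
                if f.frame < 0:
                    sub = reverse_complement(sub)
                frames = {x.frame: x.protein for x in six_frame_translate(sub)}
                assert frames[1] == f.protein[aa_start:aa_end]


class TestSeededSearch:
    def test_verbatim_planted_copy_recovered_at_full_identity(self, refs, scoring):
        query = refs.library[0].seq
        donor = refs.leaf_nt[refs.library[0].id]
        bg = generate_background(10_000, 0.4, 7)
        genome, truth = plant_insertions(
            bg, [("d", "caulimovirid", donor)], DecayModel(), seed=9
        )
        hsps = seeded_search(query, genome, scoring)
        assert hsps
        top = hsps[0]
        q_cov = (top.query_interval[1] - top.query_interval[0]) / len(query)
        assert q_cov >= 0.95
        assert top.genome_interval == truth[0].interval
        # score equals the full Smith-Waterman score of query vs its own
        # translation (perfect copy, no gaps)
        assert top.score == sw_score(query, query)

    def test_seeded_score_matches_full_dp_on_decayed_copy(self, refs, scoring):
        query = refs.library[2].seq
        donor = refs.leaf_nt[refs.library[2].id]
        bg = generate_background(8_000, 0.4, 17)
        genome, _ = plant_insertions(
            bg, [("d", "caulimovirid", donor)],
            DecayModel(sub_rate=0.10, seed=1), seed=19,
        )
        hsps = seeded_search(query, genome, scoring)
        assert hsps
        by_frame = {}
        for f in six_frame_translate(genome.seq):
            by_frame[f.frame] = sw_score(query, f.protein)
        best_frame = max(by_frame, key=by_frame.get)
        top = hsps[0]
        assert top.frame == best_frame
        assert abs(top.score - by_frame[best_frame]) <= 1.0

    def test_no_shared_kmer_yields_no_hits(self, scoring):
        genome = GenomeRecord("g", "A" * 3_000)
        assert seeded_search("W" * 50, genome, scoring) == []

    def test_empty_genome(self, scoring):
        assert seeded_search("MKWVMKWV", GenomeRecord("g", ""), scoring) == []


class TestEvalue:
    def test_closed_form(self):
        scheme = ScoringScheme(lam=0.267, K=0.041)
        expected = 0.041 * 240 * 1e6 * math.exp(-26.7)
        assert scheme.evalue(100, 240, 10**6) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_score(self):
        scheme = ScoringScheme()
        evs = [scheme.evalue(s, 240, 10**6) for s in range(50, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_gap_penalties_validated(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=0)


class TestMergeLoci:
    def test_overlap_union(self):
        loci = merge_hit_loci([_hsp(100, 400), _hsp(350, 600)])
        assert [(l.start, l.end) for l in loci] == [(100, 600)]

    def test_touching_halfopen_intervals_not_merged(self):
        loci = merge_hit_loci([_hsp(100, 400), _hsp(400, 600)])
        assert [(l.start, l.end) for l in loci] == [(100, 400), (400, 600)]

    def test_merging_ignores_frame_and_strand(self):
        loci = merge_hit_loci([_hsp(100, 400, frame=2), _hsp(200, 500, frame=-3)])
        assert [(l.start, l.end) for l in loci] == [(100, 500)]

    def test_mixed_genomes_rejected(self):
        with pytest.raises(ValueError):
            merge_hit_loci([_hsp(0, 30), _hsp(0, 30, genome="other")])

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 90)),
            min_size=1, max_size=30,
        )
    )
    def test_matches_brute_force_union_and_is_idempotent(self, raw):
        hsps = [_hsp(s, s + w) for s, w in raw]
        loci = merge_hit_loci(hsps)
        got = [(l.start, l.end) for l in loci]
        assert got == brute_interval_union([h.genome_interval for h in hsps])
        again = merge_hit_loci(
            [_hsp(s, e, score=l.best_score) for (s, e), l in zip(got, loci)]
        )
        assert [(l.start, l.end) for l in again] == got
        # disjoint and sorted
        for (s1, e1), (s2, e2) in zip(got, got[1:]):
            assert e1 <= s2

    def test_supporting_hsps_and_best_score_carried(self):
        loci = merge_hit_loci([_hsp(0, 90, 10.0), _hsp(30, 120, 99.0)])
        assert loci[0].best_score == 99.0
        assert len(loci[0].hsp_indices) == 2


class TestExtendLoci:
    def test_flank_widens_both_sides(self):
        loci = merge_hit_loci([_hsp(1000, 1600)])
        out = extend_loci(loci, genome_length=10_000, flank=120)
        assert (out[0].start, out[0].end) == (880, 1720)

    def test_clamped_at_origin(self):
        out = extend_loci(merge_hit_loci([_hsp(50, 200)]), 10_000, flank=120)
        assert (out[0].start, out[0].end) == (0, 320)

    def test_clamped_at_genome_end(self):
        out = extend_loci(merge_hit_loci([_hsp(900, 990)]), 1_000, flank=120)
        assert (out[0].start, out[0].end) == (780, 1000)

    def test_zero_flank_is_identity(self):
        loci = merge_hit_loci([_hsp(100, 400), _hsp(500, 700)])
        out = extend_loci(loci, 10_000, flank=0)
        assert [(l.start, l.end) for l in out] == [(100, 400), (500, 700)]

    def test_extension_remerges_created_overlaps(self):
        loci = merge_hit_loci([_hsp(100, 400), _hsp(500, 700)])
        out = extend_loci(loci, 10_000, flank=120)
        assert [(l.start, l.end) for l in out] == [(0, 820)]


class TestPlantedRecovery:
    def test_most_planted_copies_recovered_at_moderate_decay(self, scoring):
        """At 10% substitution decay nearly every planted caulimovirid copy
        still intersects a retained, extended locus."""
        from ecrtmine.pipeline import mine_genome
        from ecrtmine.synthetic import make_benchmark_bundle

        bundle = make_benchmark_bundle(
            seed=29, n_genomes=1, genome_length=200_000,
            n_caulimovirid=10, n_decoy=0,
            decay_model=DecayModel(sub_rate=0.10),
        )
        g = bundle.genomes[0]
        gm = mine_genome(g, bundle.library, scoring)
        truth = bundle.truth_for(g.id)
        hit = sum(
            1 for t in truth
            if any(l.start < t.end and t.start < l.end for l in gm.extended)
        )
        assert hit / len(truth) >= 0.90
        covered = sum(l.end - l.start for l in gm.extended)
        assert covered <= len(g)
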