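"""Translation filtering, reciprocal classification and pass-2 eligibility."""

import numpy as np
import pytest

from oracles import sw_score

from ecrtmine.classify import (
    align_protein,
    best_translation,
    classify_locus,
    pass2_threshold_bp,
    reciprocal_classify,
    select_for_placement,
)
from ecrtmine.seqio import LibraryProtein
from ecrtmine.synthetic import (
    DecayModel,
    decay,
    mutate_protein,
    random_protein,
    reverse_translate,
    translate_nt,
)


class TestBestTranslation:
    def test_clean_720_base_orf(self, rng):
        protein = random_protein(240, rng)
        nt = reverse_translate(protein, 1)
        cands = best_translation("L", nt, min_len=200)
        assert cands and cands[0].aa_sequence == protein
        assert cands[0].frame == 1 and cands[0].aa_length == 240

    def test_190_aa_segment_fails_200_filter(self, rng):
        nt = reverse_translate(random_protein(190, rng), 2)
        assert best_translation("L", nt, min_len=200) == []

    def test_internal_stop_splits_segments(self, rng):
        left = random_protein(210, rng)
        right = random_protein(30, rng)
        nt = reverse_translate(left, 3) + "TAA" + reverse_translate(right, 4)
        cands = best_translation("L", nt, min_len=200)
        assert [c.aa_sequence for c in cands if c.frame == 1] == [left]

    def test_segments_returned_longest_first(self, rng):
        a, b = random_protein(230, rng), random_protein(210, rng)
        nt = reverse_translate(a, 5) + "TGA" + reverse_translate(b, 6)
        lengths = [c.aa_length for c in best_translation("L", nt)]
        assert lengths == sorted(lengths, reverse=True)


class TestAlignProtein:
    def test_blosum62_diagonal_example(self, scoring):
        # M:5 K:5 W:11 V:4 on the BLOSUM62 diagonal
        score, aln_len, ident = align_protein("MKWV", "MKWV", scoring)
        assert (score, aln_len, ident) == (25.0, 4, 1.0)

    def test_self_alignment_identity(self, scoring, rng):
        p = random_protein(80, rng)
        _, _, ident = align_protein(p, p, scoring)
        assert ident == 1.0

    def test_score_matches_dp_oracle_on_random_pairs(self, scoring, rng):
        for i in range(30):
            a = random_protein(int(rng.integers(40, 120)), rng)
            b = (
                random_protein(int(rng.integers(40, 120)), rng)
                if i % 2
                else mutate_protein(a, 0.3, rng)
            )
            score, _, _ = align_protein(a, b, scoring)
            assert score == sw_score(a, b)

    def test_empty_sequence_rejected(self, scoring):
        with pytest.raises(ValueError):
            align_protein("", "MKWV", scoring)


def _decayed_protein(nt: str, sub_rate: float, seed: int) -> str:
    out, _ = decay(nt, DecayModel(sub_rate=sub_rate, seed=seed))
    prot = max(translate_nt(out).split("*"), key=len)
    return prot


class TestReciprocalClassify:
    def test_decayed_caulimovirid_copy_accepted(self, refs, scoring):
        nt = refs.leaf_nt["cauB1"]
        prot = _decayed_protein(nt, 0.05, 31)
        assert len(prot) >= 200
        cands = best_translation("L", reverse_translate(prot, 1))
        result = reciprocal_classify(cands[0], refs.library, scoring)
        assert result.status == "accepted"
        assert result.best_family == "caulimovirid"

    def test_decayed_gypsy_copy_rejected_by_family(self, refs, scoring):
        nt = refs.gypsy_nt["gypsy1"]
        prot = _decayed_protein(nt, 0.05, 37)
        cands = best_translation("L", reverse_translate(prot, 2))
        result = reciprocal_classify(cands[0], refs.library, scoring)
        assert result.status == "rejected_family"
        assert result.best_family == "gypsy_decoy"

    def test_short_alignment_rejected_by_length(self, refs, scoring):
        """A 150-aa fragment of a caulimovirid aligns over < 170 residues."""
        frag = refs.library[0].seq[:150]
        cands = best_translation("L", reverse_translate(frag, 3), min_len=100)
        result = reciprocal_classify(cands[0], refs.library, scoring)
        assert result.best_family == "caulimovirid"
        assert result.aln_len_aa < 170
        assert result.status == "rejected_length"

    def test_min_aln_monotonicity(self, refs, scoring):
        """Raising the minimum alignment length never grows the accepted set."""
        frags = [refs.library[i].seq[: 170 + 30 * i] for i in range(3)]
        accepted = []
        for min_aln in (150, 170, 200, 240):
            acc = set()
            for i, f in enumerate(frags):
                cands = best_translation(str(i), reverse_translate(f, i), min_len=100)
                r = reciprocal_classify(
                    cands[0], refs.library, scoring, min_aln=min_aln
                )
                if r.status == "accepted":
                    acc.add(i)
            accepted.append(acc)
        for small, large in zip(accepted[1:], accepted):
            assert small <= large

    def test_single_family_library_rejected(self, scoring, rng):
        lib = [LibraryProtein("x", "caulimovirid", random_protein(240, rng))]
        cands = best_translation("L", reverse_translate(lib[0].seq, 1))
        with pytest.raises(ValueError):
            reciprocal_classify(cands[0], lib, scoring)

    def test_every_locus_gets_exactly_one_status(self, refs, scoring, rng):
        statuses = set()
        for i in range(4):
            nt = reverse_translate(random_protein(250, rng), i)
            c = classify_locus(f"l{i}", nt, refs.library, scoring)
            assert c.status in {"accepted", "rejected_family", "rejected_length"}
            statuses.add(c.status)
        assert statuses  # partition covered, no locus unclassified


class TestPass2:
    def test_generic_threshold_is_576_bp(self):
        assert pass2_threshold_bp(240, 0.8) == 576

    def test_span_600_of_240aa_subject_is_eligible(self, refs, scoring):
        """A verbatim 200-aa fragment aligns over 600 nt >= 576."""
        subject = refs.library[0]
        frag_nt = refs.leaf_nt[subject.id][:600]
        eligible, span, best = select_for_placement(
            "L", frag_nt, refs.library, scoring
        )
        assert span == 600
        assert eligible and best == subject.id

    def test_span_500_of_240aa_subject_is_not_eligible(self, refs, scoring):
        frag_nt = refs.leaf_nt[refs.library[0].id][:498]  # 166 codons
        eligible, span, _ = select_for_placement("L", frag_nt, refs.library, scoring)
        assert span < 576 and not eligible

    def test_per_subject_scaling_for_longer_subjects(self, scoring, rng):
        """700 nt of a 300-aa subject misses 0.8 * 900 = 720."""
        long_prot = random_protein(300, rng)
        decoy = random_protein(240, rng)
        lib = [
            LibraryProtein("caulong", "caulimovirid", long_prot),
            LibraryProtein("gy", "gypsy_decoy", decoy),
        ]
        frag_nt = reverse_translate(long_prot[:233], 1)  # 699 nt span
        eligible, span, best = select_for_placement("L", frag_nt, lib, scoring)
        assert best == "caulong" and span < 720
        assert not eligible
        assert pass2_threshold_bp(300, 0.8) == 720

    def test_gypsy_best_hit_is_never_eligible(self, refs, scoring):
        frag_nt = refs.gypsy_nt["gypsy2"]
        eligible, _, best = select_for_placement("L", frag_nt, refs.library, scoring)
        assert best.startswith("gypsy")
        assert not eligible

    def test_pseudogenized_locus_recovered_by_pass2_not_pass1(self, refs, scoring):
        """Premature stops destroy every long ORF, but the translated
        alignment crosses them at matrix cost, so the locus stays eligible
        at the nucleotide level — the motivation for the second pass."""
        nt = refs.leaf_nt["cauA3"]
        decayed, log = decay(nt, DecayModel(stop_rate=3.0, seed=41))
        assert any(e[0] == "stop" for e in log)
        c = classify_locus("L", decayed, refs.library, scoring)
        eligible, span, _ = select_for_placement("L", decayed, refs.library, scoring)
        assert c.status == "rejected_length"  # no intact >= 200 aa segment
        assert eligible and span >= 576
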