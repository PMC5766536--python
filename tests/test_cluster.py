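"""Pairwise identity, greedy clustering, alignment filtering, networks."""

import numpy as np
import pytest

from oracles import semiglobal_score, union_find_components

from ecrtmine.cluster import (
    build_network,
    delineate_otus,
    filter_alignment,
    greedy_cluster,
    pairwise_identity,
)
from ecrtmine.synthetic import mutate_protein, random_protein


def _family(ancestor: str, n: int, frac: float, rng) -> dict[str, str]:
    return {f"s{i}": mutate_protein(ancestor, frac, rng) for i in range(n)}


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("AAAA", "AAAA") == 1.0

    def test_one_mismatch_in_four_columns(self):
        assert pairwise_identity("AAAA", "AATA") == 0.75

    def test_symmetric(self, rng):
        a = random_protein(60, rng)
        b = mutate_protein(a, 0.2, rng)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_terminal_gaps_excluded_for_fragment(self, rng):
        """A verbatim internal fragment scores identity 1.0 — the columns
        outside the fragment are terminal gaps and leave the denominator."""
        a = random_protein(100, rng)
        assert pairwise_identity(a, a[25:75]) == 1.0

    def test_gapless_pairs_match_hamming_closed_form(self, rng):
        """For equal-length mutated copies the optimal free-end-gap
        alignment is the ungapped one, so identity equals the Hamming
        fraction; the alignment score equals the DP oracle's."""
        from ecrtmine.scoring import ScoringScheme

        scheme = ScoringScheme()
        for i in range(20):
            a = random_protein(50, rng)
            b = a[:5] + mutate_protein(a[5:-5], 0.2, rng) + a[-5:]
            hamming = sum(x == y for x, y in zip(a, b)) / 50
            assert pairwise_identity(a, b, scheme) == hamming
            got = float(scheme.semiglobal_aligner().align(a, b)[0].score)
            assert got == semiglobal_score(a, b)

    def test_alternative_denominator_flag(self, rng):
        a = random_protein(80, rng)
        frag = a[10:50]
        assert pairwise_identity(a, frag, denominator="shorter") == 1.0
        with pytest.raises(ValueError):
            pairwise_identity(a, frag, denominator="bogus")


class TestGreedyCluster:
    def test_identical_set_collapses_to_one_cluster(self, rng):
        p = random_protein(60, rng)
        clusters = greedy_cluster({f"s{i}": p for i in range(5)}, 0.8)
        assert len(clusters) == 1 and len(clusters[0]) == 5

    def test_threshold_one_gives_singletons(self, rng):
        seqs = {f"s{i}": random_protein(50, rng) for i in range(4)}
        clusters = greedy_cluster(seqs, 1.0)
        assert len(clusters) == 4

    def test_two_divergent_families_split_at_55(self, rng):
        """Families built from unrelated ancestors sit below 40% mutual
        identity (checked exhaustively) and form exactly two clusters."""
        fam_a = _family(random_protein(240, rng), 4, 0.1, rng)
        fam_b = {
            k + "b": v
            for k, v in _family(random_protein(240, rng), 4, 0.1, rng).items()
        }
        seqs = {**fam_a, **fam_b}
        for ka in fam_a:
            for kb in fam_b:
                assert pairwise_identity(seqs[ka], seqs[kb]) <= 0.40
        clusters = greedy_cluster(seqs, 0.55)
        assert len(clusters) == 2
        member_sets = sorted(sorted(c.members) for c in clusters)
        assert member_sets == [sorted(fam_a), sorted(fam_b)]

    def test_representative_is_longest_member(self, rng):
        base = random_protein(100, rng)
        seqs = {"long": base + "AAAA", "short": base}
        clusters = greedy_cluster(seqs, 0.5)
        assert clusters[0].representative == "long"

    def test_deterministic_across_runs(self, rng):
        seqs = {f"s{i}": random_protein(80, rng) for i in range(6)}
        a = [sorted(c.members) for c in greedy_cluster(seqs, 0.3)]
        b = [sorted(c.members) for c in greedy_cluster(seqs, 0.3)]
        assert a == b

    def test_every_sequence_in_exactly_one_cluster(self, rng):
        seqs = {f"s{i}": random_protein(60, rng) for i in range(9)}
        clusters = greedy_cluster(seqs, 0.4)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(seqs)

    def test_invalid_threshold(self, rng):
        with pytest.raises(ValueError):
            greedy_cluster({"a": "MKWV"}, 0.0)


class TestFilterAlignment:
    def test_ungapped_identical_alignment_unchanged(self, rng):
        row = random_protein(100, rng)
        msa = {f"s{i}": row for i in range(5)}
        out = filter_alignment(msa)
        assert out.rows == msa and not out.emptied

    def test_sparse_sequence_removed(self, rng):
        full = random_protein(100, rng)
        sparse = full[:10] + "-" * 90
        msa = {f"s{i}": full for i in range(10)}
        msa["sparse"] = sparse
        out = filter_alignment(msa)
        assert "sparse" in out.dropped_sequences
        assert len(out.rows) == 10

    def test_majority_gap_column_removed(self, rng):
        core = random_protein(20, rng)
        msa = {}
        for i in range(10):
            # column 5 is a gap in 6 of 10 rows: 0.4 non-gap < 0.5
            row = list(core)
            if i < 6:
                row[5] = "-"
            msa[f"s{i}"] = "".join(row)
        out = filter_alignment(msa)
        assert 5 in out.dropped_columns
        assert all(len(r) == 19 for r in out.rows.values())

    def test_idempotent(self, rng):
        full = random_protein(60, rng)
        msa = {f"s{i}": full for i in range(6)}
        msa["bad"] = full[:5] + "-" * 55
        once = filter_alignment(msa)
        twice = filter_alignment(once.rows)
        assert twice.rows == once.rows

    def test_emptied_alignment_flagged_not_raised(self):
        msa = {"a": "MK--------", "b": "--------WV"}
        out = filter_alignment(msa)
        assert out.emptied

    def test_non_rectangular_rejected(self):
        with pytest.raises(ValueError):
            filter_alignment({"a": "MKWV", "b": "MKW"})


class TestNetwork:
    def test_two_families_two_components(self, rng):
        fam_a = _family(random_protein(120, rng), 3, 0.1, rng)
        fam_b = {
            k + "b": v for k, v in _family(random_protein(120, rng), 3, 0.1, rng).items()
        }
        net = build_network({**fam_a, **fam_b}, 0.5)
        assert net.n_components == 2

    def test_chain_connects_transitively(self, rng):
        """a-b and b-c sit above threshold while a-c sits below, yet all
        three share one component."""
        a = random_protein(150, rng)
        b = mutate_protein(a, 0.25, rng)
        c = mutate_protein(b, 0.25, rng)
        t = 0.6
        assert pairwise_identity(a, b) >= t
        assert pairwise_identity(b, c) >= t
        assert pairwise_identity(a, c) < t
        net = build_network({"a": a, "b": b, "c": c}, t)
        assert net.n_components == 1

    def test_components_match_union_find_oracle(self, rng):
        seqs = {}
        for fam in range(3):
            seqs.update(
                {
                    f"f{fam}s{i}": s
                    for i, s in enumerate(
                        _family(random_protein(90, rng), 3, 0.15, rng).values()
                    )
                }
            )
        t = 0.5
        net = build_network(seqs, t)
        ids = sorted(seqs)
        edges = [
            (a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if pairwise_identity(seqs[a], seqs[b]) >= t
        ]
        assert net.components == union_find_components(ids, edges)

    def test_component_count_monotone_in_threshold(self, rng):
        seqs = {
            f"s{i}": mutate_protein(random_protein(100, rng), 0.1, rng)
            for i in range(6)
        }
        counts = [build_network(seqs, t).n_components for t in (0.9, 0.6, 0.3, 0.05)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_network({}, 0.5)


class TestDelineateOTUs:
    def test_stable_otu_set_on_two_family_pool(self, rng):
        fam_a = _family(random_protein(200, rng), 5, 0.12, rng)
        fam_b = {
            k + "b": v
            for k, v in _family(random_protein(200, rng), 5, 0.12, rng).items()
        }
        clusters, network = delineate_otus(
            {**fam_a, **fam_b}, cluster_id=0.55, network_id=0.35
        )
        assert network.n_components == 2
        reps = {c.representative for c in clusters}
        assert set(network.nodes) == reps
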