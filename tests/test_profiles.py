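import numpy as np
import pytest

from gridmsa.fastlsa import FastLsaParams, Mode
from gridmsa.generate import random_family
from gridmsa.io_formats import Msa
from gridmsa.pipeline import align_sequences
from gridmsa.profiles import (PROFILE_ROWS, Profile, ProfilePairTask,
                              build_profile, merge_groups, prfscore,
                              profile_align, profile_align_scored,
                              progressive_align)
from gridmsa.scoring import SCALE, ScoringScheme
from gridmsa.tree import SequenceWeights, compute_weights, midpoint_root, \
    nj_build
from gridmsa.pairwise import build_distance_matrix

from .conftest import make_record, make_scorer, oracle_inputs, random_dna
from .oracle import gotoh_align, rescore_moves


def unit_weights(*ids):
    return SequenceWeights({i: 1.0 for i in ids})


def single_profile(residues, scheme, rid="s"):
    return build_profile(Msa([(rid, residues)]), unit_weights(rid), scheme)


class TestBuildProfile:
    def test_profile_has_35_rows(self, dna_scheme):
        msa = Msa([("a", "AC-GT"), ("b", "ACAGT")])
        p = build_profile(msa, unit_weights("a", "b"), dna_scheme)
        assert p.data.shape == (PROFILE_ROWS, 5)

    def test_35_rows_for_protein_too(self):
        scheme = ScoringScheme.protein()
        msa = Msa([("a", "MKV"), ("b", "MRV")])
        p = build_profile(msa, unit_weights("a", "b"), scheme)
        assert p.data.shape[0] == PROFILE_ROWS

    def test_single_sequence_columns_are_matrix_rows(self, dna_scheme):
        p = single_profile("ACGT", dna_scheme)
        assert p.m == 4
        a_idx = dna_scheme.residues.index("A")
        expect = dna_scheme.matrix[a_idx]
        L = len(dna_scheme.residues)
        assert np.allclose(p.score_rows[:L, 0], expect)
        assert np.all(p.score_rows[L:, :] == 0)

    def test_all_gap_column_is_zero(self, dna_scheme):
        msa = Msa([("a", "A-T"), ("b", "A-T")])
        p = build_profile(msa, unit_weights("a", "b"), dna_scheme)
        assert np.all(p.score_rows[:, 1] == 0)
        assert np.all(p.freq[:, 1] == 0)

    def test_gap_columns_dilute_penalties(self, dna_scheme):
        msa = Msa([("a", "A-T"), ("b", "AAT")])
        p = build_profile(msa, unit_weights("a", "b"), dna_scheme)
        assert p.gap_open[1] == pytest.approx(dna_scheme.gap_open
                                              * (1 - 0.7 * 0.5))
        assert p.gap_open[0] == pytest.approx(dna_scheme.gap_open)

    def test_missing_weight_rejected(self, dna_scheme):
        msa = Msa([("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(ValueError, match="weight"):
            build_profile(msa, unit_weights("a"), dna_scheme)


class TestPrfscore:
    def test_single_sequence_profiles_give_matrix_score(self):
        scheme = ScoringScheme.protein()
        p1 = single_profile("MKV", scheme, "a")
        p2 = single_profile("RWC", scheme, "b")
        for i, x in enumerate("MKV"):
            for j, y in enumerate("RWC"):
                assert prfscore(p1, p2, i, j) == pytest.approx(
                    scheme.score(x, y))

    def test_all_gap_column_scores_zero(self, dna_scheme):
        p1 = build_profile(Msa([("a", "A-T"), ("b", "A-T")]),
                           unit_weights("a", "b"), dna_scheme)
        p2 = single_profile("ACG", dna_scheme, "c")
        assert prfscore(p1, p2, 1, 0) == 0.0

    def test_symmetry_on_random_columns(self, dna_scheme):
        fam = random_family(n=4, length=40, seed=21)
        res = align_sequences(fam)
        half = Msa(res.msa.rows[:2]), Msa(res.msa.rows[2:])
        w = res.weights
        p1 = build_profile(half[0], w, dna_scheme)
        p2 = build_profile(half[1], w, dna_scheme)
        rng = np.random.default_rng(0)
        for _ in range(100):
            i = int(rng.integers(p1.m))
            j = int(rng.integers(p2.m))
            assert prfscore(p1, p2, i, j) == pytest.approx(
                prfscore(p2, p1, j, i))


class TestProfileAlign:
    def test_two_single_profiles_equal_global_pairwise(self, dna_scheme):
        rng = np.random.default_rng(55)
        for _ in range(10):
            a = random_dna(rng, int(rng.integers(10, 50)))
            b = random_dna(rng, int(rng.integers(10, 50)))
            task = ProfilePairTask(
                p1=single_profile(a, dna_scheme, "a"),
                p2=single_profile(b, dna_scheme, "b"),
                group_a=Msa([("a", a)]), group_b=Msa([("b", b)]))
            msa, score, moves = profile_align_scored(task)
            oscore, omoves, *_ = gotoh_align(
                *oracle_inputs(a, b, dna_scheme))
            assert moves == omoves
            assert round(score * SCALE) == oscore

    def test_self_alignment_introduces_no_gaps(self, dna_scheme):
        fam = random_family(n=3, length=60, seed=8)
        res = align_sequences(fam)
        group = res.msa
        p = build_profile(group, res.weights, dna_scheme)
        copy_rows = [(rid + "_2", seq) for rid, seq in group.rows]
        p2 = build_profile(Msa(copy_rows),
                           SequenceWeights({rid + "_2": res.weights[rid]
                                            for rid in group.ids}),
                           dna_scheme)
        task = ProfilePairTask(p1=p, p2=p2, group_a=group,
                               group_b=Msa(copy_rows))
        msa, score, moves = profile_align_scored(task)
        assert moves == ["D"] * group.length
        assert msa.length == group.length

    def test_fragment_policy_changes_nothing(self, dna_scheme):
        fam = random_family(n=4, length=120, seed=10)
        base = align_sequences(fam, fragment_policy=False)
        frag = align_sequences(fam, fragment_policy=True)
        assert base.msa.rows == frag.msa.rows

    def test_merge_score_matches_columnwise_rescoring(self, dna_scheme):
        """Each merge's corner DP value equals an independent affine
        rescoring of its move path with prfscore and the profile gap rows."""
        fam = random_family(n=5, length=100, seed=12)
        dm, _ = build_distance_matrix(fam)
        rooted = midpoint_root(nj_build(dm))
        weights = compute_weights(rooted)
        msa, records = progressive_align(fam, rooted, weights, dna_scheme)
        groups = {frozenset({rec.id}): Msa([(rec.id, rec.residues)])
                  for rec in fam}
        from gridmsa.tree import traversal_schedule
        for step, rec in zip(traversal_schedule(rooted), records):
            ga, gb = groups.pop(step.left), groups.pop(step.right)
            p1 = build_profile(ga, weights, dna_scheme)
            p2 = build_profile(gb, weights, dna_scheme)
            from gridmsa.profiles import ProfilePairScorer
            sc = ProfilePairScorer(p1, p2)
            sub = sc.sub_block(0, p1.m, 0, p2.m)
            total = rescore_moves(
                rec.moves, (0, 0), sub,
                list(sc.gap_open_a), list(sc.gap_ext_a),
                list(sc.gap_open_b), list(sc.gap_ext_b))
            assert total == round(rec.score * SCALE)
            groups[step.members] = rec.msa


class TestProgressiveAlign:
    def test_two_sequences_reduce_to_global_pairwise(self, dna_scheme):
        fam = random_family(n=2, length=150, seed=14)
        res = align_sequences(fam)
        a, b = fam[0].residues, fam[1].residues
        _score, moves, origin, _ = gotoh_align(
            *oracle_inputs(a, b, dna_scheme))
        from gridmsa.fastlsa import moves_to_strings
        ga, gb = moves_to_strings(a, b, moves, origin)
        assert res.msa.row(fam.ids[0]) == ga
        assert res.msa.row(fam.ids[1]) == gb

    def test_identical_sequences_stay_gapless(self):
        fam = random_family(n=5, length=90, sub_rate=0.0, indel_rate=0.0,
                            seed=15)
        res = align_sequences(fam)
        assert res.msa.length == 90
        assert all("-" not in seq for _, seq in res.msa.rows)

    def test_rows_strip_back_to_inputs(self):
        fam = random_family(n=4, length=200, seed=16)
        res = align_sequences(fam)
        for rec in fam:
            assert res.msa.stripped(rec.id) == rec.residues

    def test_rows_in_input_order(self, small_family):
        res = align_sequences(small_family)
        assert res.msa.ids == small_family.ids

    def test_mismatched_tree_rejected(self, dna_scheme, small_family):
        other = random_family(n=6, length=100, seed=99, id_prefix="x")
        dm, _ = build_distance_matrix(other)
        rooted = midpoint_root(nj_build(dm))
        with pytest.raises(ValueError, match="leaves"):
            progressive_align(small_family, rooted,
                              compute_weights(rooted), dna_scheme)

    def test_invariant_under_k_and_workers(self):
        from gridmsa.scheduler import Scheduler

        fam = random_family(n=5, length=120, seed=17)
        base = align_sequences(fam)
        for kwargs in ({"params": FastLsaParams(k=3)},
                       {"sched": Scheduler(workers=4)},
                       {"params": FastLsaParams(k=7),
                        "sched": Scheduler(workers=2)}):
            res = align_sequences(fam, **kwargs)
            assert res.msa.rows == base.msa.rows
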