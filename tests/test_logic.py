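import random

import pytest

from conftest import mk_hsp, random_session, run_from_hsps
from oracles import brute_common, brute_cross, brute_multiple, brute_rbh
from reciblast.filtering import FilterSpec
from reciblast.logic import (
    ReciprocalSession,
    common_hits,
    cross_pairs,
    multiple_region_hits,
    reciprocal_best_hits,
    session_summary,
)
from reciblast.model import DataError, Direction, NotFoundError


def session_of(hsps_ab, hsps_ba, lens_a=None, lens_b=None):
    return ReciprocalSession.from_runs(
        run_from_hsps(hsps_ab, Direction.A_VS_B, lens_a),
        run_from_hsps(hsps_ba, Direction.B_VS_A, lens_b),
    )


def figure_session():
    """A2 hits {B1, B2}; A3 hits {B2, B3} — the textbook shared-hit case."""
    hsps = [
        mk_hsp(qid="A2", sid="B1"),
        mk_hsp(qid="A2", sid="B2"),
        mk_hsp(qid="A3", sid="B2"),
        mk_hsp(qid="A3", sid="B3"),
    ]
    return session_of(hsps, [])


class TestCommon:
    def test_intersection_of_two_queries(self):
        rows = common_hits(figure_session(), Direction.A_VS_B, ["A2", "A3"])
        assert [sid for sid, _ in rows] == ["B2"]
        (_, support) = rows[0]
        assert set(support) == {"A2", "A3"}
        assert all(hs for hs in support.values())

    def test_single_query_returns_all_its_subjects(self):
        rows = common_hits(figure_session(), Direction.A_VS_B, ["A2"])
        assert [sid for sid, _ in rows] == ["B1", "B2"]

    def test_unknown_query_and_empty_selection_error(self):
        s = figure_session()
        with pytest.raises(NotFoundError, match="A99"):
            common_hits(s, Direction.A_VS_B, ["A99"])
        with pytest.raises(DataError):
            common_hits(s, Direction.A_VS_B, [])

    def test_intersection_law_against_bruteforce(self):
        rng = random.Random(17)
        for _ in range(30):
            session, hsps_ab, _ = random_session(rng)
            qids = list(session.run_ab.query_results)
            if not qids:
                continue
            selected = rng.sample(qids, min(len(qids), rng.randint(2, 4)))
            got = {sid for sid, _ in common_hits(session, Direction.A_VS_B, selected)}
            assert got == brute_common(hsps_ab, selected)
            # ∩ of singletons equals the joint selection
            single = [
                {sid for sid, _ in common_hits(session, Direction.A_VS_B, [q])}
                for q in selected
            ]
            assert got == set.intersection(*single)


class TestCross:
    def test_reciprocal_pair_emitted(self):
        s = session_of([mk_hsp(qid="A1", sid="B2")], [mk_hsp(qid="B2", sid="A1")])
        (p,) = cross_pairs(s)
        assert (p.a_id, p.b_id) == ("A1", "B2") and p.is_rbh

    def test_one_directional_match_excluded(self):
        s = session_of([mk_hsp(qid="A1", sid="B2")], [mk_hsp(qid="B2", sid="A9", s_len=100)])
        assert cross_pairs(s) == []

    def test_mutual_match_without_mutual_best_is_cross_not_rbh(self):
        hsps_ab = [mk_hsp(qid="A1", sid="B1", evalue=1e-50)]
        hsps_ba = [
            mk_hsp(qid="B1", sid="A9", evalue=1e-80),
            mk_hsp(qid="B1", sid="A1", evalue=1e-40),
        ]
        (p,) = cross_pairs(session_of(hsps_ab, hsps_ba))
        assert not p.is_rbh
        assert reciprocal_best_hits(session_of(hsps_ab, hsps_ba)) == []

    def test_ties_resolved_by_bitscore_then_subject_id(self):
        hsps_ab = [
            mk_hsp(qid="A1", sid="B1", evalue=1e-50, bitscore=200),
            mk_hsp(qid="A1", sid="B2", evalue=1e-50, bitscore=300),
        ]
        hsps_ba = [
            mk_hsp(qid="B2", sid="A1", evalue=1e-50),
            mk_hsp(qid="B1", sid="A1", evalue=1e-50),
        ]
        rbh = reciprocal_best_hits(session_of(hsps_ab, hsps_ba))
        assert [(p.a_id, p.b_id) for p in rbh] == [("A1", "B2")]

    def test_swapping_runs_gives_same_unordered_pairs(self):
        rng = random.Random(23)
        for _ in range(20):
            session, hsps_ab, hsps_ba = random_session(rng)
            fwd = {(p.a_id, p.b_id) for p in cross_pairs(session)}
            swapped = ReciprocalSession.from_runs(
                run_from_hsps(hsps_ba, Direction.A_VS_B),
                run_from_hsps(hsps_ab, Direction.B_VS_A),
            )
            rev = {(p.b_id, p.a_id) for p in cross_pairs(swapped)}
            assert fwd == rev

    def test_rbh_subset_of_cross(self):
        rng = random.Random(29)
        for _ in range(20):
            session, *_ = random_session(rng)
            cross = {(p.a_id, p.b_id) for p in cross_pairs(session)}
            rbh = {(p.a_id, p.b_id) for p in reciprocal_best_hits(session)}
            assert rbh <= cross

    def test_each_sequence_in_at_most_one_rbh_pair(self):
        rng = random.Random(31)
        for _ in range(20):
            session, *_ = random_session(rng)
            rbh = reciprocal_best_hits(session)
            a_side = [p.a_id for p in rbh]
            b_side = [p.b_id for p in rbh]
            assert len(a_side) == len(set(a_side)) and len(b_side) == len(set(b_side))

    def test_self_session_excludes_trivial_pair(self):
        hsps = [
            mk_hsp(qid="X", sid="X", evalue=1e-100),
            mk_hsp(qid="X", sid="Y", evalue=1e-50),
            mk_hsp(qid="Y", sid="Y", evalue=1e-100),
            mk_hsp(qid="Y", sid="X", evalue=1e-50),
        ]
        session = ReciprocalSession.from_runs(run_from_hsps(hsps, Direction.SELF))
        pairs = cross_pairs(session)
        assert [(p.a_id, p.b_id) for p in pairs] == [("X", "Y")]
        # the self-match does not block mutual-best ranking
        assert pairs[0].is_rbh

    def test_sum_bitscore_ranking_option(self):
        # two weak HSPs on B1 outweigh one strong on B2 under summed bitscore
        hsps_ab = [
            mk_hsp(qid="A1", sid="B1", evalue=1e-20, bitscore=150, q_start=1, q_end=40),
            mk_hsp(qid="A1", sid="B1", evalue=1e-20, bitscore=150, q_start=50, q_end=90),
            mk_hsp(qid="A1", sid="B2", evalue=1e-30, bitscore=200),
        ]
        hsps_ba = [
            mk_hsp(qid="B1", sid="A1", evalue=1e-20, bitscore=150),
            mk_hsp(qid="B2", sid="A1", evalue=1e-30, bitscore=200),
        ]
        s = session_of(hsps_ab, hsps_ba)
        best_hsp = {(p.a_id, p.b_id) for p in reciprocal_best_hits(s)}
        summed = {(p.a_id, p.b_id) for p in reciprocal_best_hits(s, ranking="sum_bitscore")}
        assert best_hsp == {("A1", "B2")}
        assert summed == {("A1", "B1")}


class TestMultiple:
    def test_threshold_at_two_hsps(self):
        hsps = [
            mk_hsp(qid="A5", sid="B2", q_start=1, q_end=40),
            mk_hsp(qid="A5", sid="B2", q_start=50, q_end=90),
            mk_hsp(qid="A5", sid="B3"),
        ]
        out = multiple_region_hits(session_of(hsps, []), Direction.A_VS_B)
        assert [(q, s, k) for q, s, k, _ in out] == [("A5", "B2", 2)]

    def test_all_singletons_empty(self):
        hsps = [mk_hsp(qid="A1", sid="B1"), mk_hsp(qid="A2", sid="B2")]
        assert multiple_region_hits(session_of(hsps, []), Direction.A_VS_B) == []

    def test_counts_invariant_to_hsp_order(self):
        rng = random.Random(5)
        session, hsps_ab, _ = random_session(rng, max_queries=5, max_hsps=80)
        base = multiple_region_hits(session, Direction.A_VS_B)
        shuffled = list(hsps_ab)
        rng.shuffle(shuffled)
        redo = multiple_region_hits(session_of(shuffled, []), Direction.A_VS_B)
        assert [(q, s, k) for q, s, k, _ in base] == [(q, s, k) for q, s, k, _ in redo]

    def test_strict_mode_collapses_stacked_hsps(self):
        # two HSPs on the same query interval are one region, not two
        hsps = [
            mk_hsp(qid="A1", sid="B1", q_start=10, q_end=60, evalue=1e-30),
            mk_hsp(qid="A1", sid="B1", q_start=12, q_end=58, evalue=1e-20),
        ]
        s = session_of(hsps, [])
        assert [(q, x, k) for q, x, k, _ in multiple_region_hits(s, Direction.A_VS_B)] == [
            ("A1", "B1", 2)
        ]
        assert multiple_region_hits(s, Direction.A_VS_B, strict=True) == []

    def test_strict_mode_keeps_separated_regions(self):
        hsps = [
            mk_hsp(qid="A1", sid="B1", q_start=1, q_end=50),
            mk_hsp(qid="A1", sid="B1", q_start=100, q_end=150),
        ]
        out = multiple_region_hits(session_of(hsps, []), Direction.A_VS_B, strict=True)
        assert [(q, s, k) for q, s, k, _ in out] == [("A1", "B1", 2)]


class TestFilterConsistencyAndSummary:
    def test_filtered_ops_equal_physically_pruned_runs(self):
        rng = random.Random(37)
        spec = FilterSpec.of(evalue=(0, 1e-10), coverage=(0.3, 1.0))
        for _ in range(20):
            session, hsps_ab, hsps_ba = random_session(rng)
            filtered = session.with_filter(spec)
            pruned = session_of(
                [h for h in hsps_ab if spec.passes(h)],
                [h for h in hsps_ba if spec.passes(h)],
            )
            assert {(p.a_id, p.b_id) for p in cross_pairs(filtered)} == {
                (p.a_id, p.b_id) for p in cross_pairs(pruned)
            }
            assert {(p.a_id, p.b_id) for p in reciprocal_best_hits(filtered)} == brute_rbh(
                [h for h in hsps_ab if spec.passes(h)],
                [h for h in hsps_ba if spec.passes(h)],
            )
            got_multi = {
                (q, s): k for q, s, k, _ in multiple_region_hits(filtered, Direction.A_VS_B)
            }
            assert got_multi == brute_multiple([h for h in hsps_ab if spec.passes(h)])

    def test_summary_tallies_match_operation_outputs(self):
        rng = random.Random(41)
        session, *_ = random_session(rng)
        s = session_summary(session)
        assert s["cross_pairs"] == len(cross_pairs(session))
        assert s["rbh_pairs"] == len(reciprocal_best_hits(session))
        assert s["multi_region_pairs"]["ab"] == len(
            multiple_region_hits(session, Direction.A_VS_B)
        )

    def test_empty_session_all_zero(self):
        s = session_summary(session_of([], [], {"A1": 100}, {"B1": 100}))
        assert s["cross_pairs"] == 0 and s["rbh_pairs"] == 0
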