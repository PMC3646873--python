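import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from reciblast.filtering import span_fraction
from reciblast.logic import ReciprocalSession
from reciblast.model import BlastRun, Direction, Hsp, QueryResult
from reciblast.synth import PlantedStructure, fabricate_blast_tabular


def mk_hsp(
    qid="Q1",
    sid="S1",
    q_len=100,
    s_len=100,
    q_start=1,
    q_end=None,
    s_start=1,
    s_end=None,
    evalue=1e-10,
    bitscore=100.0,
    identity=90.0,
    similarity=95.0,
    align_length=None,
    mismatches=0,
    gap_opens=0,
) -> Hsp:
    q_end = q_end if q_end is not None else q_len
    s_end = s_end if s_end is not None else s_len
    align_length = align_length or (q_end - q_start + 1)
    return Hsp(
        query_id=qid,
        subject_id=sid,
        percent_identity=identity,
        percent_similarity=similarity,
        align_length=align_length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bitscore=bitscore,
        q_len=q_len,
        s_len=s_len,
        coverage=span_fraction(q_start, q_end, q_len),
        inv_cov=span_fraction(s_start, s_end, s_len),
    )


def run_from_hsps(hsps, direction=Direction.A_VS_B, query_lengths=None):
    results = {}
    qlens = dict(query_lengths or {})
    slens = {}
    for h in hsps:
        qlens.setdefault(h.query_id, h.q_len)
        slens.setdefault(h.subject_id, h.s_len)
        results.setdefault(h.query_id, QueryResult(h.query_id, h.q_len)).hsps.append(h)
    run = BlastRun(
        direction=direction,
        program="blastp",
        parameters={},
        query_results=results,
        query_lengths=qlens,
        subject_lengths=slens,
    )
    if query_lengths:
        run.ensure_all_queries(query_lengths)
    return run


def random_hsps(rng: random.Random, query_ids, subject_ids, n_hsps, lens_q, lens_s):
    hsps = []
    for _ in range(n_hsps):
        qid = rng.choice(query_ids)
        sid = rng.choice(subject_ids)
        q_len, s_len = lens_q[qid], lens_s[sid]
        q_span = rng.randint(1, q_len)
        s_span = rng.randint(1, s_len)
        q_start = rng.randint(1, q_len - q_span + 1)
        s_start = rng.randint(1, s_len - s_span + 1)
        hsps.append(
            mk_hsp(
                qid=qid,
                sid=sid,
                q_len=q_len,
                s_len=s_len,
                q_start=q_start,
                q_end=q_start + q_span - 1,
                s_start=s_start,
                s_end=s_start + s_span - 1,
                evalue=10.0 ** rng.uniform(-60, 1),
                bitscore=round(rng.uniform(30, 500), 1),
                identity=round(rng.uniform(20, 100), 2),
                similarity=round(rng.uniform(20, 100), 2),
            )
        )
    return hsps


def random_session(rng: random.Random, max_queries=20, max_hsps=120, self_mode=False):
    """A random in-memory reciprocal session (no planted structure)."""
    n_a = rng.randint(1, max_queries)
    n_b = n_a if self_mode else rng.randint(1, max_queries)
    ids_a = [f"A{i}" for i in range(n_a)]
    ids_b = ids_a if self_mode else [f"B{i}" for i in range(n_b)]
    lens_a = {i: rng.randint(50, 400) for i in ids_a}
    lens_b = lens_a if self_mode else {i: rng.randint(50, 400) for i in ids_b}
    hsps_ab = random_hsps(rng, ids_a, ids_b, rng.randint(0, max_hsps), lens_a, lens_b)
    if self_mode:
        run = run_from_hsps(hsps_ab, Direction.SELF, lens_a)
        return ReciprocalSession.from_runs(run), hsps_ab, hsps_ab
    hsps_ba = random_hsps(rng, ids_b, ids_a, rng.randint(0, max_hsps), lens_b, lens_a)
    run_ab = run_from_hsps(hsps_ab, Direction.A_VS_B, lens_a)
    run_ba = run_from_hsps(hsps_ba, Direction.B_VS_A, lens_b)
    return ReciprocalSession.from_runs(run_ab, run_ba), hsps_ab, hsps_ba


@pytest.fixture
def planted_spec():
    return PlantedStructure(seed=7)


@pytest.fixture
def planted_session(planted_spec, tmp_path):
    """Session parsed from fabricated tabular files, with its manifest."""
    from reciblast.blast_io import parse_tabular

    ab, ba, manifest = fabricate_blast_tabular(planted_spec, tmp_path)
    lens_a = manifest["query_lengths"]["a"]
    lens_b = manifest["query_lengths"]["b"]
    run_ab = parse_tabular(ab, lens_a, lens_b, direction=Direction.A_VS_B)
    run_ba = parse_tabular(ba, lens_b, lens_a, direction=Direction.B_VS_A)
    return ReciprocalSession.from_runs(run_ab, run_ba), manifest
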