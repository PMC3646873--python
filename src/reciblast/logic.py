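"""Set operations over a reciprocal session.

Four operations interrogate a paired (A→B, B→A) search:

* :func:`common_hits` — subjects shared by the hit lists of *every*
  selected query (intersection), e.g. proteins carrying the same domain.
* :func:`cross_pairs` — (a, b) pairs matched reciprocally as
  query/subject in both directions.
* :func:`reciprocal_best_hits` — the classic RBH ortholog-candidate
  criterion: b is a's top-ranked subject and a is b's.
* :func:`multiple_region_hits` — queries matching ≥ 2 regions on one
  subject (repeats, multi-domain matches, multiple binding sites).

When the session carries an active :class:`~reciblast.filtering.FilterSpec`
every operation reads only the visible HSPs, so filtering composes with
the logic exactly as if the hidden HSPs did not exist.

Ranking rule for "best": lowest e-value, ties broken by highest bitscore,
then highest query coverage, then lexicographically smallest subject id —
deterministic by construction.  A hit's rank is that of its single best
HSP; summed-bitscore ranking is available via ``ranking="sum_bitscore"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .filtering import FilterSpec
from .model import BlastRun, CrossPair, DataError, Direction, Hsp, NotFoundError


def hsp_rank_key(h: Hsp) -> Tuple[float, float, float, str]:
    """Sort key under which the best HSP comes first."""
    return (h.evalue, -h.bitscore, -h.coverage, h.subject_id)


@dataclass
class ReciprocalSession:
    """A paired (A→B, B→A) run bundle; logical operations execute on it.

    For a self-BLAST (one dataset searched against itself) the single run
    serves both directions and trivial self-pairs (x, x) are excluded from
    cross/RBH output.
    """

    run_ab: BlastRun
    run_ba: BlastRun
    filter_spec: FilterSpec = field(default_factory=FilterSpec)

    @classmethod
    def from_runs(
        cls,
        run_ab: BlastRun,
        run_ba: Optional[BlastRun] = None,
        filter_spec: Optional[FilterSpec] = None,
    ) -> "ReciprocalSession":
        if run_ba is None:
            if run_ab.direction != Direction.SELF:
                raise DataError("a single-run session requires a self-directed run")
            run_ba = run_ab
        return cls(run_ab, run_ba, filter_spec or FilterSpec())

    @property
    def is_self(self) -> bool:
        return self.run_ab.direction == Direction.SELF or self.run_ab is self.run_ba

    def run(self, direction: Direction) -> BlastRun:
        if direction in (Direction.A_VS_B, Direction.SELF):
            return self.run_ab
        if direction == Direction.B_VS_A:
            return self.run_ba
        raise DataError(f"unknown direction {direction!r}")

    def with_filter(self, spec: FilterSpec) -> "ReciprocalSession":
        """Same session with ``spec`` applied symmetrically to both runs."""
        return ReciprocalSession(self.run_ab, self.run_ba, spec)

    def visible_hits(self, direction: Direction) -> Dict[str, Dict[str, List[Hsp]]]:
        """query id → subject id → visible HSPs (insertion order kept);
        every known query appears, even with no visible hits."""
        run = self.run(direction)
        out: Dict[str, Dict[str, List[Hsp]]] = {}
        for qid, qr in run.query_results.items():
            by_subject: Dict[str, List[Hsp]] = {}
            for h in qr.hsps:
                if self.filter_spec.passes(h):
                    by_subject.setdefault(h.subject_id, []).append(h)
            out[qid] = by_subject
        return out


def _best_hsp(hsps: Sequence[Hsp]) -> Hsp:
    return min(hsps, key=hsp_rank_key)


def _best_subject(by_subject: Dict[str, List[Hsp]], ranking: str) -> Optional[str]:
    if not by_subject:
        return None
    if ranking == "best_hsp":
        return min(
            by_subject, key=lambda sid: hsp_rank_key(_best_hsp(by_subject[sid]))
        )
    if ranking == "sum_bitscore":
        return min(
            by_subject,
            key=lambda sid: (-sum(h.bitscore for h in by_subject[sid]), sid),
        )
    raise DataError(f"unknown ranking {ranking!r}; use 'best_hsp' or 'sum_bitscore'")


def common_hits(
    session: ReciprocalSession,
    direction: Direction,
    selected_queries: Sequence[str],
) -> List[Tuple[str, Dict[str, List[Hsp]]]]:
    """Subjects present in the hit list of EVERY selected query.

    Returns ``(subject_id, {query_id: supporting HSPs})`` tuples sorted by
    subject id; the HSPs carry the position of each hit on its query.
    """
    if not selected_queries:
        raise DataError("COMMON requires at least one selected query")
    hits = session.visible_hits(direction)
    for qid in selected_queries:
        if qid not in hits:
            raise NotFoundError(f"unknown query id {qid!r} in {direction.value} run")
    shared = set(hits[selected_queries[0]])
    for qid in selected_queries[1:]:
        shared &= set(hits[qid])
    return [
        (sid, {qid: hits[qid][sid] for qid in selected_queries})
        for sid in sorted(shared)
    ]


def cross_pairs(session: ReciprocalSession, ranking: str = "best_hsp") -> List[CrossPair]:
    """Every unordered (a, b) matched as query/subject in both directions.

    ``is_rbh`` is set on the pairs that are additionally each other's
    top-ranked hit.  Output sorted by (a_id, b_id).  In a self session the
    trivial (x, x) pair is excluded and each unordered pair appears once.
    """
    hits_ab = session.visible_hits(Direction.A_VS_B)
    hits_ba = session.visible_hits(Direction.B_VS_A)
    if session.is_self:
        # a sequence's trivial match to itself must not occupy the
        # top rank, or no self-session pair could ever be mutual-best
        ranked = {
            q: {s: hs for s, hs in subj.items() if s != q}
            for q, subj in hits_ab.items()
        }
        best_ab = best_ba = {q: _best_subject(s, ranking) for q, s in ranked.items()}
    else:
        best_ab = {q: _best_subject(s, ranking) for q, s in hits_ab.items()}
        best_ba = {q: _best_subject(s, ranking) for q, s in hits_ba.items()}
    pairs: List[CrossPair] = []
    seen = set()
    for a_id, by_subject in hits_ab.items():
        for b_id, fwd in by_subject.items():
            if session.is_self:
                if a_id == b_id:
                    continue
                key = tuple(sorted((a_id, b_id)))
                if key in seen:
                    continue
            rev = hits_ba.get(b_id, {}).get(a_id)
            if not rev:
                continue
            if session.is_self:
                # canonicalize the unordered pair to lexicographic order
                x, y = sorted((a_id, b_id))
                seen.add((x, y))
                fwd, rev = hits_ab[x][y], hits_ab[y][x]
            else:
                x, y = a_id, b_id
            is_rbh = best_ab.get(x) == y and best_ba.get(y) == x
            pairs.append(CrossPair(x, y, _best_hsp(fwd), _best_hsp(rev), is_rbh))
    pairs.sort(key=lambda p: (p.a_id, p.b_id))
    return pairs


def reciprocal_best_hits(session: ReciprocalSession, ranking: str = "best_hsp") -> List[CrossPair]:
    """The cross pairs that are mutual best hits; each sequence occurs in
    at most one returned pair."""
    return [p for p in cross_pairs(session, ranking=ranking) if p.is_rbh]


def _count_regions(hsps: List[Hsp], max_overlap: float) -> List[Hsp]:
    """Greedily pick HSPs (best first) whose query intervals overlap every
    previously picked one by at most ``max_overlap`` of the shorter span."""
    picked: List[Hsp] = []
    for h in sorted(hsps, key=hsp_rank_key):
        ok = True
        for p in picked:
            ov = min(h.q_end, p.q_end) - max(h.q_start, p.q_start) + 1
            shorter = min(h.q_end - h.q_start, p.q_end - p.q_start) + 1
            if ov > max_overlap * shorter:
                ok = False
                break
        if ok:
            picked.append(h)
    return picked


def multiple_region_hits(
    session: ReciprocalSession,
    direction: Direction,
    strict: bool = False,
    max_overlap: float = 0.5,
) -> List[Tuple[str, str, int, List[Hsp]]]:
    """(query, subject) pairs whose query matches ≥ 2 regions on the subject.

    By default every HSP counts as a region (raw tabular row semantics).
    With ``strict=True`` only HSPs whose query intervals overlap at most
    ``max_overlap`` (fraction of the shorter span) count as distinct
    regions — the multi-domain / repeated-site reading.
    Singleton pairs are filtered out entirely.
    """
    hits = session.visible_hits(direction)
    out: List[Tuple[str, str, int, List[Hsp]]] = []
    for qid in sorted(hits):
        for sid in sorted(hits[qid]):
            hsps = hits[qid][sid]
            regions = _count_regions(hsps, max_overlap) if strict else hsps
            if len(regions) >= 2:
                out.append((qid, sid, len(regions), hsps))
    return out


def session_summary(session: ReciprocalSession) -> Dict[str, object]:
    """Whole-dataset tallies of the three operations plus per-query subject
    counts (a pre-screen for COMMON selections)."""
    pairs = cross_pairs(session)
    directions = [Direction.A_VS_B] if session.is_self else [Direction.A_VS_B, Direction.B_VS_A]
    multi = {
        d.value: len(multiple_region_hits(session, d)) for d in directions
    }
    subject_counts = {
        d.value: {q: len(s) for q, s in session.visible_hits(d).items()}
        for d in directions
    }
    return {
        "cross_pairs": len(pairs),
        "rbh_pairs": sum(1 for p in pairs if p.is_rbh),
        "multi_region_pairs": multi,
        "per_query_subject_counts": subject_counts,
    }
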