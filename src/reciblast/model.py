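"""Domain model for reciprocal BLAST sessions.

The objects here mirror the shape of raw BLAST output as closely as
possible: coordinates are the native 1-based inclusive values, minus-strand
nucleotide hits keep ``s_start > s_end`` exactly as reported, and queries
that produced no hits are retained as empty :class:`QueryResult` records so
that downstream set operations can distinguish "no hits" from "not
searched".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterator, List, Mapping, Optional


class ReciblastError(Exception):
    """Base class for errors raised by this package."""


class DataError(ReciblastError):
    """Malformed or inconsistent input data."""


class NotFoundError(ReciblastError):
    """A requested record does not exist."""


class StoreIntegrityError(ReciblastError):
    """A session store is internally inconsistent (e.g. raw files moved)."""


class Alphabet(str, Enum):
    PROTEIN = "protein"
    NUCLEOTIDE = "nucleotide"


class Direction(str, Enum):
    A_VS_B = "ab"
    B_VS_A = "ba"
    SELF = "self"


#: Characters accepted as unambiguous or IUPAC-ambiguous nucleotides.
NUCLEOTIDE_CHARS = frozenset("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: id (first header token), description, length, alphabet."""

    id: str
    description: str
    length: int
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DataError(f"sequence {self.id!r} has length {self.length}; must be >= 1")


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair (a single aligned region).

    ``coverage`` is the fraction of the query spanned by the aligned
    segment, ``inv_cov`` the fraction of the subject; both are computed
    from the native coordinates at parse time (strand-agnostic on the
    subject side).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    percent_similarity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    q_len: int
    s_len: int
    coverage: float
    inv_cov: float

    def validate(self) -> "Hsp":
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise DataError(
                f"{self.query_id}->{self.subject_id}: query coordinates "
                f"{self.q_start}..{self.q_end} violate 1 <= start <= end <= q_len={self.q_len}"
            )
        lo, hi = min(self.s_start, self.s_end), max(self.s_start, self.s_end)
        if lo < 1 or hi > self.s_len:
            raise DataError(
                f"{self.query_id}->{self.subject_id}: subject coordinates "
                f"{self.s_start}..{self.s_end} outside 1..{self.s_len}"
            )
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.inv_cov <= 1.0):
            raise DataError(
                f"{self.query_id}->{self.subject_id}: coverage {self.coverage} "
                f"or inv_cov {self.inv_cov} outside [0, 1]"
            )
        if self.evalue < 0:
            raise DataError(f"{self.query_id}->{self.subject_id}: negative e-value {self.evalue}")
        return self


@dataclass
class QueryResult:
    """All HSPs of one query in one directional search, in emission order."""

    query_id: str
    query_length: int
    hsps: List[Hsp] = field(default_factory=list)

    @property
    def subject_ids(self) -> List[str]:
        """Distinct subject ids, in order of first appearance."""
        seen: Dict[str, None] = {}
        for h in self.hsps:
            seen.setdefault(h.subject_id, None)
        return list(seen)

    def validate(self) -> "QueryResult":
        for h in self.hsps:
            if h.query_id != self.query_id:
                raise DataError(
                    f"QueryResult {self.query_id!r} contains an HSP of query {h.query_id!r}"
                )
        return self


@dataclass
class BlastRun:
    """All query results of one directional search plus the length registry.

    ``query_results`` is keyed by query id and preserves insertion order;
    queries with zero hits appear with empty HSP lists.  ``source_path`` /
    ``source_format`` point at the raw BLAST output the run was parsed
    from, when there is one — the session store uses them to retain raw
    alignments for lazy retrieval.
    """

    direction: Direction
    program: Optional[str]
    parameters: Dict[str, object]
    query_results: Dict[str, QueryResult]
    query_lengths: Dict[str, int]
    subject_lengths: Dict[str, int]
    source_path: Optional[str] = None
    source_format: Optional[str] = None

    def iter_hsps(self) -> Iterator[Hsp]:
        for qr in self.query_results.values():
            yield from qr.hsps

    @property
    def hsps(self) -> List[Hsp]:
        return list(self.iter_hsps())

    def ensure_all_queries(self, query_lengths: Mapping[str, int]) -> None:
        """Add empty QueryResults for known queries that produced no hits."""
        for qid, qlen in query_lengths.items():
            if qid not in self.query_results:
                self.query_results[qid] = QueryResult(qid, qlen)
            self.query_lengths.setdefault(qid, qlen)


@dataclass(frozen=True)
class CrossPair:
    """A reciprocally matched (a, b) pair with its best HSP in each direction."""

    a_id: str
    b_id: str
    best_ab: Hsp
    best_ba: Hsp
    is_rbh: bool
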