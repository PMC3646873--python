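"""Coverage metrics and reversible multi-criteria filtering.

Filtering is a *view*: a :class:`FilteredView` never touches the underlying
:class:`~reciblast.model.BlastRun`, so applying and clearing filters is
lossless.  All range bounds are inclusive on both ends, and the criteria of
a spec combine by conjunction — an HSP is visible only if it satisfies
every supplied range.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

from .model import BlastRun, DataError, Hsp, QueryResult

#: HSP attributes a FilterSpec may constrain.
FILTERABLE_PARAMETERS = (
    "evalue",
    "percent_identity",
    "percent_similarity",
    "coverage",
    "inv_cov",
    "bitscore",
    "align_length",
)

Range = Tuple[Optional[float], Optional[float]]


def compute_coverage(hsp: Hsp) -> float:
    """Fraction of the query spanned by the aligned segment."""
    return span_fraction(hsp.q_start, hsp.q_end, hsp.q_len)


def compute_inv_cov(hsp: Hsp) -> float:
    """Fraction of the subject spanned; strand-agnostic (|end − start| + 1)."""
    return span_fraction(hsp.s_start, hsp.s_end, hsp.s_len)


def span_fraction(start: int, end: int, length: int) -> float:
    if length <= 0:
        raise DataError(f"sequence length must be >= 1, got {length}")
    return (abs(end - start) + 1) / length


def query_union_coverage(hsps: Iterable[Hsp]) -> float:
    """Union coverage of a query over one subject: merged query-interval
    length divided by query length.

    The per-row ``coverage`` column describes a single HSP; when a hit
    comprises several HSPs (multiple domains, repeats) the union is the
    meaningful whole-hit quantity.  All HSPs passed in must share one
    query.
    """
    hsps = list(hsps)
    if not hsps:
        return 0.0
    q_len = hsps[0].q_len
    intervals = sorted((h.q_start, h.q_end) for h in hsps)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return covered / q_len


@dataclass(frozen=True)
class FilterSpec:
    """Inclusive numeric ranges over HSP parameters; empty spec passes all.

    Either bound of a range may be ``None`` (one-sided limit).
    """

    ranges: Mapping[str, Range] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if name not in FILTERABLE_PARAMETERS:
                raise DataError(
                    f"unknown filter parameter {name!r}; "
                    f"choose from {', '.join(FILTERABLE_PARAMETERS)}"
                )
            if lo is not None and hi is not None and lo > hi:
                raise DataError(f"filter range for {name!r} has min {lo} > max {hi}")

    @classmethod
    def of(cls, **ranges: Range) -> "FilterSpec":
        """Build a spec from keyword ranges, e.g. ``FilterSpec.of(percent_similarity=(40, 80))``."""
        return cls({k: v for k, v in ranges.items() if v is not None})

    @property
    def is_empty(self) -> bool:
        return not self.ranges

    def passes(self, hsp: Hsp) -> bool:
        for name, (lo, hi) in self.ranges.items():
            value = getattr(hsp, name)
            if lo is not None and value < lo:
                return False
            if hi is not None and value > hi:
                return False
        return True

    def merged(self, other: "FilterSpec") -> "FilterSpec":
        """Conjunction of two specs (per-parameter intersection of ranges)."""
        ranges: Dict[str, Range] = dict(self.ranges)
        for name, (lo, hi) in other.ranges.items():
            if name in ranges:
                olo, ohi = ranges[name]
                lo = olo if lo is None else lo if olo is None else max(lo, olo)
                hi = ohi if hi is None else hi if ohi is None else min(hi, ohi)
            # An empty intersection (lo > hi) matches nothing; the
            # constructor rejects such a range, so use the sentinel spec.
            if lo is not None and hi is not None and lo > hi:
                return _ImpossibleSpec()
            ranges[name] = (lo, hi)
        return FilterSpec(ranges)


class _ImpossibleSpec(FilterSpec):
    """Spec whose ranges contradict each other; passes nothing."""

    def __init__(self) -> None:
        object.__setattr__(self, "ranges", {})

    @property
    def is_empty(self) -> bool:  # not the identity filter
        return False

    def passes(self, hsp: Hsp) -> bool:
        return False


@dataclass
class FilteredView:
    """Non-destructive view of a BlastRun under a FilterSpec."""

    source: BlastRun
    spec: FilterSpec = field(default_factory=FilterSpec)

    @property
    def visible_hsps(self) -> List[Hsp]:
        return [h for h in self.source.iter_hsps() if self.spec.passes(h)]

    def visible_query_results(self) -> List[QueryResult]:
        """Per-query visible HSPs; queries whose HSPs are all filtered out
        remain present as empty rows."""
        out = []
        for qr in self.source.query_results.values():
            out.append(
                QueryResult(qr.query_id, qr.query_length, [h for h in qr.hsps if self.spec.passes(h)])
            )
        return out


def apply_filters(run: Union[BlastRun, FilteredView], spec: FilterSpec) -> FilteredView:
    """Create a filtered view; stacking on an existing view conjoins specs."""
    if isinstance(run, FilteredView):
        return FilteredView(run.source, run.spec.merged(spec))
    return FilteredView(run, spec)


def clear_filters(view: FilteredView) -> FilteredView:
    """Drop every criterion; the full HSP set of the source reappears."""
    return FilteredView(view.source, FilterSpec())


EXPORT_COLUMNS = (
    "query_id",
    "subject_id",
    "identity",
    "similarity",
    "align_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
    "coverage",
    "inv_cov",
)


def _format_row(h: Hsp) -> str:
    return "\t".join(
        (
            h.query_id,
            h.subject_id,
            repr(h.percent_identity),
            repr(h.percent_similarity),
            str(h.align_length),
            str(h.mismatches),
            str(h.gap_opens),
            str(h.q_start),
            str(h.q_end),
            str(h.s_start),
            str(h.s_end),
            f"{h.evalue:.6e}",
            repr(h.bitscore),
            f"{h.coverage:.4f}",
            f"{h.inv_cov:.4f}",
        )
    )


def export_table(view: Union[FilteredView, BlastRun], path) -> int:
    """Write the visible HSPs as a TSV table; returns the data-row count.

    E-values are rendered in scientific notation and the two coverage
    fractions with 4 decimal places, so exports diff reproducibly.
    """
    if isinstance(view, BlastRun):
        view = FilteredView(view)
    rows = view.visible_hsps
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EXPORT_COLUMNS) + "\n")
        for h in rows:
            fh.write(_format_row(h) + "\n")
    return len(rows)


def read_exported_table(path, query_lengths: Mapping[str, int], subject_lengths: Mapping[str, int]) -> List[Hsp]:
    """Read a table written by :func:`export_table` back into HSPs.

    Sequence lengths are not part of the export schema and must be supplied
    (e.g. from the originating run's registries).
    """
    out: List[Hsp] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EXPORT_COLUMNS:
            raise DataError(f"{path}: not a reciblast export table (header mismatch)")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            if qid not in query_lengths:
                raise DataError(f"{path}: unknown query id {qid!r} (no length supplied)")
            if sid not in subject_lengths:
                raise DataError(f"{path}: unknown subject id {sid!r} (no length supplied)")
            h = Hsp(
                query_id=qid,
                subject_id=sid,
                percent_identity=float(f[2]),
                percent_similarity=float(f[3]),
                align_length=int(f[4]),
                mismatches=int(f[5]),
                gap_opens=int(f[6]),
                q_start=int(f[7]),
                q_end=int(f[8]),
                s_start=int(f[9]),
                s_end=int(f[10]),
                evalue=float(f[11]),
                bitscore=float(f[12]),
                q_len=query_lengths[qid],
                s_len=subject_lengths[sid],
                coverage=float(f[13]),
                inv_cov=float(f[14]),
            )
            out.append(h)
    return out


def run_statistics(run_or_view: Union[BlastRun, FilteredView]) -> Dict[str, object]:
    """Summary counts and min/median/max of e-value, identity and coverage
    over the visible HSPs."""
    if isinstance(run_or_view, BlastRun):
        view = FilteredView(run_or_view)
    else:
        view = run_or_view
    per_query = view.visible_query_results()
    hsps = [h for qr in per_query for h in qr.hsps]
    summary: Dict[str, object] = {
        "queries": len(per_query),
        "queries_with_hits": sum(1 for qr in per_query if qr.hsps),
        "distinct_subjects": len({h.subject_id for h in hsps}),
        "hsps": len(hsps),
    }
    if hsps:
        for name, attr in (
            ("evalue", "evalue"),
            ("identity", "percent_identity"),
            ("coverage", "coverage"),
        ):
            values = [getattr(h, attr) for h in hsps]
            summary[name] = {
                "min": min(values),
                "median": statistics.median(values),
                "max": max(values),
            }
    return summary


def statistics_json(run_or_view: Union[BlastRun, FilteredView]) -> str:
    return json.dumps(run_statistics(run_or_view), sort_keys=True, indent=2)
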