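"""Synthetic datasets with known ground truth.

Two fixture tiers:

* :func:`generate_fasta_pair` writes a pair of protein FASTA datasets in
  which homology is *planted* — mutually-best pairs are mutated whole-
  sequence copies, shared "domains" are a common segment inserted into
  several sequences, and repeated segments produce multi-region matches —
  so that a real BLAST search recovers the planted relations.
* :func:`fabricate_blast_tabular` / :func:`fabricate_blast_xml` skip BLAST
  entirely and write the two directional result files directly, with
  e-values arranged so the planted reciprocal pairs are mutually best by
  construction.  Decoy hits are placed only on unordered pairs that never
  occur in both directions and never on a planted (query, subject) pair,
  so the ground-truth manifest is exact: RBH output equals the planted
  pairs, and multi-region counts equal the repeat map.

Everything is reproducible from (parameters, seed).

What this emulates — and what it does not: sequences are i.i.d. random
backgrounds with point-substituted copies; there are no indels, no
phylogeny, no composition bias.  Passing tests show the machinery is
correct, not that any biological dataset behaves this way.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .model import DataError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PlantedStructure:
    """Parameters of a planted dataset pair.

    ``rbh_pairs`` lists the intended mutually-best (a, b) pairs;
    ``shared_domain_map`` maps a domain label to (queries in A, subjects
    in B) sharing that segment; ``repeat_map`` plants k separated copies
    of a segment of the query inside the subject.  Ids not covered by any
    relation act as decoys.
    """

    n_a: int = 30
    n_b: int = 30
    n_rbh: int = 5
    shared_domain_map: Optional[Dict[str, Tuple[List[str], List[str]]]] = None
    repeat_map: Optional[Dict[Tuple[str, str], int]] = None
    seq_len: Tuple[int, int] = (200, 400)
    segment_len: int = 60
    substitution_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_domain_map is None:
            k = self.n_rbh
            self.shared_domain_map = {
                "D1": ([f"A{k + 1}", f"A{k + 2}"], [f"B{k + 1}"]),
            }
        if self.repeat_map is None:
            k = self.n_rbh
            self.repeat_map = {(f"A{k + 3}", f"B{k + 2}"): 2}
        ids_a, ids_b = set(self.ids_a), set(self.ids_b)
        for a, b in self.rbh_pairs:
            if a not in ids_a or b not in ids_b:
                raise DataError(f"planted RBH pair ({a}, {b}) references unknown ids")
        for label, (qs, ss) in self.shared_domain_map.items():
            for q in qs:
                if q not in ids_a:
                    raise DataError(f"domain {label}: unknown query {q!r}")
            for s in ss:
                if s not in ids_b:
                    raise DataError(f"domain {label}: unknown subject {s!r}")
        for (q, s), k in self.repeat_map.items():
            if q not in ids_a or s not in ids_b:
                raise DataError(f"repeat entry ({q}, {s}) references unknown ids")
            if k < 2:
                raise DataError(f"repeat count for ({q}, {s}) must be >= 2, got {k}")
        if self.segment_len > self.seq_len[0] // 2:
            raise DataError(
                f"segment length {self.segment_len} does not fit a sequence of "
                f"minimum length {self.seq_len[0]} (need <= half)"
            )

    @property
    def ids_a(self) -> List[str]:
        return [f"A{i + 1}" for i in range(self.n_a)]

    @property
    def ids_b(self) -> List[str]:
        return [f"B{i + 1}" for i in range(self.n_b)]

    @property
    def rbh_pairs(self) -> List[Tuple[str, str]]:
        return [(f"A{i + 1}", f"B{i + 1}") for i in range(self.n_rbh)]

    def manifest(self) -> Dict:
        return {
            "seed": self.seed,
            "rbh_pairs": [list(p) for p in self.rbh_pairs],
            "common": {
                label: {"queries": qs, "subjects": ss}
                for label, (qs, ss) in self.shared_domain_map.items()
            },
            "multiple": [[q, s, k] for (q, s), k in self.repeat_map.items()],
            "substitution_rate": self.substitution_rate,
        }


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AMINO_ACIDS if a != c]))
        else:
            out.append(c)
    return "".join(out)


def generate_fasta_pair(spec: PlantedStructure, directory) -> Tuple[Path, Path, Dict]:
    """Write dataset A and B FASTA files plus the ground-truth manifest.

    Mutually-best pairs are whole-sequence mutated copies; shared domains
    and repeats are mutated copies of a common segment spliced into random
    backgrounds at separated positions.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    rate = spec.substitution_rate

    seqs_a = {
        aid: _random_protein(rng, rng.randint(*spec.seq_len)) for aid in spec.ids_a
    }
    seqs_b = {
        bid: _random_protein(rng, rng.randint(*spec.seq_len)) for bid in spec.ids_b
    }
    for a, b in spec.rbh_pairs:
        seqs_b[b] = _mutate(rng, seqs_a[a], rate)
    for label, (queries, subjects) in spec.shared_domain_map.items():
        domain = _random_protein(rng, spec.segment_len)
        for sid in queries:
            seqs_a[sid] = _splice(rng, seqs_a[sid], [_mutate(rng, domain, rate)])
        for sid in subjects:
            seqs_b[sid] = _splice(rng, seqs_b[sid], [_mutate(rng, domain, rate)])
    for (q, s), k in spec.repeat_map.items():
        segment = seqs_a[q][: spec.segment_len]
        seqs_b[s] = _splice(
            rng, seqs_b[s], [_mutate(rng, segment, rate) for _ in range(k)]
        )

    path_a = directory / "dataset_a.fasta"
    path_b = directory / "dataset_b.fasta"
    for path, seqs in ((path_a, seqs_a), (path_b, seqs_b)):
        with open(path, "w", encoding="utf-8") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid} synthetic\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
    manifest = spec.manifest()
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return path_a, path_b, manifest


def _splice(rng: random.Random, background: str, segments: List[str]) -> str:
    """Replace non-overlapping stretches of the background with the given
    segments, keeping total length and leaving gaps between them."""
    total = sum(len(s) for s in segments)
    if total + len(segments) * 10 > len(background):
        raise DataError(
            f"cannot place {len(segments)} segment(s) of total length {total} "
            f"in a sequence of length {len(background)}"
        )
    slots = []
    pos = 0
    free = len(background) - total
    gap = free // (len(segments) + 1)
    out = []
    for seg in segments:
        out.append(background[pos:pos + gap])
        pos += gap
        out.append(seg)
        pos += len(seg)
    out.append(background[pos:])
    return "".join(out)[: len(background)]


# ---------------------------------------------------------------------------
# fabricated BLAST outputs (no BLAST+ required)


@dataclass
class NoiseParams:
    """Decoy-hit generation: how many random one-directional hits to add
    and the log10 e-value window they are drawn from (always far worse
    than the planted signals)."""

    n_decoys_per_direction: int = 40
    evalue_log10_range: Tuple[float, float] = (-18.0, -3.0)


@dataclass
class _Row:
    qseqid: str
    sseqid: str
    pident: float
    ppos: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int


def _make_row(
    rng: random.Random,
    qid: str,
    sid: str,
    qlen: int,
    slen: int,
    evalue: float,
    bitscore: float,
    span: Optional[int] = None,
    q_window: Optional[Tuple[int, int]] = None,
    s_window: Optional[Tuple[int, int]] = None,
) -> _Row:
    if span is None:
        span = rng.randint(30, max(31, min(qlen, slen) // 2))
    span = min(span, qlen, slen)
    if q_window:
        qstart = rng.randint(q_window[0], max(q_window[0], q_window[1] - span + 1))
    else:
        qstart = rng.randint(1, qlen - span + 1)
    if s_window:
        sstart = rng.randint(s_window[0], max(s_window[0], s_window[1] - span + 1))
    else:
        sstart = rng.randint(1, slen - span + 1)
    identities = rng.randint(int(span * 0.6), span)
    positives = rng.randint(identities, span)
    return _Row(
        qseqid=qid,
        sseqid=sid,
        pident=100.0 * identities / span,
        ppos=100.0 * positives / span,
        length=span,
        mismatch=span - identities,
        gapopen=0,
        qstart=qstart,
        qend=qstart + span - 1,
        sstart=sstart,
        send=sstart + span - 1,
        evalue=evalue,
        bitscore=bitscore,
        qlen=qlen,
        slen=slen,
    )


def fabricate_rows(
    spec: PlantedStructure, noise: Optional[NoiseParams] = None
) -> Tuple[List[_Row], List[_Row], Dict[str, int], Dict[str, int], Dict]:
    """Build the (A→B, B→A) row lists realizing the planted structure."""
    noise = noise or NoiseParams()
    rng = random.Random(spec.seed)
    lens_a = {aid: rng.randint(*spec.seq_len) for aid in spec.ids_a}
    lens_b = {bid: rng.randint(*spec.seq_len) for bid in spec.ids_b}
    rows_ab: List[_Row] = []
    rows_ba: List[_Row] = []
    used_ab: set = set()
    used_ba: set = set()

    for i, (a, b) in enumerate(spec.rbh_pairs):
        ev = 10.0 ** (-80 - i)  # far below anything else; distinct per pair
        span = min(lens_a[a], lens_b[b]) - 10
        rows_ab.append(_make_row(rng, a, b, lens_a[a], lens_b[b], ev, 500.0 + i, span=span))
        rows_ba.append(_make_row(rng, b, a, lens_b[b], lens_a[a], ev, 500.0 + i, span=span))
        used_ab.add((a, b))
        used_ba.add((b, a))

    for label, (queries, subjects) in spec.shared_domain_map.items():
        for q in queries:
            for s in subjects:
                ev = 10.0 ** rng.uniform(-32, -28)
                rows_ab.append(
                    _make_row(rng, q, s, lens_a[q], lens_b[s], ev, 120.0, span=spec.segment_len)
                )
                used_ab.add((q, s))

    for (q, s), k in spec.repeat_map.items():
        s_len = lens_b[s]
        slot = s_len // k
        for j in range(k):
            ev = 10.0 ** rng.uniform(-27, -24)
            rows_ab.append(
                _make_row(
                    rng, q, s, lens_a[q], s_len, ev, 100.0,
                    span=min(spec.segment_len, slot - 1),
                    s_window=(j * slot + 1, (j + 1) * slot),
                )
            )
        used_ab.add((q, s))

    # decoys: one-directional only, never on a planted pair, and never the
    # same unordered pair in both directions -> no accidental mutual best
    lo, hi = noise.evalue_log10_range
    for _ in range(noise.n_decoys_per_direction):
        for _attempt in range(100):
            a = rng.choice(spec.ids_a)
            b = rng.choice(spec.ids_b)
            if (a, b) not in used_ab and (b, a) not in used_ba:
                used_ab.add((a, b))
                rows_ab.append(
                    _make_row(rng, a, b, lens_a[a], lens_b[b], 10.0 ** rng.uniform(lo, hi), 50.0)
                )
                break
        for _attempt in range(100):
            a = rng.choice(spec.ids_a)
            b = rng.choice(spec.ids_b)
            if (b, a) not in used_ba and (a, b) not in used_ab:
                used_ba.add((b, a))
                rows_ba.append(
                    _make_row(rng, b, a, lens_b[b], lens_a[a], 10.0 ** rng.uniform(lo, hi), 50.0)
                )
                break
    rows_ab.sort(key=lambda r: (r.qseqid, r.evalue))
    rows_ba.sort(key=lambda r: (r.qseqid, r.evalue))
    return rows_ab, rows_ba, lens_a, lens_b, spec.manifest()


def _write_tabular(rows: List[_Row], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    (
                        r.qseqid, r.sseqid, repr(r.pident), repr(r.ppos),
                        str(r.length), str(r.mismatch), str(r.gapopen),
                        str(r.qstart), str(r.qend), str(r.sstart), str(r.send),
                        f"{r.evalue:.6e}", repr(r.bitscore),
                        str(r.qlen), str(r.slen),
                    )
                )
                + "\n"
            )


def fabricate_blast_tabular(
    spec: PlantedStructure,
    directory,
    noise: Optional[NoiseParams] = None,
) -> Tuple[Path, Path, Dict]:
    """Write the two 15-column extended tabular files plus the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows_ab, rows_ba, lens_a, lens_b, manifest = fabricate_rows(spec, noise)
    ab, ba = directory / "ab.tsv", directory / "ba.tsv"
    _write_tabular(rows_ab, ab)
    _write_tabular(rows_ba, ba)
    manifest["query_lengths"] = {"a": lens_a, "b": lens_b}
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return ab, ba, manifest


def _row_alignment(rng: random.Random, r: _Row) -> Tuple[str, str, str]:
    """Fabricate gapless qseq/midline/hseq strings consistent with the row."""
    identities = r.length - r.mismatch
    qseq = _random_protein(rng, r.length)
    hseq = list(qseq)
    positions = rng.sample(range(r.length), r.mismatch)
    for p in positions:
        hseq[p] = rng.choice([a for a in AMINO_ACIDS if a != qseq[p]])
    midline = "".join(q if q == h else " " for q, h in zip(qseq, hseq))
    return qseq, midline, "".join(hseq)


def _write_xml(rows: List[_Row], program: str, lens_q: Dict[str, int], path: Path, seed: int) -> None:
    rng = random.Random(seed)
    by_query: Dict[str, List[_Row]] = {}
    for r in rows:
        by_query.setdefault(r.qseqid, []).append(r)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write("<BlastOutput>\n")
        fh.write(f"  <BlastOutput_program>{program}</BlastOutput_program>\n")
        fh.write(f"  <BlastOutput_version>{program.upper()} 0.0.0</BlastOutput_version>\n")
        fh.write("  <BlastOutput_reference>synthetic fixture</BlastOutput_reference>\n")
        fh.write("  <BlastOutput_db>synthetic</BlastOutput_db>\n")
        first = next(iter(lens_q))
        fh.write("  <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>\n")
        fh.write(f"  <BlastOutput_query-def>{first} synthetic</BlastOutput_query-def>\n")
        fh.write(f"  <BlastOutput_query-len>{lens_q[first]}</BlastOutput_query-len>\n")
        fh.write("  <BlastOutput_param>\n    <Parameters>\n"
                 "      <Parameters_matrix>BLOSUM62</Parameters_matrix>\n"
                 "      <Parameters_expect>10</Parameters_expect>\n"
                 "      <Parameters_gap-open>11</Parameters_gap-open>\n"
                 "      <Parameters_gap-extend>1</Parameters_gap-extend>\n"
                 "      <Parameters_filter>F</Parameters_filter>\n"
                 "    </Parameters>\n  </BlastOutput_param>\n")
        fh.write("<BlastOutput_iterations>\n")
        for qnum, qid in enumerate(lens_q, start=1):
            fh.write("<Iteration>\n")
            fh.write(f"  <Iteration_iter-num>{qnum}</Iteration_iter-num>\n")
            fh.write(f"  <Iteration_query-ID>Query_{qnum}</Iteration_query-ID>\n")
            fh.write(f"  <Iteration_query-def>{qid} synthetic</Iteration_query-def>\n")
            fh.write(f"  <Iteration_query-len>{lens_q[qid]}</Iteration_query-len>\n")
            fh.write("<Iteration_hits>\n")
            by_subject: Dict[str, List[_Row]] = {}
            for r in by_query.get(qid, []):
                by_subject.setdefault(r.sseqid, []).append(r)
            for hnum, sid in enumerate(by_subject, start=1):
                rs = by_subject[sid]
                fh.write("<Hit>\n")
                fh.write(f"  <Hit_num>{hnum}</Hit_num>\n")
                fh.write(f"  <Hit_id>{sid}</Hit_id>\n")
                fh.write(f"  <Hit_def>{sid} synthetic</Hit_def>\n")
                fh.write(f"  <Hit_accession>{sid}</Hit_accession>\n")
                fh.write(f"  <Hit_len>{rs[0].slen}</Hit_len>\n")
                fh.write("<Hit_hsps>\n")
                for onum, r in enumerate(rs, start=1):
                    identities = r.length - r.mismatch
                    positives = round(r.ppos * r.length / 100)
                    qseq, midline, hseq = _row_alignment(rng, r)
                    fh.write("<Hsp>\n")
                    fh.write(f"  <Hsp_num>{onum}</Hsp_num>\n")
                    fh.write(f"  <Hsp_bit-score>{r.bitscore!r}</Hsp_bit-score>\n")
                    fh.write(f"  <Hsp_score>{int(r.bitscore * 2)}</Hsp_score>\n")
                    fh.write(f"  <Hsp_evalue>{r.evalue!r}</Hsp_evalue>\n")
                    fh.write(f"  <Hsp_query-from>{r.qstart}</Hsp_query-from>\n")
                    fh.write(f"  <Hsp_query-to>{r.qend}</Hsp_query-to>\n")
                    fh.write(f"  <Hsp_hit-from>{r.sstart}</Hsp_hit-from>\n")
                    fh.write(f"  <Hsp_hit-to>{r.send}</Hsp_hit-to>\n")
                    fh.write("  <Hsp_query-frame>0</Hsp_query-frame>\n")
                    fh.write("  <Hsp_hit-frame>0</Hsp_hit-frame>\n")
                    fh.write(f"  <Hsp_identity>{identities}</Hsp_identity>\n")
                    fh.write(f"  <Hsp_positive>{positives}</Hsp_positive>\n")
                    fh.write("  <Hsp_gaps>0</Hsp_gaps>\n")
                    fh.write(f"  <Hsp_align-len>{r.length}</Hsp_align-len>\n")
                    fh.write(f"  <Hsp_qseq>{qseq}</Hsp_qseq>\n")
                    fh.write(f"  <Hsp_hseq>{hseq}</Hsp_hseq>\n")
                    fh.write(f"  <Hsp_midline>{midline}</Hsp_midline>\n")
                    fh.write("</Hsp>\n")
                fh.write("</Hit_hsps>\n")
                fh.write("</Hit>\n")
            fh.write("</Iteration_hits>\n")
            fh.write("</Iteration>\n")
        fh.write("</BlastOutput_iterations>\n")
        fh.write("</BlastOutput>\n")


def fabricate_blast_xml(
    spec: PlantedStructure,
    directory,
    noise: Optional[NoiseParams] = None,
) -> Tuple[Path, Path, Dict]:
    """Write the same fabricated searches as BLAST XML (with alignment
    strings), field-equivalent to :func:`fabricate_blast_tabular` for the
    same spec and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows_ab, rows_ba, lens_a, lens_b, manifest = fabricate_rows(spec, noise)
    ab, ba = directory / "ab.xml", directory / "ba.xml"
    _write_xml(rows_ab, "blastp", lens_a, ab, spec.seed + 1)
    _write_xml(rows_ba, "blastp", lens_b, ba, spec.seed + 2)
    return ab, ba, manifest
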