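"""Reading FASTA datasets, running BLAST+ and parsing its outputs.

Two ingestion paths produce the same in-memory model: driving the BLAST+
binaries directly over a pair of FASTA files (``run_reciprocal_blast``),
or importing pre-computed searches in tabular (``parse_tabular``) or XML
(``parse_xml``) form.  The tabular reader accepts the standard 12-column
``-outfmt 6`` dialect (lengths must then be supplied separately) and the
extended 15-column dialect

    qseqid sseqid pident ppos length mismatch gapopen
    qstart qend sstart send evalue bitscore qlen slen

auto-detected by column count.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

from Bio import SeqIO
from Bio.Blast import NCBIXML

from .filtering import span_fraction
from .model import (
    Alphabet,
    BlastRun,
    DataError,
    Direction,
    Hsp,
    NUCLEOTIDE_CHARS,
    QueryResult,
    SequenceRecord,
)

TABULAR_EXTENDED_COLUMNS = (
    "qseqid sseqid pident ppos length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
)


def detect_alphabet(sequence: str) -> Alphabet:
    """Nucleotide iff every character is an unambiguous or IUPAC-ambiguous
    base (ACGTUN + RYSWKMBDHV); anything else is protein."""
    chars = set(sequence.upper()) - {"-", "*", "."}
    if chars and chars <= NUCLEOTIDE_CHARS:
        return Alphabet.NUCLEOTIDE
    return Alphabet.PROTEIN


def read_fasta(path, alphabet: Optional[Alphabet] = None) -> List[SequenceRecord]:
    """Read a multi-FASTA dataset into SequenceRecords (file order kept).

    The alphabet of each record is auto-detected unless ``alphabet`` is
    given.  Duplicate ids, empty files and non-FASTA content are errors.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise DataError(
                        f"{path}: not FASTA — line {lineno} does not start a '>' header"
                    )
                break
        else:
            raise DataError(f"{path}: empty dataset")
    records: List[SequenceRecord] = []
    seen: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "")
        if rec.id in seen:
            raise DataError(f"{path}: duplicate sequence id {rec.id!r}")
        seen[rec.id] = 1
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(
                id=rec.id,
                description=desc,
                length=len(seq),
                alphabet=alphabet or detect_alphabet(seq),
            )
        )
    if not records:
        raise DataError(f"{path}: empty dataset")
    return records


def _build_hsp(
    query_id: str,
    subject_id: str,
    pident: float,
    ppos: float,
    length: int,
    mismatch: int,
    gapopen: int,
    qstart: int,
    qend: int,
    sstart: int,
    send: int,
    evalue: float,
    bitscore: float,
    qlen: int,
    slen: int,
) -> Hsp:
    return Hsp(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=pident,
        percent_similarity=ppos,
        align_length=length,
        mismatches=mismatch,
        gap_opens=gapopen,
        q_start=qstart,
        q_end=qend,
        s_start=sstart,
        s_end=send,
        evalue=evalue,
        bitscore=bitscore,
        q_len=qlen,
        s_len=slen,
        coverage=span_fraction(qstart, qend, qlen),
        inv_cov=span_fraction(sstart, send, slen),
    ).validate()


def parse_tabular(
    path,
    query_lengths: Optional[Mapping[str, int]] = None,
    subject_lengths: Optional[Mapping[str, int]] = None,
    direction: Direction = Direction.A_VS_B,
    program: Optional[str] = None,
) -> BlastRun:
    """Parse BLAST tabular output (12-column standard or 15-column extended).

    With the 12-column dialect the two length mappings are mandatory since
    coverage/inv-cov need full sequence lengths.  Comment lines ('#') are
    skipped; rows are grouped into per-query results preserving emission
    order; queries listed in ``query_lengths`` but absent from the file are
    retained as empty results.
    """
    path = Path(path)
    results: Dict[str, QueryResult] = {}
    qlens: Dict[str, int] = dict(query_lengths or {})
    slens: Dict[str, int] = dict(subject_lengths or {})
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) == 15:
                extended = True
            elif len(f) == 12:
                extended = False
            else:
                raise DataError(
                    f"{path}:{lineno}: expected 12 or 15 tab-separated columns, got {len(f)}"
                )
            try:
                qid, sid = f[0], f[1]
                pident = float(f[2])
                if extended:
                    ppos = float(f[3])
                    length, mismatch, gapopen = int(f[4]), int(f[5]), int(f[6])
                    qstart, qend, sstart, send = map(int, f[7:11])
                    evalue, bitscore = float(f[11]), float(f[12])
                    qlen, slen = int(f[13]), int(f[14])
                else:
                    # no ppos column: similarity falls back to identity
                    ppos = pident
                    length, mismatch, gapopen = int(f[3]), int(f[4]), int(f[5])
                    qstart, qend, sstart, send = map(int, f[6:10])
                    evalue, bitscore = float(f[10]), float(f[11])
                    if qid not in qlens:
                        raise DataError(
                            f"{path}:{lineno}: query {qid!r} missing from the "
                            "supplied length mapping (12-column input has no qlen)"
                        )
                    if sid not in slens:
                        raise DataError(
                            f"{path}:{lineno}: subject {sid!r} missing from the "
                            "supplied length mapping (12-column input has no slen)"
                        )
                    qlen, slen = qlens[qid], slens[sid]
            except DataError:
                raise
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed numeric field ({exc})") from exc
            qlens.setdefault(qid, qlen)
            slens.setdefault(sid, slen)
            hsp = _build_hsp(
                qid, sid, pident, ppos, length, mismatch, gapopen,
                qstart, qend, sstart, send, evalue, bitscore, qlen, slen,
            )
            results.setdefault(qid, QueryResult(qid, qlen)).hsps.append(hsp)
            n_rows += 1
    run = BlastRun(
        direction=direction,
        program=program,
        parameters={},
        query_results=results,
        query_lengths=qlens,
        subject_lengths=slens,
        source_path=str(path),
        source_format="tabular",
    )
    if query_lengths:
        run.ensure_all_queries(query_lengths)
    return run


def _gap_opens(query_seq: str, sbjct_seq: str) -> int:
    """Gap openings = runs of '-' across both alignment strings."""
    n = 0
    for s in (query_seq, sbjct_seq):
        in_gap = False
        for c in s:
            if c == "-":
                if not in_gap:
                    n += 1
                in_gap = True
            else:
                in_gap = False
    return n


def _first_token(text: str) -> str:
    return text.split()[0] if text.split() else text


def parse_xml(path, direction: Direction = Direction.A_VS_B) -> BlastRun:
    """Parse BLAST XML (``-outfmt 5``) into the same model as parse_tabular.

    Sequence lengths come from the XML itself; identity and similarity are
    recomputed as 100·identities/align_length and 100·positives/align_length;
    queries with zero hits are retained as empty results.
    """
    path = Path(path)
    results: Dict[str, QueryResult] = {}
    qlens: Dict[str, int] = {}
    slens: Dict[str, int] = {}
    program = None
    try:
        with open(path, encoding="utf-8") as fh:
            for rec in NCBIXML.parse(fh):
                program = rec.application.lower() if rec.application else program
                qid = _first_token(rec.query)
                qlen = int(rec.query_length)
                qlens[qid] = qlen
                qr = results.setdefault(qid, QueryResult(qid, qlen))
                for aln in rec.alignments:
                    sid = aln.hit_id
                    if sid.startswith("gnl|BL_ORD_ID|"):
                        sid = _first_token(aln.hit_def)
                    slen = int(aln.length)
                    slens[sid] = slen
                    for h in aln.hsps:
                        qr.hsps.append(
                            _build_hsp(
                                qid,
                                sid,
                                100.0 * h.identities / h.align_length,
                                100.0 * (h.positives if h.positives is not None else h.identities)
                                / h.align_length,
                                h.align_length,
                                h.align_length - h.identities - (h.gaps or 0),
                                _gap_opens(h.query or "", h.sbjct or ""),
                                h.query_start,
                                h.query_end,
                                h.sbjct_start,
                                h.sbjct_end,
                                float(h.expect),
                                float(h.bits),
                                qlen,
                                slen,
                            )
                        )
    except DataError:
        raise
    except Exception as exc:  # malformed / truncated XML
        raise DataError(f"{path}: cannot parse BLAST XML ({exc})") from exc
    return BlastRun(
        direction=direction,
        program=program,
        parameters={},
        query_results=results,
        query_lengths=qlens,
        subject_lengths=slens,
        source_path=str(path),
        source_format="xml",
    )


@dataclass(frozen=True)
class BlastParams:
    """Search settings handed to the BLAST+ binaries.

    Defaults follow BLAST+ itself; only the e-value cutoff is pinned
    explicitly (10, the BLAST default).
    """

    evalue: float = 10.0
    word_size: Optional[int] = None
    gapopen: Optional[int] = None
    gapextend: Optional[int] = None
    matrix: Optional[str] = None

    def to_args(self) -> List[str]:
        args = ["-evalue", str(self.evalue)]
        for flag, value in (
            ("-word_size", self.word_size),
            ("-gapopen", self.gapopen),
            ("-gapextend", self.gapextend),
            ("-matrix", self.matrix),
        ):
            if value is not None:
                args += [flag, str(value)]
        return args

    def as_dict(self) -> Dict[str, object]:
        return {k: v for k, v in asdict(self).items() if v is not None}


def select_program(query_alphabet: Alphabet, db_alphabet: Alphabet) -> str:
    """blastp for protein/protein, blastn for nucleotide/nucleotide,
    blastx for nucleotide query vs protein database; anything else is
    unsupported (tblastn/tblastx are out of scope)."""
    if query_alphabet == Alphabet.PROTEIN and db_alphabet == Alphabet.PROTEIN:
        return "blastp"
    if query_alphabet == Alphabet.NUCLEOTIDE and db_alphabet == Alphabet.NUCLEOTIDE:
        return "blastn"
    if query_alphabet == Alphabet.NUCLEOTIDE and db_alphabet == Alphabet.PROTEIN:
        return "blastx"
    raise DataError(
        "protein query against a nucleotide database requires tblastn, "
        "which is not supported"
    )


def _require_binary(name: str) -> str:
    exe = shutil.which(name)
    if exe is None:
        raise DataError(
            f"BLAST+ binary {name!r} not found on PATH; install the NCBI "
            "BLAST+ suite (makeblastdb, blastp, blastn, blastx)"
        )
    return exe


def _run(cmd: List[str]) -> None:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise DataError(
            f"{cmd[0]} exited with status {proc.returncode}: {proc.stderr.strip()}"
        )


def _dataset_alphabet(records: List[SequenceRecord]) -> Alphabet:
    if all(r.alphabet == Alphabet.NUCLEOTIDE for r in records):
        return Alphabet.NUCLEOTIDE
    return Alphabet.PROTEIN


def _one_direction(
    query_fasta: Path,
    db_fasta: Path,
    query_records: List[SequenceRecord],
    db_records: List[SequenceRecord],
    params: BlastParams,
    direction: Direction,
    workdir: Path,
    tag: str,
) -> BlastRun:
    q_alpha = _dataset_alphabet(query_records)
    db_alpha = _dataset_alphabet(db_records)
    program = select_program(q_alpha, db_alpha)
    _require_binary("makeblastdb")
    _require_binary(program)
    db_prefix = workdir / f"db_{tag}"
    dbtype = "prot" if db_alpha == Alphabet.PROTEIN else "nucl"
    _run(
        ["makeblastdb", "-in", str(db_fasta), "-dbtype", dbtype,
         "-out", str(db_prefix), "-parse_seqids"]
    )
    out_xml = workdir / f"{tag}.xml"
    _run(
        [program, "-query", str(query_fasta), "-db", str(db_prefix),
         "-outfmt", "5", "-out", str(out_xml)] + params.to_args()
    )
    run = parse_xml(out_xml, direction=direction)
    run.program = program
    run.parameters = params.as_dict()
    # registries cover the whole datasets, not only sequences with hits
    run.ensure_all_queries({r.id: r.length for r in query_records})
    for r in db_records:
        run.subject_lengths.setdefault(r.id, r.length)
    return run


def run_reciprocal_blast(
    dataset_a,
    dataset_b=None,
    params: Optional[BlastParams] = None,
    workdir=None,
) -> Union[Tuple[BlastRun, BlastRun], BlastRun]:
    """All-vs-all reciprocal BLAST between two FASTA datasets.

    Each dataset is formatted as a database and searched with the other's
    sequences as queries, giving an (A→B, B→A) pair of runs.  With
    ``dataset_b`` absent the dataset is searched against itself and a
    single self-directed run is returned.  Raw XML outputs are kept in
    ``workdir`` (a temporary directory by default) for alignment retrieval.
    """
    params = params or BlastParams()
    if workdir is None:
        workdir = Path(tempfile.mkdtemp(prefix="reciblast_"))
    else:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
    dataset_a = Path(dataset_a)
    records_a = read_fasta(dataset_a)
    if dataset_b is None:
        return _one_direction(
            dataset_a, dataset_a, records_a, records_a, params,
            Direction.SELF, workdir, "self",
        )
    dataset_b = Path(dataset_b)
    records_b = read_fasta(dataset_b)
    alpha_a = _dataset_alphabet(records_a)
    alpha_b = _dataset_alphabet(records_b)
    if alpha_a != alpha_b:
        raise DataError(
            "mixed protein/nucleotide dataset pairs cannot be searched "
            "reciprocally: one direction would require tblastn, which is "
            "not supported (blastx covers only nucleotide query vs protein db)"
        )
    run_ab = _one_direction(
        dataset_a, dataset_b, records_a, records_b, params,
        Direction.A_VS_B, workdir, "ab",
    )
    run_ba = _one_direction(
        dataset_b, dataset_a, records_b, records_a, params,
        Direction.B_VS_A, workdir, "ba",
    )
    return run_ab, run_ba
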