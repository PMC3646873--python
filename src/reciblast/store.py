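"""Compact alignment-free on-disk store for reciprocal sessions.

The store keeps two JSON documents plus the retained raw BLAST outputs:

* ``manifest.json`` — schema version, dataset id/length registries,
  programs and search parameters, active filter, raw-file names;
* ``hsp_index.json`` — every HSP record, per direction and per query,
  WITHOUT alignment text (the bulky part of BLAST output), plus byte
  offsets into the raw XML files from which each alignment block can be
  re-read lazily;
* ``raw/ab.xml`` / ``raw/ba.xml`` (or ``.tsv``) — the untouched outputs.

Serialization is deterministic (sorted keys, no timestamps), so saving
the same session twice produces byte-identical files, and a load of a
save reproduces every HSP field exactly (JSON round-trips Python floats
losslessly).
"""

from __future__ import annotations

import json
import re
import shutil
from pathlib import Path
from typing import Dict, List, Optional, Tuple
from xml.etree import ElementTree

from . import __version__
from .filtering import FilterSpec
from .logic import ReciprocalSession
from .model import (
    BlastRun,
    DataError,
    Direction,
    Hsp,
    NotFoundError,
    QueryResult,
    StoreIntegrityError,
)

SCHEMA_VERSION = "1"

_HSP_FIELDS = (
    "query_id", "subject_id", "percent_identity", "percent_similarity",
    "align_length", "mismatches", "gap_opens", "q_start", "q_end",
    "s_start", "s_end", "evalue", "bitscore", "q_len", "s_len",
    "coverage", "inv_cov",
)


def _index_xml_alignments(path: Path) -> Dict[Tuple[str, str], List[Tuple[int, int]]]:
    """Byte spans of every <Hsp> element, keyed by (query id, subject id),
    in emission order."""
    data = path.read_bytes()
    out: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for it in re.finditer(rb"<Iteration>.*?</Iteration>", data, re.S):
        m = re.search(rb"<Iteration_query-def>(.*?)</Iteration_query-def>", it.group(0))
        if m is None:
            continue
        qid = m.group(1).decode().split()[0]
        for hit in re.finditer(rb"<Hit>.*?</Hit>", it.group(0), re.S):
            hid = re.search(rb"<Hit_id>(.*?)</Hit_id>", hit.group(0))
            sid = hid.group(1).decode() if hid else ""
            if sid.startswith("gnl|BL_ORD_ID|"):
                hdef = re.search(rb"<Hit_def>(.*?)</Hit_def>", hit.group(0))
                sid = hdef.group(1).decode().split()[0] if hdef else sid
            for hsp in re.finditer(rb"<Hsp>.*?</Hsp>", hit.group(0), re.S):
                start = it.start() + hit.start() + hsp.start()
                end = it.start() + hit.start() + hsp.end()
                out.setdefault((qid, sid), []).append((start, end))
    return out


def _run_to_index(run: BlastRun, raw_name: Optional[str], store_dir: Path) -> Dict:
    locator: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    if raw_name and run.source_format == "xml":
        locator = _index_xml_alignments(store_dir / "raw" / raw_name)
    queries = []
    for qr in run.query_results.values():
        counter: Dict[str, int] = {}
        hsps = []
        for h in qr.hsps:
            ordinal = counter.get(h.subject_id, 0)
            counter[h.subject_id] = ordinal + 1
            rec = {f: getattr(h, f) for f in _HSP_FIELDS}
            spans = locator.get((h.query_id, h.subject_id))
            if spans and ordinal < len(spans):
                rec["align_offset"] = list(spans[ordinal])
            hsps.append(rec)
        queries.append(
            {"query_id": qr.query_id, "query_length": qr.query_length, "hsps": hsps}
        )
    return {
        "direction": run.direction.value,
        "program": run.program,
        "parameters": run.parameters,
        "query_lengths": run.query_lengths,
        "subject_lengths": run.subject_lengths,
        "raw_file": raw_name,
        "raw_format": run.source_format if raw_name else None,
        "queries": queries,
    }


def _retain_raw(run: BlastRun, tag: str, store_dir: Path) -> Optional[str]:
    if not run.source_path:
        return None
    src = Path(run.source_path)
    if not src.exists():
        return None
    ext = "xml" if run.source_format == "xml" else "tsv"
    name = f"{tag}.{ext}"
    raw_dir = store_dir / "raw"
    raw_dir.mkdir(parents=True, exist_ok=True)
    dst = raw_dir / name
    if src.resolve() != dst.resolve():
        shutil.copyfile(src, dst)
    return name


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def save_session(session: ReciprocalSession, directory) -> Dict:
    """Persist a session; returns the manifest."""
    store_dir = Path(directory)
    store_dir.mkdir(parents=True, exist_ok=True)
    raw_ab = _retain_raw(session.run_ab, "ab", store_dir)
    raw_ba = (
        raw_ab
        if session.is_self
        else _retain_raw(session.run_ba, "ba", store_dir)
    )
    index = {"ab": _run_to_index(session.run_ab, raw_ab, store_dir)}
    if not session.is_self:
        index["ba"] = _run_to_index(session.run_ba, raw_ba, store_dir)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "generator": f"reciblast {__version__}",
        "self_session": session.is_self,
        "programs": {
            "ab": session.run_ab.program,
            "ba": None if session.is_self else session.run_ba.program,
        },
        "parameters": session.run_ab.parameters,
        "datasets": {
            "a": session.run_ab.query_lengths,
            "b": session.run_ab.subject_lengths,
        },
        "filter": {k: list(v) for k, v in session.filter_spec.ranges.items()},
        "raw_files": {"ab": raw_ab, "ba": raw_ba},
    }
    _dump_json(manifest, store_dir / "manifest.json")
    _dump_json(index, store_dir / "hsp_index.json")
    return manifest


def _index_to_run(doc: Dict, store_dir: Path) -> BlastRun:
    results: Dict[str, QueryResult] = {}
    for q in doc["queries"]:
        qr = QueryResult(q["query_id"], q["query_length"])
        for rec in q["hsps"]:
            qr.hsps.append(Hsp(**{f: rec[f] for f in _HSP_FIELDS}))
        results[qr.query_id] = qr
    raw = doc.get("raw_file")
    return BlastRun(
        direction=Direction(doc["direction"]),
        program=doc.get("program"),
        parameters=doc.get("parameters", {}),
        query_results=results,
        query_lengths={k: int(v) for k, v in doc["query_lengths"].items()},
        subject_lengths={k: int(v) for k, v in doc["subject_lengths"].items()},
        source_path=str(store_dir / "raw" / raw) if raw else None,
        source_format=doc.get("raw_format"),
    )


class SessionStore:
    """A loaded store directory: the session plus lazy alignment access."""

    def __init__(self, directory):
        self.directory = Path(directory)
        manifest_path = self.directory / "manifest.json"
        index_path = self.directory / "hsp_index.json"
        if not manifest_path.exists() or not index_path.exists():
            raise StoreIntegrityError(
                f"{self.directory}: not a session store (manifest.json / hsp_index.json missing)"
            )
        with open(manifest_path, encoding="utf-8") as fh:
            self.manifest = json.load(fh)
        with open(index_path, encoding="utf-8") as fh:
            self._index = json.load(fh)
        run_ab = _index_to_run(self._index["ab"], self.directory)
        run_ba = (
            run_ab if "ba" not in self._index else _index_to_run(self._index["ba"], self.directory)
        )
        spec = FilterSpec(
            {k: (v[0], v[1]) for k, v in self.manifest.get("filter", {}).items()}
        )
        self.session = ReciprocalSession(run_ab, run_ba, spec)

    def _hsp_record(self, direction: Direction, query_id: str, subject_id: str, ordinal: int) -> Dict:
        key = "ab" if direction in (Direction.A_VS_B, Direction.SELF) else "ba"
        if key not in self._index:
            key = "ab"
        doc = self._index[key]
        for q in doc["queries"]:
            if q["query_id"] != query_id:
                continue
            n = 0
            for rec in q["hsps"]:
                if rec["subject_id"] == subject_id:
                    if n == ordinal:
                        return rec | {"_raw": doc.get("raw_file")}
                    n += 1
            raise NotFoundError(
                f"no HSP #{ordinal} of {query_id!r} on {subject_id!r} in the {key} run"
            )
        raise NotFoundError(f"unknown query {query_id!r} in the {key} run")

    def fetch_alignment(
        self, direction: Direction, query_id: str, subject_id: str, ordinal: int = 0
    ) -> str:
        """Re-read one pairwise alignment block from the retained raw output.

        The HSP index holds no alignment text; this resolves the stored
        byte offsets and formats the block (query line, match line,
        subject line) from the raw XML.
        """
        rec = self._hsp_record(direction, query_id, subject_id, ordinal)
        offset = rec.get("align_offset")
        raw = rec.pop("_raw", None)
        if offset is None or raw is None:
            raise NotFoundError(
                f"no retained alignment for {query_id!r} vs {subject_id!r} "
                "(store was built from alignment-free tabular input)"
            )
        raw_path = self.directory / "raw" / raw
        if not raw_path.exists():
            raise StoreIntegrityError(f"raw output {raw_path} is missing or moved")
        with open(raw_path, "rb") as fh:
            fh.seek(offset[0])
            fragment = fh.read(offset[1] - offset[0])
        try:
            el = ElementTree.fromstring(fragment)
        except ElementTree.ParseError as exc:
            raise StoreIntegrityError(
                f"{raw_path}: stale alignment offsets ({exc})"
            ) from exc
        get = lambda tag: (el.findtext(tag) or "")
        return format_alignment_block(
            query_id,
            subject_id,
            int(get("Hsp_query-from")),
            int(get("Hsp_query-to")),
            int(get("Hsp_hit-from")),
            int(get("Hsp_hit-to")),
            get("Hsp_qseq"),
            get("Hsp_midline"),
            get("Hsp_hseq"),
        )


def format_alignment_block(
    query_id: str,
    subject_id: str,
    q_from: int,
    q_to: int,
    s_from: int,
    s_to: int,
    qseq: str,
    midline: str,
    hseq: str,
    width: int = 60,
) -> str:
    """Render one HSP as a classic pairwise text alignment."""
    lines = [f"Query: {query_id}  Subject: {subject_id}", ""]
    q_step = 1 if q_to >= q_from else -1
    s_step = 1 if s_to >= s_from else -1
    q_pos, s_pos = q_from, s_from
    for i in range(0, len(qseq), width):
        qc, mc, sc = qseq[i:i + width], midline[i:i + width], hseq[i:i + width]
        q_adv = sum(1 for c in qc if c != "-")
        s_adv = sum(1 for c in sc if c != "-")
        q_end = q_pos + q_step * (q_adv - 1) if q_adv else q_pos
        s_end = s_pos + s_step * (s_adv - 1) if s_adv else s_pos
        lines.append(f"Query  {q_pos:<6d} {qc}  {q_end}")
        lines.append(f"       {'':<6s} {mc}")
        lines.append(f"Sbjct  {s_pos:<6d} {sc}  {s_end}")
        lines.append("")
        q_pos = q_end + q_step if q_adv else q_pos
        s_pos = s_end + s_step if s_adv else s_pos
    return "\n".join(lines).rstrip() + "\n"


def load_session(directory) -> ReciprocalSession:
    """Load a saved store back into a session."""
    return SessionStore(directory).session


def fetch_alignment(store: SessionStore, direction: Direction, query_id: str, subject_id: str, ordinal: int = 0) -> str:
    """Functional alias for :meth:`SessionStore.fetch_alignment`."""
    return store.fetch_alignment(direction, query_id, subject_id, ordinal)
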