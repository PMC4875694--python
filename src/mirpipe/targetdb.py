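"""Single-file SQLite store of predicted and validated miRNA-target pairs.

Public target resources (TargetScan-like prediction tables, miRTarBase-like
validation tables, or custom pair lists) are ingested from generic TSV
files through a per-source column mapping, so the store does not depend on
any resource's native dump format. Each store keeps one evidence row per
(miRNA, target, source); exact duplicates within a source collapse to one
row keeping the maximum score. Queries aggregate per (miRNA, target) pair,
reporting the supporting sources and predicted/validated counts.
"""

from __future__ import annotations

import hashlib
import logging
import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

EVIDENCE_CLASSES = ("predicted", "validated")
TARGET_ID_KINDS = ("gene", "transcript")

_NAME_STYLE_RE = re.compile(r"^[A-Za-z]{3,4}-")


def normalize_mirna_id(raw: str) -> str:
    """Trim whitespace; lower-case 'hsa-...'-style names; preserve accessions.

    No cross-release miRBase name resolution is attempted — callers must
    harmonize releases themselves.
    """
    s = raw.strip()
    if _NAME_STYLE_RE.match(s):
        return s.lower()
    return s


@dataclass(frozen=True)
class TargetEvidence:
    """One (miRNA, target, source) record."""

    mirna_id: str
    target_id: str
    target_id_kind: str
    source_name: str
    evidence_class: str
    score: float | None = None


@dataclass(frozen=True)
class SourceSpec:
    """How to ingest one TSV resource file.

    ``mirna_col`` and ``target_col`` are 0-based column indices (or header
    names when ``header=True``); ``score_col`` is optional.
    """

    path: str
    source_name: str
    evidence_class: str
    mirna_col: int | str = 0
    target_col: int | str = 1
    score_col: int | str | None = None
    target_id_kind: str = "gene"
    header: bool = False

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValidationError(
                f"source {self.source_name}: evidence_class must be one of "
                f"{EVIDENCE_CLASSES}, got {self.evidence_class!r}"
            )
        if self.target_id_kind not in TARGET_ID_KINDS:
            raise ValidationError(
                f"source {self.source_name}: bad target_id_kind {self.target_id_kind!r}"
            )


_SCHEMA = """
CREATE TABLE IF NOT EXISTS sources (
    source_name TEXT PRIMARY KEY,
    evidence_class TEXT NOT NULL,
    n_rows INTEGER NOT NULL,
    checksum TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS evidence (
    mirna_id TEXT NOT NULL,
    target_id TEXT NOT NULL,
    target_id_kind TEXT NOT NULL,
    source_name TEXT NOT NULL,
    evidence_class TEXT NOT NULL,
    score REAL,
    PRIMARY KEY (mirna_id, target_id, source_name)
);
CREATE INDEX IF NOT EXISTS idx_evidence_target ON evidence (target_id);
"""


def _file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _iter_source_rows(spec: SourceSpec):
    """Yield (mirna_id, target_id, score) triples from a source TSV."""

    def resolve(col, header_fields, what):
        if isinstance(col, int):
            return col
        if header_fields is None or col not in header_fields:
            raise FormatError(
                f"source {spec.source_name}: cannot map {what} column {col!r}"
            )
        return header_fields.index(col)

    with open(spec.path) as fh:
        header_fields = None
        first = True
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if first:
                first = False
                if spec.header:
                    header_fields = fields
                    continue
            mi = resolve(spec.mirna_col, header_fields, "miRNA id")
            ti = resolve(spec.target_col, header_fields, "target id")
            si = (
                resolve(spec.score_col, header_fields, "score")
                if spec.score_col is not None
                else None
            )
            needed = max(mi, ti, si if si is not None else 0)
            if len(fields) <= needed:
                raise FormatError(
                    f"source {spec.source_name} line {lineno}: "
                    f"expected >= {needed + 1} columns, got {len(fields)}"
                )
            score = None
            if si is not None and fields[si].strip():
                try:
                    score = float(fields[si])
                except ValueError as exc:
                    raise FormatError(
                        f"source {spec.source_name} line {lineno}: "
                        f"non-numeric score {fields[si]!r}"
                    ) from exc
            yield normalize_mirna_id(fields[mi]), fields[ti].strip(), score


def build_database(sources: list[SourceSpec], out_path: str | Path) -> Path:
    """Build (or rebuild) the evidence store from a list of sources.

    Within one source, duplicate (miRNA, target) rows collapse to one row
    keeping the maximum score. An empty source file logs a warning and
    contributes zero rows. Rebuilding from identical sources yields
    identical logical content.
    """
    out_path = Path(out_path)
    if out_path.exists():
        out_path.unlink()
    con = sqlite3.connect(out_path)
    try:
        con.executescript(_SCHEMA)
        for spec in sources:
            n = 0
            for mirna_id, target_id, score in _iter_source_rows(spec):
                cur = con.execute(
                    "SELECT score FROM evidence WHERE mirna_id=? AND target_id=? "
                    "AND source_name=?",
                    (mirna_id, target_id, spec.source_name),
                )
                row = cur.fetchone()
                if row is None:
                    con.execute(
                        "INSERT INTO evidence VALUES (?,?,?,?,?,?)",
                        (
                            mirna_id,
                            target_id,
                            spec.target_id_kind,
                            spec.source_name,
                            spec.evidence_class,
                            score,
                        ),
                    )
                    n += 1
                else:
                    old = row[0]
                    best = max(
                        (x for x in (old, score) if x is not None), default=None
                    )
                    if best != old:
                        con.execute(
                            "UPDATE evidence SET score=? WHERE mirna_id=? AND "
                            "target_id=? AND source_name=?",
                            (best, mirna_id, target_id, spec.source_name),
                        )
            if n == 0:
                logger.warning("source %s contributed zero rows", spec.source_name)
            con.execute(
                "INSERT OR REPLACE INTO sources VALUES (?,?,?,?)",
                (
                    spec.source_name,
                    spec.evidence_class,
                    n,
                    _file_checksum(spec.path),
                ),
            )
        con.commit()
    finally:
        con.close()
    return out_path


@dataclass(frozen=True)
class AggregatedPair:
    """Query-time aggregation of all evidence for one (miRNA, target) pair."""

    mirna_id: str
    target_id: str
    sources: tuple[str, ...]
    n_predicted_sources: int
    n_validated_sources: int
    best_score: float | None


def query_pairs(
    store: str | Path,
    mirnas: set[str] | None = None,
    targets: set[str] | None = None,
) -> list[AggregatedPair]:
    """Aggregate evidence per (miRNA, target) pair, optionally filtered.

    Filters are applied after miRNA-id normalization; absent filters mean no
    restriction. Output is deterministically ordered by (mirna_id,
    target_id).
    """
    store = Path(store)
    if not store.exists():
        raise ValidationError(f"store {store} does not exist")
    con = sqlite3.connect(store)
    try:
        try:
            rows = con.execute(
                "SELECT mirna_id, target_id, source_name, evidence_class, score "
                "FROM evidence ORDER BY mirna_id, target_id, source_name"
            ).fetchall()
        except sqlite3.DatabaseError as exc:
            raise FormatError(f"malformed store {store}: {exc}") from exc
    finally:
        con.close()
    if mirnas is not None:
        mirnas = {normalize_mirna_id(m) for m in mirnas}
    out: list[AggregatedPair] = []
    current: tuple[str, str] | None = None
    bucket: list[tuple[str, str, float | None]] = []

    def flush():
        if current is None:
            return
        srcs = tuple(s for s, _, _ in bucket)
        scores = [sc for _, _, sc in bucket if sc is not None]
        out.append(
            AggregatedPair(
                mirna_id=current[0],
                target_id=current[1],
                sources=srcs,
                n_predicted_sources=sum(1 for _, c, _ in bucket if c == "predicted"),
                n_validated_sources=sum(1 for _, c, _ in bucket if c == "validated"),
                best_score=max(scores) if scores else None,
            )
        )

    for mirna_id, target_id, source_name, evidence_class, score in rows:
        if mirnas is not None and mirna_id not in mirnas:
            continue
        if targets is not None and target_id not in targets:
            continue
        key = (mirna_id, target_id)
        if key != current:
            flush()
            current = key
            bucket = []
        bucket.append((source_name, evidence_class, score))
    flush()
    return out


def export_pairs_tsv(pairs: list[AggregatedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna_id\ttarget_id\tsources\tn_predicted_sources\t"
            "n_validated_sources\tbest_score\n"
        )
        for p in pairs:
            score = "" if p.best_score is None else f"{p.best_score:.6g}"
            fh.write(
                f"{p.mirna_id}\t{p.target_id}\t{','.join(p.sources)}\t"
                f"{p.n_predicted_sources}\t{p.n_validated_sources}\t{score}\n"
            )
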