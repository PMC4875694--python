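"""Readers and writers for the toolkit's on-disk formats.

Covers tab-delimited sample sheets, FASTA sequence files (RNA or DNA
alphabet), GFF3 (miRBase dialect) and GTF (Ensembl dialect) annotation,
expression matrices as self-describing TSV, the miRBase-GFF3 ->
quantification-annotation conversion, and small-RNA annotation extraction.

Coordinates in :class:`FeatureRecord` are kept 1-based inclusive exactly as
they appear in GFF/GTF files; interval arithmetic elsewhere in the package
uses 0-based half-open coordinates with explicit converters.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")
DNA_ALPHABET = frozenset("ACGTN")

#: Valid units for an expression matrix, roughly in processing order.
MATRIX_UNITS = (
    "raw_count",
    "cpm",
    "size_factor_scaled",
    "upper_quartile_scaled",
    "fpkm",
    "log2_fpkm",
    "log2",
)


@dataclass(frozen=True)
class SampleRecord:
    """One row of a sample sheet: a unique id, a file path and optional labels."""

    sample_id: str
    path: str
    treatment: str | None = None
    sample: str | None = None


@dataclass
class FeatureRecord:
    """One annotation feature with 1-based inclusive genomic coordinates."""

    feature_id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    feature_type: str
    biotype: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid coordinates for {self.feature_id}: "
                f"require 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"invalid strand {self.strand!r} for {self.feature_id}"
            )

    @property
    def length(self) -> int:
        """Feature length in nucleotides (end - start + 1)."""
        return self.end - self.start + 1

    def to_zero_based(self) -> tuple[int, int]:
        """Return (start, end) as a 0-based half-open interval."""
        return self.start - 1, self.end


class ExpressionMatrix:
    """A features x samples numeric table with a declared unit.

    Wraps a pandas DataFrame (rows = features, columns = samples) and
    validates the unit contract: raw counts must be non-negative integers,
    every unit requires finite values, and ids must be unique.
    """

    def __init__(self, values: pd.DataFrame, unit: str):
        if unit not in MATRIX_UNITS:
            raise ValidationError(f"unknown matrix unit {unit!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature id(s): {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("matrix contains non-finite values")
        if unit == "raw_count":
            if (arr < 0).any() or not np.array_equal(arr, np.round(arr)):
                raise ValidationError(
                    "raw_count matrix must hold non-negative integers"
                )
        self.values = values
        self.unit = unit

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nf, ns = self.values.shape
        return f"ExpressionMatrix({nf} features x {ns} samples, unit={self.unit})"


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a tab-delimited sample sheet.

    Columns: sample_id, path, then optional treatment and sample labels. A
    first line starting with ``#`` or whose first field is ``sample_id`` is
    treated as a header and skipped. Duplicate sample ids are an error.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and (
                line.startswith("#") or fields[0].strip().lower() == "sample_id"
            ):
                continue
            if len(fields) < 2:
                raise FormatError(
                    f"sample sheet {path.name} line {lineno}: "
                    "expected at least 2 tab-separated columns (id, path)"
                )
            sid = fields[0].strip()
            fpath = fields[1].strip()
            if not fpath:
                raise ValidationError(
                    f"sample sheet line {lineno}: empty path for sample {sid}"
                )
            if sid in seen:
                raise ValidationError(f"duplicate sample id {sid}")
            seen.add(sid)
            treatment = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
            sample = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
            records.append(SampleRecord(sid, fpath, treatment, sample))
    return records


def write_sample_sheet(records: list[SampleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fields = [r.sample_id, r.path]
            if r.treatment is not None or r.sample is not None:
                fields.append(r.treatment or "")
            if r.sample is not None:
                fields.append(r.sample)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str) -> dict[str, str]:
    """Read a FASTA file into an id -> upper-cased sequence map.

    ``alphabet`` is ``"rna"`` (A,C,G,U,N) or ``"dna"`` (A,C,G,T,N). The id is
    the header token before the first whitespace. Characters outside the
    alphabet and duplicate ids are errors.
    """
    if alphabet == "rna":
        allowed = RNA_ALPHABET
    elif alphabet == "dna":
        allowed = DNA_ALPHABET
    else:
        raise ValidationError(f"unknown alphabet {alphabet!r}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for offset, ch in enumerate(seq):
            if ch not in allowed:
                raise FormatError(
                    f"record {rec.id}: character {ch!r} at offset {offset} "
                    f"not in {alphabet} alphabet"
                )
        if rec.id in out:
            raise ValidationError(f"duplicate sequence id {rec.id}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')

#: attribute keys probed, in order, for the biotype of a GTF feature
BIOTYPE_KEYS = ("gene_biotype", "transcript_biotype", "biotype")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _GTF_ATTR_RE.finditer(text)}


def read_features(path: str | Path, dialect: str) -> list[FeatureRecord]:
    """Parse a 9-column GFF3 (miRBase dialect) or GTF (Ensembl dialect) file.

    Coordinates are kept 1-based inclusive. GFF3 requires an ``ID``
    attribute; GTF requires ``gene_id``. Unknown feature types are retained.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValidationError(f"unknown annotation dialect {dialect!r}")
    path = Path(path)
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path.name} line {lineno}: expected 9 columns, got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise FormatError(f"coordinate order, line {lineno}: {start} > {end}")
            if dialect == "gff3":
                attrs = _parse_gff3_attributes(attr_s)
                if "ID" not in attrs:
                    raise FormatError(
                        f"{path.name} line {lineno}: missing mandatory GFF3 "
                        "attribute 'ID'"
                    )
                feature_id = attrs["ID"]
                gene_id = attrs.get("Derives_from", feature_id)
                biotype = attrs.get("biotype", "")
            else:
                attrs = _parse_gtf_attributes(attr_s)
                if "gene_id" not in attrs:
                    raise FormatError(
                        f"{path.name} line {lineno}: missing mandatory GTF "
                        "attribute 'gene_id'"
                    )
                gene_id = attrs["gene_id"]
                feature_id = attrs.get("transcript_id", gene_id)
                biotype = ""
                for key in BIOTYPE_KEYS:
                    if key in attrs:
                        biotype = attrs[key]
                        break
            try:
                features.append(
                    FeatureRecord(
                        feature_id=feature_id,
                        gene_id=gene_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        feature_type=ftype,
                        biotype=biotype,
                        attributes=attrs,
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from exc
    return features


def mirbase_to_quant_annotation(
    features: list[FeatureRecord], level: str
) -> list[FeatureRecord]:
    """Convert miRBase-dialect GFF3 features into quantifiable exon-like records.

    miRBase annotates precursors as ``miRNA_primary_transcript`` and mature
    strands as ``miRNA`` with a ``Derives_from`` link; Ensembl-style
    quantification needs one exon-like record per unit with gene and
    transcript ids. ``level="mature"`` emits one record per mature miRNA
    (transcript_id = its ID, gene_id = Derives_from, falling back to its own
    ID with a warning); ``level="precursor"`` emits one record per hairpin.
    Coordinates and strand are preserved exactly; other feature types are
    ignored.
    """
    if level not in ("mature", "precursor"):
        raise ValidationError(f"unknown level {level!r}")
    wanted = "miRNA" if level == "mature" else "miRNA_primary_transcript"
    out: list[FeatureRecord] = []
    for f in features:
        if f.feature_type != wanted:
            continue
        gene_id = f.attributes.get("Derives_from") if level == "mature" else f.feature_id
        if level == "mature" and not gene_id:
            logger.warning(
                "mature miRNA %s has no Derives_from; using its own ID as gene_id",
                f.feature_id,
            )
            gene_id = f.feature_id
        out.append(
            FeatureRecord(
                feature_id=f.feature_id,
                gene_id=gene_id,
                chrom=f.chrom,
                start=f.start,
                end=f.end,
                strand=f.strand,
                feature_type="exon",
                biotype="miRNA",
                attributes={
                    "gene_id": gene_id,
                    "transcript_id": f.feature_id,
                    "Name": f.attributes.get("Name", f.feature_id),
                },
            )
        )
    if level == "mature" and not out:
        raise ValidationError("no mature annotations (no type-miRNA features)")
    return out


#: default size-selection bounds (nt) for small-RNA annotation extraction
SMALL_RNA_MIN_LEN = 15
SMALL_RNA_MAX_LEN = 80


def extract_small_rna_annotation(
    features: list[FeatureRecord],
    min_len: int = SMALL_RNA_MIN_LEN,
    max_len: int = SMALL_RNA_MAX_LEN,
    biotypes: set[str] | frozenset[str] = frozenset({"miRNA", "snoRNA", "snRNA", "misc_RNA", "rRNA", "tRNA"}),
) -> list[FeatureRecord]:
    """Size-select small-RNA features by biotype and length (default 15-80 nt)."""
    if not biotypes:
        raise ValidationError("empty biotype set")
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} > max_len {max_len}")
    return [
        f for f in features if f.biotype in biotypes and min_len <= f.length <= max_len
    ]


# ---------------------------------------------------------------------------
# expression matrix TSV
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as self-describing TSV.

    First line is a ``#unit=<unit>`` comment, then a header row whose first
    cell is literally ``feature_id`` followed by sample ids. Integer counts
    are written exactly; floats with 12 significant digits.
    """
    is_int = matrix.unit == "raw_count"
    with open(path, "w") as fh:
        fh.write(f"#unit={matrix.unit}\n")
        fh.write("feature_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for fid, row in matrix.values.iterrows():
            if is_int:
                cells = [str(int(v)) for v in row]
            else:
                cells = [f"{v:.12g}" for v in row]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_matrix`."""
    path = Path(path)
    unit = "raw_count"
    rows: list[tuple[str, list[float]]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#unit="):
                    unit = line[len("#unit=") :].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise FormatError(
                    f"{path.name} row {lineno}: expected {len(header) + 1} "
                    f"columns, got {len(fields)}"
                )
            values = []
            for j, cell in enumerate(fields[1:]):
                try:
                    v = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"{path.name}: non-numeric cell at row {lineno}, "
                        f"sample {header[j]}: {cell!r}"
                    ) from exc
                if not math.isfinite(v):
                    raise FormatError(
                        f"{path.name}: non-finite cell at row {lineno}, "
                        f"sample {header[j]}"
                    )
                values.append(v)
            rows.append((fields[0], values))
    if header is None:
        raise FormatError(f"{path.name}: missing header row")
    ids = [fid for fid, _ in rows]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate feature id {dup}")
    df = pd.DataFrame([v for _, v in rows], index=ids, columns=header)
    return ExpressionMatrix(df, unit)
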