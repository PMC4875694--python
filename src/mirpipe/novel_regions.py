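"""Merging per-sample putative small-RNA predictions into genomic regions.

Novel-miRNA discovery tools emit per-sample tables of candidate intervals
with read counts. Candidates from different samples describing the same
locus are merged here: two predictions belong to the same region iff they
are connected through a chain of same-chromosome, same-strand interval
overlaps (>= 1 bp by default; a merge gap can widen the linking distance).
Each region spans the union bounds of its constituents, sums constituent
counts per sample, and becomes one row of a unified raw-count matrix whose
row ids use the 1-based inclusive display convention
``chrom:start-end(strand)``.

Merged regions can then be annotated with overlapping known features
(strand-agnostic by default — genomic context matters more than orientation
for a candidate locus; a strict-strand flag is available).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError, ValidationError
from .io_formats import ExpressionMatrix, FeatureRecord


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval on a strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def display_id(self) -> str:
        """1-based inclusive display form, e.g. ``chr5:181243270-181243420(-)``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}({self.strand})"


@dataclass
class NovelRegion:
    """A merged region with per-sample summed counts and annotations."""

    interval: GenomicInterval
    per_sample_counts: dict[str, int]
    n_constituents: int
    annotations: list[str] = field(default_factory=list)

    @property
    def region_id(self) -> str:
        return self.interval.display_id


Prediction = tuple[str, GenomicInterval, int]


def read_prediction_table(path: str | Path, sample_id: str) -> list[Prediction]:
    """Read a BED-like per-sample prediction table.

    Columns: chrom, start, end, strand, count (0-based half-open, tab
    separated; lines starting with ``#`` or a ``chrom`` header are skipped).
    """
    preds: list[Prediction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":
                continue
            if len(fields) < 5:
                raise FormatError(
                    f"{Path(path).name} line {lineno}: expected 5 columns "
                    "(chrom, start, end, strand, count)"
                )
            try:
                start, end, count = int(fields[1]), int(fields[2]), int(fields[4])
            except ValueError as exc:
                raise FormatError(
                    f"{Path(path).name} line {lineno}: non-integer field"
                ) from exc
            if count < 0:
                raise ValidationError(
                    f"{Path(path).name} line {lineno}: negative count"
                )
            preds.append(
                (sample_id, GenomicInterval(fields[0], start, end, fields[3]), count)
            )
    return preds


def merge_predictions(
    predictions: list[Prediction], merge_gap: int = 0
) -> tuple[list[NovelRegion], ExpressionMatrix]:
    """Merge overlapping predictions into regions and build a count matrix.

    Predictions are grouped per (chrom, strand), sorted by start, and swept:
    a prediction starting within ``merge_gap`` of the running region end
    (default 0, i.e. >= 1 bp true overlap) extends the current region,
    otherwise a new region starts. Counts from the same sample sum within a
    region. The matrix rows follow region order (chrom, strand, start);
    columns are all sample ids in sorted order.
    """
    if not predictions:
        raise ValidationError("no predictions to merge")
    for sid, iv, count in predictions:
        if count < 0:
            raise ValidationError(f"negative count for {sid} at {iv.display_id}")

    by_key: dict[tuple[str, str], list[Prediction]] = defaultdict(list)
    for p in predictions:
        by_key[(p[1].chrom, p[1].strand)].append(p)

    regions: list[NovelRegion] = []
    for key in sorted(by_key):
        chrom, strand = key
        group = sorted(by_key[key], key=lambda p: (p[1].start, p[1].end))
        cur: list[Prediction] = []
        cur_end = None
        for p in group:
            if cur_end is not None and p[1].start <= cur_end + merge_gap - 1:
                cur.append(p)
                cur_end = max(cur_end, p[1].end)
            else:
                if cur:
                    regions.append(_finish_region(chrom, strand, cur))
                cur = [p]
                cur_end = p[1].end
        if cur:
            regions.append(_finish_region(chrom, strand, cur))

    sample_ids = sorted({p[0] for p in predictions})
    rows = {
        r.region_id: [r.per_sample_counts.get(s, 0) for s in sample_ids]
        for r in regions
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return regions, ExpressionMatrix(df.astype(float), "raw_count")


def _finish_region(chrom: str, strand: str, members: list[Prediction]) -> NovelRegion:
    start = min(p[1].start for p in members)
    end = max(p[1].end for p in members)
    counts: dict[str, int] = defaultdict(int)
    for sid, _, c in members:
        counts[sid] += c
    return NovelRegion(
        interval=GenomicInterval(chrom, start, end, strand),
        per_sample_counts=dict(counts),
        n_constituents=len(members),
    )


def annotate_regions(
    regions: list[NovelRegion],
    features: list[FeatureRecord],
    strict_strand: bool = False,
) -> list[NovelRegion]:
    """Attach names of known features overlapping each region by >= 1 bp.

    Feature coordinates (1-based inclusive) are converted to 0-based
    half-open before the overlap test. The feature's ``Name`` attribute is
    preferred, falling back to its feature_id. Annotations are sorted and
    de-duplicated; strand is ignored unless ``strict_strand``.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        start, end = f.to_zero_based()
        name = f.attributes.get("Name") or f.feature_id
        trees[f.chrom].addi(start, end, (name, f.strand))
    for r in regions:
        hits = trees[r.interval.chrom].overlap(r.interval.start, r.interval.end)
        names = {
            name
            for iv in hits
            for name, strand in [iv.data]
            if not strict_strand or strand == r.interval.strand
        }
        r.annotations = sorted(names)
    return regions


def write_region_table(regions: list[NovelRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "region_id\tchrom\tstart\tend\tstrand\tn_constituents\tannotations\n"
        )
        for r in regions:
            fh.write(
                f"{r.region_id}\t{r.interval.chrom}\t{r.interval.start}\t"
                f"{r.interval.end}\t{r.interval.strand}\t{r.n_constituents}\t"
                f"{','.join(r.annotations)}\n"
            )
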