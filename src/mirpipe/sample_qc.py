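"""Per-sample read statistics and sample-exclusion filters.

After adapter/quality trimming (performed upstream by whatever trimmer the
user prefers), each sample is summarised by the number of reads before and
after trimming and the mean per-base Phred quality of the trimmed file.
Samples are then excluded when too few reads survived trimming or the mean
quality is poor — both thresholds are user choices with no hidden defaults,
and the comparison is strictly "less than": a sample sitting exactly at a
threshold is kept.

FASTQ input must be Phred+33; convert Phred+64 files upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError, ValidationError

PHRED_OFFSET = 33


@dataclass(frozen=True)
class QCStats:
    """Read-survival and quality summary for one sample."""

    sample_id: str
    reads_total: int
    reads_surviving: int
    mean_quality: float

    def __post_init__(self) -> None:
        if not (0 <= self.reads_surviving <= self.reads_total):
            raise ValidationError(
                f"{self.sample_id}: reads_surviving {self.reads_surviving} "
                f"outside [0, reads_total={self.reads_total}]"
            )
        if self.mean_quality < 0:
            raise ValidationError(f"{self.sample_id}: negative mean quality")

    @property
    def survival_fraction(self) -> float:
        return self.reads_surviving / self.reads_total


def _count_fastq(path: str | Path) -> tuple[int, int, int]:
    """Return (n_reads, total_bases, total_quality) of a 4-line-record FASTQ."""
    n_lines = 0
    total_bases = 0
    total_quality = 0
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.rstrip("\n")
            n_lines += 1
            if i % 4 == 0 and not line.startswith("@"):
                raise FormatError(
                    f"{Path(path).name} line {i + 1}: expected '@' header"
                )
            if i % 4 == 3:
                total_bases += len(line)
                total_quality += sum(ord(c) - PHRED_OFFSET for c in line)
    if n_lines % 4 != 0:
        raise FormatError(
            f"{Path(path).name}: {n_lines} lines is not a multiple of 4"
        )
    return n_lines // 4, total_bases, total_quality


def compute_qc_stats(
    pre_trim: str | Path, post_trim: str | Path, sample_id: str
) -> QCStats:
    """Compute read-survival and mean-quality statistics for one sample.

    Reads are counted as 4-line FASTQ records; ``mean_quality`` is the
    unweighted mean Phred score over all bases of the post-trim file
    (base-weighted, FastQC-style).
    """
    n_pre, _, _ = _count_fastq(pre_trim)
    if n_pre == 0:
        raise ValidationError(f"{sample_id}: zero input reads")
    n_post, bases, qual = _count_fastq(post_trim)
    mean_quality = qual / bases if bases else 0.0
    return QCStats(sample_id, n_pre, n_post, mean_quality)


def filter_samples(
    stats: list[QCStats], min_survival: float, min_mean_quality: float
) -> tuple[list[QCStats], list[tuple[QCStats, list[str]]]]:
    """Partition samples into kept and excluded (with exclusion reasons).

    A sample is excluded iff ``survival_fraction < min_survival`` or
    ``mean_quality < min_mean_quality`` — strict inequalities, so boundary
    samples are kept. Returns ``(kept, excluded)`` where each excluded entry
    carries the triggering rule name(s): "survival", "quality".
    """
    if not (0 <= min_survival <= 1):
        raise ValidationError(f"min_survival must be in [0,1], got {min_survival}")
    kept: list[QCStats] = []
    excluded: list[tuple[QCStats, list[str]]] = []
    for s in stats:
        reasons = []
        if s.survival_fraction < min_survival:
            reasons.append("survival")
        if s.mean_quality < min_mean_quality:
            reasons.append("quality")
        if reasons:
            excluded.append((s, reasons))
        else:
            kept.append(s)
    return kept, excluded


def write_qc_report(
    stats: list[QCStats],
    kept: list[QCStats],
    excluded: list[tuple[QCStats, list[str]]],
    path: str | Path,
) -> None:
    """Write a TSV QC report (one row per sample, kept flag and reasons)."""
    reason_by_id = {s.sample_id: r for s, r in excluded}
    kept_ids = {s.sample_id for s in kept}
    with open(path, "w") as fh:
        fh.write(
            "sample_id\treads_total\treads_surviving\tsurvival_fraction\t"
            "mean_quality\tkept\treasons\n"
        )
        for s in stats:
            fh.write(
                f"{s.sample_id}\t{s.reads_total}\t{s.reads_surviving}\t"
                f"{s.survival_fraction:.6g}\t{s.mean_quality:.6g}\t"
                f"{'yes' if s.sample_id in kept_ids else 'no'}\t"
                f"{','.join(reason_by_id.get(s.sample_id, []))}\n"
            )
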