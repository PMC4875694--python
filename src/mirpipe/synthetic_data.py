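"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the toolkit's real inputs:

* :func:`synth_sequences` — random mature miRNAs plus 3'UTRs with planted
  seed sites. UTR backgrounds are scrubbed so that no unplanted occurrence
  of any miRNA's 6mer core survives, making scanner tests exact (recall and
  false positives are 1.0 / 0 by construction, not statistically).
* :func:`synth_expression` — two-group miRNA and mRNA count matrices with
  planted anti-correlated pairs among independent null features. Counts are
  rounded powers of two of a latent Gaussian log2-expression (bivariate for
  planted pairs, with the requested correlation and group mean shifts),
  scaled to per-sample library sizes. A log-normal latent is simpler than a
  negative binomial and adequate for correlation/filter testing.
* :func:`synth_predictions` — per-sample candidate-interval tables built
  from well-separated blocks with controlled overlap chains, plus the true
  region partition.

All randomness flows through ``numpy.random.default_rng(spec.seed)``:
identical specs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .novel_regions import GenomicInterval, Prediction
from .seedmatch import SITE_TYPES, MatureMiRNA, site_motifs

_BASES = "ACGT"
_RNA_BASES = "ACGU"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dataset (all generators share it)."""

    seed: int = 0
    # sequences
    n_mirnas: int = 10
    n_utrs: int = 20
    utr_length: int = 500
    planted_sites: tuple[tuple[int, int, str], ...] = ()
    # expression
    n_samples_per_group: int = 20
    n_planted_pairs: int = 50
    n_null_pairs: int = 450
    target_r: float = -0.8
    planted_log2fc: float = 1.0
    noise_sd: float = 0.5
    base_log2_mean: tuple[float, float] = (5.0, 9.0)
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    # predictions
    n_regions: int = 30
    max_chain: int = 4
    n_samples: int = 4

    def __post_init__(self) -> None:
        if abs(self.target_r) >= 1:
            raise ValidationError(f"|target r| must be < 1, got {self.target_r}")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_mirnas(rng: np.random.Generator, n: int) -> list[MatureMiRNA]:
    """Random 20-24 nt miRNAs whose seed motifs cannot shadow each other.

    A planted motif of one miRNA must not contain another miRNA's 6mer core
    as a substring (otherwise the scanner would report an unplanted site
    inside a planted window); candidates violating this against any
    already-accepted miRNA are redrawn.
    """
    out: list[MatureMiRNA] = []
    eightmers: list[str] = []
    for i in range(n):
        for _attempt in range(1000):
            length = int(rng.integers(20, 25))
            seq = "".join(rng.choice(list(_RNA_BASES), size=length))
            m = MatureMiRNA(mirna_id=f"mir{i:03d}", sequence=seq)
            motifs = site_motifs(m)
            core, eight = motifs["6mer"], motifs["8mer"]
            prev_cores = [site_motifs(x)["6mer"] for x in out]
            n_self = sum(
                1 for k in range(len(eight) - 5) if eight[k : k + 6] == core
            )
            if n_self != 1:
                continue  # periodic seed: core recurs inside its own 8mer
            if any(core in e for e in eightmers) or any(
                c in eight for c in prev_cores
            ) or core in prev_cores:
                continue
            out.append(m)
            eightmers.append(eight)
            break
        else:
            raise ValidationError("could not draw mutually compatible miRNA seeds")
    return out


def _forbidden_cores(mirnas: list[MatureMiRNA]) -> list[str]:
    return [site_motifs(m)["6mer"] for m in mirnas]


def _scrub(
    seq: list[str],
    cores: list[str],
    protected: set[int],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Mutate bases in place until no core occurs outside protected columns."""
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = False
        for core in cores:
            pos = text.find(core)
            while pos != -1:
                cols = set(range(pos, pos + 6))
                if not cols <= protected:
                    editable = sorted(cols - protected)
                    j = int(rng.choice(editable))
                    current = seq[j]
                    seq[j] = str(rng.choice([b for b in _BASES if b != current]))
                    dirty = True
                pos = text.find(core, pos + 1)
        if not dirty:
            return
    raise ValidationError(
        "could not build a motif-free UTR background (motif density too high)"
    )


def synth_sequences(
    spec: SynthSpec,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate miRNAs, UTRs with planted sites, and the truth table.

    ``spec.planted_sites`` holds (mirna index, utr index, site_type)
    triples. Sites within one UTR are placed at disjoint, well-separated
    offsets; for sub-8mer types the stronger flanking context is explicitly
    avoided so the planted class is exact. The truth table has columns
    mirna_id, transcript_id, utr_start, utr_end, site_type.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = _random_mirnas(rng, spec.n_mirnas)
    cores = _forbidden_cores(mirnas)

    per_utr: dict[int, list[tuple[int, str]]] = {}
    for mi, ui, stype in spec.planted_sites:
        if stype not in SITE_TYPES:
            raise ValidationError(f"unknown site type {stype!r}")
        if not (0 <= mi < spec.n_mirnas and 0 <= ui < spec.n_utrs):
            raise ValidationError("planted site indexes out of range")
        per_utr.setdefault(ui, []).append((mi, stype))

    slot = 12  # nt reserved per planted site incl. flanks
    utrs: dict[str, str] = {}
    truth_rows = []
    for ui in range(spec.n_utrs):
        tid = f"tx{ui:03d}"
        plan = per_utr.get(ui, [])
        if (len(plan) + 1) * slot * 2 > spec.utr_length:
            raise ValidationError(
                f"UTR {tid} too short for {len(plan)} planted sites"
            )
        seq = list(rng.choice(list(_BASES), size=spec.utr_length))
        protected: set[int] = set()
        # evenly spaced anchor offsets, jittered away from the ends
        offsets = np.linspace(
            slot, spec.utr_length - 2 * slot, num=max(len(plan), 1), dtype=int
        )
        for (mi, stype), off in zip(plan, offsets):
            m = mirnas[mi]
            motifs = site_motifs(m)
            motif = motifs[stype]
            core_start = int(off) if stype in ("6mer", "7mer-a1") else int(off) + 1
            full_start = int(off)
            for k, ch in enumerate(motif):
                seq[full_start + k] = ch
            m8_char = motifs["7mer-m8"][0]
            # forbid accidental upgrade to a stronger class
            if stype in ("6mer", "7mer-a1"):
                prev = core_start - 1
                if seq[prev] == m8_char:
                    seq[prev] = str(
                        rng.choice([b for b in _BASES if b != m8_char])
                    )
                protected.add(prev)
            if stype in ("6mer", "7mer-m8"):
                nxt = full_start + len(motif)
                if seq[nxt] == "A":
                    seq[nxt] = str(rng.choice(list("CGT")))
                protected.add(nxt)
            protected.update(range(full_start, full_start + len(motif)))
            site_start = full_start
            site_end = full_start + len(motif)
            truth_rows.append(
                {
                    "mirna_id": m.mirna_id,
                    "transcript_id": tid,
                    "utr_start": site_start,
                    "utr_end": site_end,
                    "site_type": stype,
                }
            )
        _scrub(seq, cores, protected, rng)
        utrs[tid] = "".join(seq)

    mirna_map = {m.mirna_id: m.sequence for m in mirnas}
    truth = pd.DataFrame(
        truth_rows,
        columns=["mirna_id", "transcript_id", "utr_start", "utr_end", "site_type"],
    )
    return mirna_map, utrs, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def synth_expression(
    spec: SynthSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Two-group miRNA/mRNA count matrices with planted anti-correlated pairs.

    Sample ids are shared between the matrices (``s000`` ...), split into
    groups ``a`` and ``b`` of ``n_samples_per_group`` each. Planted pair i
    links ``mir{i}`` with ``tx{i}``: their latent log2-expressions are
    bivariate normal with correlation ``target_r``; group b shifts the miRNA
    by ``+planted_log2fc`` and the mRNA by ``-planted_log2fc``. Null pairs
    are independent with no group shift. The truth table records planted
    flags and the intended fold changes.
    """
    if spec.n_samples_per_group < 3:
        raise ValidationError("need >= 3 samples per group")
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_planted_pairs + spec.n_null_pairs
    n = 2 * spec.n_samples_per_group
    samples = [f"s{i:03d}" for i in range(n)]
    group = np.array([0] * spec.n_samples_per_group + [1] * spec.n_samples_per_group)

    lo, hi = spec.base_log2_mean
    mu_mir = rng.uniform(lo, hi, size=n_pairs)
    mu_mrna = rng.uniform(lo, hi, size=n_pairs)

    mir_latent = np.empty((n_pairs, n))
    mrna_latent = np.empty((n_pairs, n))
    truth_rows = []
    cov = np.array(
        [[1.0, spec.target_r], [spec.target_r, 1.0]]
    ) * spec.noise_sd**2
    for i in range(n_pairs):
        planted = i < spec.n_planted_pairs
        if planted:
            z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
            shift = group * spec.planted_log2fc
            mir_latent[i] = mu_mir[i] + shift + z[:, 0]
            mrna_latent[i] = mu_mrna[i] - shift + z[:, 1]
        else:
            mir_latent[i] = mu_mir[i] + rng.normal(0, spec.noise_sd, size=n)
            mrna_latent[i] = mu_mrna[i] + rng.normal(0, spec.noise_sd, size=n)
        truth_rows.append(
            {
                "mirna_id": f"mir{i:03d}",
                "transcript_id": f"tx{i:03d}",
                "planted": planted,
                "target_r": spec.target_r if planted else 0.0,
                "mirna_log2fc": spec.planted_log2fc if planted else 0.0,
                "mrna_log2fc": -spec.planted_log2fc if planted else 0.0,
            }
        )

    lib = rng.integers(*spec.library_size_range, size=n).astype(float)

    def to_counts(latent: np.ndarray) -> np.ndarray:
        return np.round(2.0**latent * lib / 1e6)

    mir_df = pd.DataFrame(
        to_counts(mir_latent),
        index=[f"mir{i:03d}" for i in range(n_pairs)],
        columns=samples,
    )
    mrna_df = pd.DataFrame(
        to_counts(mrna_latent),
        index=[f"tx{i:03d}" for i in range(n_pairs)],
        columns=samples,
    )
    truth = pd.DataFrame(truth_rows)
    return (
        ExpressionMatrix(mir_df, "raw_count"),
        ExpressionMatrix(mrna_df, "raw_count"),
        truth,
    )


def sample_groups(spec: SynthSpec) -> dict[str, str]:
    """The sample -> treatment-label map matching :func:`synth_expression`."""
    n = spec.n_samples_per_group
    return {
        f"s{i:03d}": ("a" if i < n else "b") for i in range(2 * n)
    }


# ---------------------------------------------------------------------------
# interval predictions
# ---------------------------------------------------------------------------

def synth_predictions(
    spec: SynthSpec,
) -> tuple[list[Prediction], pd.DataFrame]:
    """Per-sample candidate intervals with a known true region partition.

    Regions are laid out in well-separated genomic blocks; within a block,
    1..max_chain predictions form an overlap chain (each shifted by less
    than the interval length) and are assigned to random samples. The truth
    table maps each prediction index to its true region id.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"s{i:03d}" for i in range(spec.n_samples)]
    preds: list[Prediction] = []
    truth_rows = []
    pos = 1000
    for region_idx in range(spec.n_regions):
        chrom = f"chr{int(rng.integers(1, 6))}"
        strand = "+" if rng.random() < 0.5 else "-"
        chain = int(rng.integers(1, spec.max_chain + 1))
        length = int(rng.integers(60, 160))
        start = pos
        for _ in range(chain):
            end = start + length
            sid = samples[int(rng.integers(0, spec.n_samples))]
            count = int(rng.integers(1, 500))
            preds.append((sid, GenomicInterval(chrom, start, end, strand), count))
            truth_rows.append(
                {
                    "prediction_index": len(preds) - 1,
                    "true_region": region_idx,
                    "chrom": chrom,
                    "strand": strand,
                }
            )
            start += int(rng.integers(1, length))  # guaranteed >= 1 bp overlap
        pos = end + 10_000  # separate blocks far beyond any chain span
    return preds, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# FASTQ fixtures for QC
# ---------------------------------------------------------------------------

def write_fastq(
    path,
    n_reads: int,
    read_length: int = 30,
    quality_char: str = "I",
    seed: int = 0,
) -> None:
    """Write a small FASTQ file with constant quality (Phred+33)."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for i in range(n_reads):
            seq = "".join(rng.choice(list(_BASES), size=read_length))
            fh.write(f"@read{i}\n{seq}\n+\n{quality_char * read_length}\n")
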