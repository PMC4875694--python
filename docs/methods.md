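# Methods

This note documents the models and procedures implemented in `mirpipe`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Seed-complementarity target prediction (`seedmatch`)

A mature miRNA (RNA alphabet, 5'→3', length ≥ 8 nt) defines two seeds:
positions 2–7 (`seed6`) and 2–8 (`seed7`). A 3'UTR (DNA alphabet,
transcript orientation) is scanned for *anchors*: exact occurrences of the
reverse complement of `seed6` after U→T conversion. Each anchor yields
exactly one site, classified by precedence into the canonical hierarchy:

| class    | UTR motif              | length |
|----------|------------------------|--------|
| 8mer     | rc(seed7) + "A"        | 8      |
| 7mer-m8  | rc(seed7)              | 7      |
| 7mer-a1  | rc(seed6) + "A"        | 7      |
| 6mer     | rc(seed6)              | 6      |

The "A" is the adenosine opposite miRNA position 1; it is matched
literally, not by complementarity to the miRNA, reflecting the biochemistry
of A-anchored sites. Design choices:

* Only perfect Watson–Crick seed pairing. No G:U wobble, no compensatory
  3' pairing, no context scoring — those belong to thermodynamic
  predictors, not to a complementarity scanner.
* `N` in a UTR matches nothing (conservative); `N` anywhere in miRNA
  positions 1–8 makes the seed ambiguous and is an error.
* Overlapping anchors are reported independently; reported offsets span
  the full motif, including the m8 base and/or the A.
* Scanning is case-insensitive; all six site classes at or above a
  configurable stringency floor can be emitted (the floor defaults to
  7mer-a1 when sites serve as integration evidence, so "stringent" classes
  only).

The implementation is anchor-based (single substring search plus O(1)
flank checks). Its correctness oracle in the test suite is a deliberately
naive search of all four motif strings with the precedence rule applied
per anchor; the two routes agree exactly on seeded random instances.

## Normalization and differential testing (`expression`)

* **CPM**: value × 10⁶ / column sum.
* **Size factors** (median-of-ratios): factor s_j = median over features
  with strictly positive counts in all samples of count_ij / geomean_i.
  Only factor *ratios* between samples are identifiable — scaling one
  sample's counts by f moves its factor relative to every other sample's
  by f while the geometric means absorb f^{1/n}. The worked two-sample
  example (column B = 2 × column A) gives (1/√2, √2).
* **Upper quartile**: per sample, the 75th percentile of *nonzero* counts
  with linear interpolation between order statistics (e.g. nonzero counts
  [1,2,3,100] → 27.25). No rescaling to 10⁶ is applied: the scale cancels
  in the t statistic and the unit tag (`upper_quartile_scaled`) records
  the convention.
* **FPKM**: count × 10⁹ / (library × length); log2 form adds a pseudocount
  (default 1) before the log.
* **UQ t-test**: UQ-normalize → log2(x+1) → per-feature two-sided Welch
  (unequal-variance) t-test between two treatment groups → BH across all
  tested features. Welch rather than a pooled test because RNA-seq group
  variances are rarely equal. Features with zero variance in both groups
  get p = 1 when means are equal (no evidence) and p = 0 otherwise (the
  limit of the statistic). With more than two treatment labels every
  unordered pair is tested.
* **Fold changes**: log2((mean_b + ε)/(mean_a + ε)) on a linear scale,
  ε = 0.5 by default. ε guards empty features; it is negligible on the CPM
  scale (values ~10²–10⁵) but material on the UQ scale (values ~0.1–10),
  so fold changes used for gating are computed from CPM.

## Evidence store (`targetdb`)

A single-file SQLite database with one `evidence` row per
(miRNA, target, source) and a `sources` table recording class, row count
and file checksum per resource. Sources are generic TSVs plus a column
mapping, so native dumps of prediction/validation resources can be
ingested after trivial reshaping and the store does not chase upstream
format drift. Within a source, duplicate pairs collapse keeping the
maximum score. miRNA ids are normalized by trimming and lower-casing
"hsa-…"-style names; accessions (e.g. MIMAT…) are preserved, and no
cross-release name resolution is attempted. Queries aggregate per pair:
supporting source list, predicted/validated counts, best score;
aggregation conserves evidence rows exactly.

## Novel-region merging (`novel_regions`)

Two predictions merge iff connected through a chain of same-chromosome,
same-strand overlaps of ≥ 1 bp (a configurable `merge_gap`, default 0, can
link nearby but non-overlapping calls). The implementation is a per
(chrom, strand) sort-and-sweep; because each region's span is gap-free by
construction, the sweep is exactly the connected components of the
pairwise overlap graph, which the tests verify against a graph-library
oracle. Constituent counts sum per sample (reads supporting distinct
overlapping calls at one locus are pooled). Region ids use the 1-based
inclusive display convention `chrom:start-end(strand)`; all internal
arithmetic is 0-based half-open. Annotation attaches names of known
features overlapping by ≥ 1 bp, strand-agnostic by default (genomic
context matters more than orientation for a candidate locus); a
strict-strand flag is provided.

## Anti-correlation integration (`integrate`)

Candidates come from the evidence store, the seed scanner, or both — never
from the full miRNA × mRNA cross product by default. Per candidate, the
Pearson r and its two-sided p (t = r√((n−2)/(1−r²)) on n−2 df) are
computed over the shared samples on log2(normalized + 1) expression
(CPM for miRNA by default; FPKM is appropriate for mRNA when lengths are
available). BH runs across the candidates actually tested, i.e. after the
expressed filter (≥ 2 reads in at least one sample; features below it are
never tested). A pair is reported iff r < r_max, q < q_max, and both
|log2FC| gates pass; each fold-change side can be switched off
independently since designs differ in whether the miRNA, the mRNA, or
both must be differentially expressed. Evidence joining marks pairs with
neither database nor seed-site support; they are dropped unless
explicitly kept.

Defaults (r_max = −0.4, q_max = 0.01, |log2FC| ≥ 0.5, ≥ 2 reads,
min site class 7mer-a1) are deliberately conservative values in common use
for tumor/normal cohort integration.

## Sample QC (`sample_qc`)

Reads are counted as 4-line FASTQ records (Phred+33 only; convert Phred+64
upstream). `mean_quality` is the base-weighted mean over all bases of the
post-trim file — the averaging unit is a design choice, matching per-base
summaries of standard QC tools. Exclusion thresholds (minimum survival
fraction, minimum mean quality) have no hidden defaults — they are
experiment-level choices — and comparisons are strictly "less than": a
sample sitting exactly at a threshold is kept.

## Synthetic data (`synthetic_data`)

The generator produces the same file formats the pipeline reads, with
truth tables sufficient to score every downstream stage.

* **Sequences**: random 20–24 nt miRNAs and fixed-length UTR backgrounds.
  Backgrounds are *scrubbed*: any occurrence of any miRNA's 6mer core
  outside a planted window is mutated away, and miRNA seeds are drawn so
  that no miRNA's core can hide inside another's planted motif. Planted
  sub-8mer sites explicitly break the stronger flanking context. Scanner
  tests on these fixtures are therefore exact (recall 1.0, zero false
  positives), not statistical.
* **Expression**: two groups of n samples; per planted pair a bivariate
  normal latent log2-expression with the requested correlation (default
  −0.8) and anti-aligned group shifts (default ±1 log2 unit); null
  features independent with no shift. Counts are rounded 2^latent scaled
  to per-sample library sizes (0.8–1.2 M). Within-group noise sd defaults
  to 0.5 log2 units — moderate biological variation for a designed
  cohort; with much larger noise a fold-change benchmark measures
  estimation error of the fold change itself rather than the integration
  logic. A log-normal latent was chosen over a negative binomial for
  simplicity; it is adequate for correlation and filter testing but does
  not reproduce RNA-seq mean–dispersion coupling.
* **Predictions**: interval blocks separated by 10 kb, each containing an
  overlap chain of 1–4 same-length intervals assigned to random samples;
  the truth table records the intended region partition.

All randomness flows through one integer-seeded generator; identical specs
give byte-identical outputs, with no hash-order dependence.

What passing on synthetic data does *not* show: behavior under real
library-composition effects, batch structure, overdispersion, multi-site
UTRs with competing miRNAs, or miRBase/Ensembl release mismatches. The
generator is a correctness harness, not a realism benchmark.

## Reporting (`report`) and CLI

Reports are deterministic (no timestamps); the HTML report is one
self-contained file with inline CSS and pre-sorted per-miRNA / per-target
tables, rendered with stdlib string templating. Sort keys: r ascending,
evidence (source count + validated count) descending, |mRNA log2FC|
descending, with (miRNA, target) tie-breaks. The `mirpipe` CLI wraps each
stage behind a flat sectioned `key = value` settings file; unknown keys
fail with a close-match suggestion, run logs record the resolved parameter
set and input checksums, and partially written outputs are removed on
failure.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
100×100 sequence instances for the scanner oracle, 100 planted sites,
500-candidate integration over 40 samples × 20 replicate simulations,
2,000-feature DE null, 200 region-merge instances, 1,000 BH vectors. These
sizes give stable empirical rates while keeping a full run in the order of
seconds to a minute.

## Known limitations

* Seed matching ignores UTR accessibility, conservation and context — by
  design; it is complementarity evidence, not a ranking score.
* The UQ t-test operates on log2(x+1) of UQ-scaled values; with very
  shallow libraries the +1 pseudocount compresses low counts.
* The evidence store does not resolve miRNA identifiers across miRBase
  releases; harmonize upstream.
* FASTQ QC assumes Phred+33 and uncompressed files.
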