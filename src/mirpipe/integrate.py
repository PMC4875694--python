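"""Anti-correlation integration of miRNA and mRNA expression.

A miRNA represses its target, so across samples a functional (miRNA, mRNA)
pair should show negatively correlated expression. For each candidate pair
the Pearson correlation r and its two-sided p-value are computed over the
samples shared by the two matrices, on log2(normalized + 1) expression;
p-values are Benjamini-Hochberg adjusted across all tested candidates, and
a pair is retained iff

    r < r_max  AND  q < q_max  AND  |log2FC| >= min_abs_log2fc

(the fold-change gate applies to the miRNA and the mRNA side independently;
either side can be switched off). Features never reaching
``min_expressed_count`` reads in any sample are dropped before testing.
Retained pairs are then joined with evidence: supporting sources from the
target store and the strongest seed-match site class; pairs with neither
kind of support are dropped by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .seedmatch import SITE_RANK, SeedSite, best_site_types
from .targetdb import AggregatedPair, normalize_mirna_id


@dataclass(frozen=True)
class IntegrationThresholds:
    """Filter settings for anti-correlation integration.

    Defaults follow common practice for tumor/normal cohorts: correlation
    ceiling -0.4 at FDR 0.01, minimum absolute log2 fold change 0.5, and an
    expression floor of 2 reads.
    """

    r_max: float = -0.4
    q_max: float = 0.01
    min_abs_log2fc: float = 0.5
    min_expressed_count: int = 2
    min_site_type: str = "7mer-a1"

    def __post_init__(self) -> None:
        if not (-1 <= self.r_max < 0):
            raise ValidationError(f"r_max must be in [-1, 0), got {self.r_max}")
        if not (0 < self.q_max <= 1):
            raise ValidationError(f"q_max must be in (0, 1], got {self.q_max}")
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if self.min_site_type not in SITE_RANK:
            raise ValidationError(f"unknown site type {self.min_site_type!r}")


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r with its two-sided p-value.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom;
    |r| = 1 gives p = 0. Constant vectors and n < 3 are errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson_test: length mismatch")
    if x.size < 3:
        raise ValidationError(f"pearson_test: need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:
        return float(np.clip(r, -1.0, 1.0)), 0.0
    return float(r), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _log_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    if matrix.unit in ("log2_fpkm", "log2"):
        return matrix.values
    return np.log2(matrix.values + 1.0)


def integrate_pairs(
    mir_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    candidates: list[tuple[str, str]],
    de_mirna: pd.DataFrame | None,
    de_mrna: pd.DataFrame | None,
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    mir_counts: ExpressionMatrix | None = None,
    mrna_counts: ExpressionMatrix | None = None,
    gate_mirna_fc: bool = True,
    gate_mrna_fc: bool = True,
    transcript_to_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Correlate candidate (miRNA, transcript) pairs and apply all gates.

    ``mir_expr``/``mrna_expr`` are normalized matrices (correlation is
    computed on log2(x+1) unless they are already log-scaled). Fold changes
    per feature come from the ``de_mirna``/``de_mrna`` tables (``feature_id``
    and ``log2_fc`` columns, e.g. from :func:`mirpipe.expression.de_ttest_uq`);
    passing ``None`` disables that side's gate. The expressed filter uses
    ``mir_counts``/``mrna_counts`` raw matrices when given, else the
    expression matrices themselves.

    Returns a DataFrame (one row per retained pair) sorted by r ascending
    with columns mirna_id, target_transcript_id, r, p_value, q_value,
    mirna_log2fc, mrna_log2fc.
    """
    if not candidates:
        raise ValidationError("empty candidate list")
    shared = [s for s in mir_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValidationError(
            f"matrices share only {len(shared)} sample ids; need >= 3"
        )

    def expressed(matrix, counts):
        src = counts if counts is not None else matrix
        keep = (src.values >= thresholds.min_expressed_count).any(axis=1)
        return set(src.values.index[keep])

    mir_ok = expressed(mir_expr, mir_counts)
    mrna_ok = expressed(mrna_expr, mrna_counts)

    mir_log = _log_expression(mir_expr)[shared]
    mrna_log = _log_expression(mrna_expr)[shared]

    def fc_map(table: pd.DataFrame | None) -> dict[str, float]:
        if table is None:
            return {}
        return dict(zip(table["feature_id"], table["log2_fc"]))

    mir_fc = fc_map(de_mirna)
    mrna_fc = fc_map(de_mrna)

    rows = []
    tested = []
    for mirna_id, transcript_id in candidates:
        if mirna_id not in mir_log.index:
            raise ValidationError(f"candidate miRNA {mirna_id} not in matrix")
        if transcript_id not in mrna_log.index:
            raise ValidationError(
                f"candidate transcript {transcript_id} not in matrix"
            )
        if mirna_id not in mir_ok or transcript_id not in mrna_ok:
            continue
        x = mir_log.loc[mirna_id].to_numpy()
        y = mrna_log.loc[transcript_id].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # constant after logging: untestable, treated as unexpressed
        r, p = pearson_test(x, y)
        tested.append((mirna_id, transcript_id, r, p))
    if not tested:
        return _empty_pairs_frame()
    q = bh_adjust([t[3] for t in tested])
    for (mirna_id, transcript_id, r, p), qv in zip(tested, q):
        m_fc = mir_fc.get(mirna_id, np.nan)
        t_fc = mrna_fc.get(transcript_id, np.nan)
        if r >= thresholds.r_max or qv >= thresholds.q_max:
            continue
        if gate_mirna_fc and de_mirna is not None:
            if np.isnan(m_fc) or abs(m_fc) < thresholds.min_abs_log2fc:
                continue
        if gate_mrna_fc and de_mrna is not None:
            if np.isnan(t_fc) or abs(t_fc) < thresholds.min_abs_log2fc:
                continue
        rows.append(
            {
                "mirna_id": mirna_id,
                "target_transcript_id": transcript_id,
                "target_gene_id": (transcript_to_gene or {}).get(
                    transcript_id, transcript_id
                ),
                "r": r,
                "p_value": p,
                "q_value": qv,
                "mirna_log2fc": m_fc,
                "mrna_log2fc": t_fc,
            }
        )
    if not rows:
        return _empty_pairs_frame()
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["r", "mirna_id", "target_transcript_id"], kind="mergesort"
    ).reset_index(drop=True)


def _empty_pairs_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "mirna_id",
            "target_transcript_id",
            "target_gene_id",
            "r",
            "p_value",
            "q_value",
            "mirna_log2fc",
            "mrna_log2fc",
        ]
    )


def attach_evidence(
    pairs: pd.DataFrame,
    db_pairs: list[AggregatedPair],
    sites: list[SeedSite],
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    keep_unsupported: bool = False,
) -> pd.DataFrame:
    """Join database and seed-complementarity evidence onto retained pairs.

    Adds columns evidence_sources (comma string), n_validated,
    best_site_type and supported. Seed sites weaker than
    ``thresholds.min_site_type`` do not count as evidence. Unsupported pairs
    are dropped unless ``keep_unsupported``.
    """
    db_index = {
        (normalize_mirna_id(p.mirna_id), p.target_id): p for p in db_pairs
    }
    min_rank = SITE_RANK[thresholds.min_site_type]
    site_best = {
        k: t for k, t in best_site_types(sites).items() if SITE_RANK[t] >= min_rank
    }
    out = pairs.copy()
    sources_col, nval_col, site_col, supported_col = [], [], [], []
    for _, row in out.iterrows():
        key = (normalize_mirna_id(row["mirna_id"]), row["target_transcript_id"])
        rec = db_index.get(key)
        best_site = site_best.get((row["mirna_id"], row["target_transcript_id"]))
        sources_col.append(",".join(rec.sources) if rec else "")
        nval_col.append(rec.n_validated_sources if rec else 0)
        site_col.append(best_site or "")
        supported_col.append(rec is not None or best_site is not None)
    out["evidence_sources"] = sources_col
    out["n_validated"] = nval_col
    out["best_site_type"] = site_col
    out["supported"] = supported_col
    if not keep_unsupported:
        out = out[out["supported"]].reset_index(drop=True)
    return out
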