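"""Count normalization, FPKM, fold changes, and the UQ-normalized t-test.

Three normalizations are provided for raw count matrices:

* ``cpm`` — counts per million: value * 1e6 / library size.
* ``size_factor`` — median-of-ratios scaling: per sample j the factor
  s_j = median_i(count_ij / geomean_i) over features whose geometric mean
  across samples is strictly positive; values are divided by s_j.
* ``upper_quartile`` — per sample, the 75th percentile (linear
  interpolation) of that sample's nonzero counts; values are divided by it.
  No further 1e6 rescaling is applied — the relative scale is what the
  downstream t-test consumes, and the output unit records the convention.

Differential testing follows the "upper-quartile normalized t-test" recipe:
UQ-normalize, log2(x+1), per-feature two-sided Welch t-test between the two
groups, Benjamini-Hochberg adjustment across all tested features. Fold
changes are computed on the normalized linear scale with a small epsilon
guarding empty features.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .integrate import bh_adjust

#: epsilon added to both group means in fold-change ratios
DEFAULT_FC_EPSILON = 0.5


def _library_sizes(matrix: ExpressionMatrix) -> np.ndarray:
    sizes = matrix.values.sum(axis=0).to_numpy(dtype=float)
    if (sizes <= 0).any():
        bad = [s for s, v in zip(matrix.sample_ids, sizes) if v <= 0]
        raise ValidationError(f"zero library size for sample(s): {bad}")
    return sizes


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (one per sample).

    Only features with a strictly positive geometric mean across samples
    (i.e. all-positive counts) enter the median.
    """
    counts = matrix.values.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "size factors undefined: no feature has positive counts in all samples"
        )
    sub = counts[all_positive]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=matrix.sample_ids)


def upper_quartile_scales(matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample 75th percentile of nonzero counts (linear interpolation)."""
    scales = {}
    for sid in matrix.sample_ids:
        col = matrix.values[sid].to_numpy(dtype=float)
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValidationError(f"sample {sid} has no nonzero counts")
        scales[sid] = float(np.percentile(nonzero, 75))
    return pd.Series(scales)


def normalize(matrix: ExpressionMatrix, method: str) -> ExpressionMatrix:
    """Normalize a raw count matrix by cpm, size_factor, or upper_quartile."""
    if matrix.unit != "raw_count":
        raise ValidationError(
            f"normalize expects raw_count input, got unit {matrix.unit!r}"
        )
    if method == "cpm":
        sizes = _library_sizes(matrix)
        out = matrix.values * (1e6 / sizes)
        return ExpressionMatrix(out, "cpm")
    if method == "size_factor":
        f = size_factors(matrix)
        return ExpressionMatrix(matrix.values / f, "size_factor_scaled")
    if method == "upper_quartile":
        u = upper_quartile_scales(matrix)
        return ExpressionMatrix(matrix.values / u, "upper_quartile_scaled")
    raise ValidationError(f"unknown normalization method {method!r}")


def to_fpkm(
    matrix: ExpressionMatrix,
    lengths: dict[str, int],
    log2: bool = False,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Fragments per kilobase per million: count * 1e9 / (library * length)."""
    if matrix.unit != "raw_count":
        raise ValidationError(
            f"to_fpkm expects raw_count input, got unit {matrix.unit!r}"
        )
    missing = [f for f in matrix.feature_ids if f not in lengths]
    if missing:
        raise ValidationError(f"missing length for feature(s): {missing[:5]}")
    lens = np.array([lengths[f] for f in matrix.feature_ids], dtype=float)
    if (lens <= 0).any():
        bad = [f for f, l in zip(matrix.feature_ids, lens) if l <= 0]
        raise ValidationError(f"non-positive length for feature(s): {bad[:5]}")
    sizes = _library_sizes(matrix)
    fpkm = matrix.values * 1e9 / sizes
    fpkm = fpkm.div(lens, axis=0)
    if log2:
        return ExpressionMatrix(np.log2(fpkm + pseudocount), "log2_fpkm")
    return ExpressionMatrix(fpkm, "fpkm")


def _group_columns(
    matrix: ExpressionMatrix, groups: dict[str, str], label: str
) -> list[str]:
    cols = [s for s in matrix.sample_ids if groups.get(s) == label]
    if not cols:
        raise ValidationError(f"group {label!r} has zero samples in the matrix")
    return cols


def log2_fold_change(
    matrix: ExpressionMatrix,
    groups: dict[str, str],
    pair: tuple[str, str],
    epsilon: float = DEFAULT_FC_EPSILON,
) -> pd.Series:
    """Per-feature log2((mean_b + eps) / (mean_a + eps)) for pair = (a, b).

    The matrix must be on a linear (not log) unit.
    """
    if matrix.unit in ("log2_fpkm", "log2"):
        raise ValidationError("fold changes require a linear-scale matrix")
    a, b = pair
    cols_a = _group_columns(matrix, groups, a)
    cols_b = _group_columns(matrix, groups, b)
    mean_a = matrix.values[cols_a].mean(axis=1)
    mean_b = matrix.values[cols_b].mean(axis=1)
    return np.log2((mean_b + epsilon) / (mean_a + epsilon))


def pairwise_comparisons(groups: dict[str, str]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct treatment labels, lexicographic."""
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValidationError("differential analysis requires two groups")
    return list(combinations(labels, 2))


def de_ttest_uq(
    matrix: ExpressionMatrix,
    groups: dict[str, str],
    pair: tuple[str, str],
    fc_epsilon: float = DEFAULT_FC_EPSILON,
) -> pd.DataFrame:
    """Upper-quartile-normalized Welch t-test between two treatment groups.

    Pipeline: UQ-normalize -> log2(x+1) -> per-feature two-sided Welch
    t-test -> BH adjustment across all tested features. Returns a DataFrame
    with columns feature_id, group_a, group_b, log2_fc, p_value, q_value,
    method. Features with zero variance in both groups get p=1 when the
    group means are equal and p=0 otherwise.
    """
    a, b = pair
    norm = normalize(matrix, "upper_quartile")
    cols_a = _group_columns(norm, groups, a)
    cols_b = _group_columns(norm, groups, b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(cols_a)} ({a}) / {len(cols_b)} ({b})"
        )
    log_vals = np.log2(norm.values + 1.0)
    xa = log_vals[cols_a].to_numpy(dtype=float)
    xb = log_vals[cols_b].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features trip scipy's precision warning; they are
        # resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    # degenerate features: no variance anywhere -> p decided by mean equality
    var0 = (xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)
    means_equal = xa.mean(axis=1) == xb.mean(axis=1)
    p = np.where(var0 & means_equal, 1.0, p)
    p = np.where(var0 & ~means_equal, 0.0, p)
    q = bh_adjust(p)
    lfc = log2_fold_change(norm, groups, pair, epsilon=fc_epsilon)
    return pd.DataFrame(
        {
            "feature_id": norm.feature_ids,
            "group_a": a,
            "group_b": b,
            "log2_fc": lfc.to_numpy(),
            "p_value": p,
            "q_value": q,
            "method": "uq_ttest",
        }
    )


def de_all_pairs(
    matrix: ExpressionMatrix, groups: dict[str, str]
) -> pd.DataFrame:
    """Run :func:`de_ttest_uq` for every pairwise combination of groups."""
    frames = [de_ttest_uq(matrix, groups, pair) for pair in pairwise_comparisons(groups)]
    return pd.concat(frames, ignore_index=True)
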