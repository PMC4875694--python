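import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpipe.errors import ValidationError
from mirpipe.expression import (
    de_ttest_uq,
    log2_fold_change,
    normalize,
    pairwise_comparisons,
    size_factors,
    to_fpkm,
    upper_quartile_scales,
)
from mirpipe.io_formats import ExpressionMatrix


def _matrix(data, unit="raw_count"):
    df = pd.DataFrame(data, dtype=float)
    df.index = [f"f{i}" for i in range(len(df))]
    return ExpressionMatrix(df, unit)


class TestNormalize:
    def test_cpm_definition(self):
        m = _matrix({"s1": [100, 900]})
        out = normalize(m, "cpm")
        assert out.unit == "cpm"
        np.testing.assert_allclose(out.values["s1"], [1e5, 9e5])

    def test_cpm_columns_sum_to_million(self, two_group_counts):
        m, _ = two_group_counts
        out = normalize(m, "cpm")
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_size_factor_doubled_column(self):
        # column B = 2 x column A -> factors (1/sqrt(2), sqrt(2))
        m = _matrix({"A": [10, 20, 30], "B": [20, 40, 60]})
        f = size_factors(m)
        np.testing.assert_allclose(f.values, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-9)

    def test_size_factor_identical_columns_all_one(self):
        m = _matrix({"A": [5, 9, 2], "B": [5, 9, 2], "C": [5, 9, 2]})
        np.testing.assert_allclose(size_factors(m).values, 1.0)

    def test_size_factor_ratio_scales_with_column_multiplier(self, two_group_counts):
        # multiplying one sample's counts by f multiplies its size factor
        # relative to every other sample by f (geomeans absorb f^(1/n), so
        # only factor ratios are identifiable -- cf. the (1/sqrt2, sqrt2)
        # worked example for a doubled column)
        m, _ = two_group_counts
        base = size_factors(m)
        scaled_df = m.values.copy()
        scaled_df.iloc[:, 0] = scaled_df.iloc[:, 0] * 3
        scaled = size_factors(ExpressionMatrix(scaled_df, "raw_count"))
        for k in range(1, len(base)):
            np.testing.assert_allclose(
                (scaled.iloc[0] / scaled.iloc[k]) / (base.iloc[0] / base.iloc[k]),
                3.0,
                rtol=1e-9,
            )

    def test_size_factor_undefined_without_all_positive_feature(self):
        m = _matrix({"A": [0, 5], "B": [5, 0]})
        with pytest.raises(ValidationError, match="size factors undefined"):
            normalize(m, "size_factor")

    def test_upper_quartile_worked_example(self):
        m = _matrix({"s": [0, 1, 2, 3, 100]})
        u = upper_quartile_scales(m)
        assert u["s"] == pytest.approx(27.25, abs=1e-9)
        out = normalize(m, "upper_quartile")
        np.testing.assert_allclose(
            out.values["s"], np.array([0, 1, 2, 3, 100]) / 27.25
        )

    def test_upper_quartile_ignores_all_zero_features(self):
        m1 = _matrix({"s1": [1, 2, 3, 100], "s2": [4, 5, 6, 7]})
        padded = _matrix({"s1": [1, 2, 3, 100, 0, 0], "s2": [4, 5, 6, 7, 0, 0]})
        np.testing.assert_allclose(
            upper_quartile_scales(m1).values, upper_quartile_scales(padded).values
        )

    def test_normalize_requires_raw_counts(self):
        m = _matrix({"s1": [1.0, 2.0]}, unit="cpm")
        with pytest.raises(ValidationError):
            normalize(m, "cpm")


class TestFpkm:
    def test_formula(self):
        m = _matrix({"s1": [10, 1e6 - 10]})
        out = to_fpkm(m, {"f0": 1000, "f1": 10})
        assert out.values.loc["f0", "s1"] == pytest.approx(10.0)

    def test_log2_zero_count_gives_zero(self):
        m = _matrix({"s1": [0, 100]})
        out = to_fpkm(m, {"f0": 500, "f1": 500}, log2=True)
        assert out.unit == "log2_fpkm"
        assert out.values.loc["f0", "s1"] == pytest.approx(0.0)

    def test_scale_invariance(self):
        m1 = _matrix({"s1": [10, 90]})
        m2 = _matrix({"s1": [20, 180]})
        lengths = {"f0": 100, "f1": 300}
        np.testing.assert_allclose(
            to_fpkm(m1, lengths).values, to_fpkm(m2, lengths).values
        )

    def test_missing_length_named(self):
        m = _matrix({"s1": [1, 2]})
        with pytest.raises(ValidationError, match="f1"):
            to_fpkm(m, {"f0": 100})


class TestFoldChange:
    def test_log2_ratio(self):
        m = _matrix({"a1": [4, 7], "a2": [4, 7], "b1": [8, 7], "b2": [8, 7]})
        groups = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        lfc = log2_fold_change(m, groups, ("a", "b"), epsilon=0)
        assert lfc["f0"] == pytest.approx(1.0)
        assert lfc["f1"] == pytest.approx(0.0)

    def test_zero_means_protected_by_epsilon(self):
        m = _matrix({"a1": [0], "b1": [0]})
        lfc = log2_fold_change(m, {"a1": "a", "b1": "b"}, ("a", "b"), epsilon=0.5)
        assert lfc["f0"] == pytest.approx(0.0)

    def test_missing_group_is_error(self):
        m = _matrix({"a1": [1]})
        with pytest.raises(ValidationError):
            log2_fold_change(m, {"a1": "a"}, ("a", "b"))


class TestPairwiseComparisons:
    def test_two_groups(self):
        assert pairwise_comparisons({"s1": "tumor", "s2": "normal"}) == [
            ("normal", "tumor")
        ]

    def test_three_groups(self):
        groups = {"s1": "a", "s2": "b", "s3": "c"}
        assert pairwise_comparisons(groups) == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_single_group_is_error(self):
        with pytest.raises(ValidationError, match="requires two groups"):
            pairwise_comparisons({"s1": "a", "s2": "a"})


class TestDeTtestUq:
    def test_identical_groups_null_feature(self, two_group_counts):
        m, groups = two_group_counts
        df = m.values.copy()
        df.iloc[0] = [3, 3, 3, 3, 3, 3, 3, 3, 3, 3]  # constant feature
        res = de_ttest_uq(ExpressionMatrix(df, "raw_count"), groups, ("a", "b"))
        row = res[res.feature_id == "f00"].iloc[0]
        # constant counts but per-sample UQ scaling differs; the feature is
        # not strictly degenerate, so only check fold change is tiny
        assert abs(row.log2_fc) < 0.2

    def test_zero_variance_equal_means_p_one(self):
        # identical columns -> UQ-normalized values identical across samples
        df = pd.DataFrame(
            {f"s{i}": [5.0, 10.0, 20.0, 40.0] for i in range(6)},
            index=["f0", "f1", "f2", "f3"],
        )
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = de_ttest_uq(ExpressionMatrix(df, "raw_count"), groups, ("a", "b"))
        assert (res.p_value == 1.0).all()
        np.testing.assert_allclose(res.log2_fc, 0.0)

    def test_planted_large_shift_detected(self):
        detected = 0
        lfc_ok = 0
        samples = [f"s{i}" for i in range(20)]
        groups = {s: ("a" if i < 10 else "b") for i, s in enumerate(samples)}
        for seed in range(1, 101):
            rng = np.random.default_rng(seed)
            latent = rng.normal(5, 1.0, size=(80, 20))
            latent[0, :10] = rng.normal(5, 0.1, size=10)
            latent[0, 10:] = rng.normal(9, 0.1, size=10)
            m = ExpressionMatrix(
                pd.DataFrame(np.round(2.0**latent),
                             index=[f"f{i}" for i in range(80)], columns=samples),
                "raw_count",
            )
            res = de_ttest_uq(m, groups, ("a", "b"))
            row = res.iloc[0]
            detected += row.q_value < 0.01
            lfc_ok += row.log2_fc > 3
        assert detected >= 95
        assert lfc_ok >= 95

    def test_bh_q_monotone_in_p(self, two_group_counts):
        m, groups = two_group_counts
        res = de_ttest_uq(m, groups, ("a", "b")).sort_values("p_value")
        assert (np.diff(res.q_value) >= -1e-12).all()
        assert (res.q_value <= 1).all()

    def test_requires_two_samples_per_group(self, two_group_counts):
        m, _ = two_group_counts
        groups = {s: ("a" if i == 0 else "b") for i, s in enumerate(m.sample_ids)}
        with pytest.raises(ValidationError, match=">=2 samples"):
            de_ttest_uq(m, groups, ("a", "b"))


class TestNullUniformity:
    def test_welch_p_uniform_under_null(self):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(20)]
        groups = {s: ("a" if i < 10 else "b") for i, s in enumerate(samples)}
        latent = rng.normal(8, 1, size=(2000, 20))
        m = ExpressionMatrix(
            pd.DataFrame(np.round(2.0**latent),
                         index=[f"f{i}" for i in range(2000)], columns=samples),
            "raw_count",
        )
        res = de_ttest_uq(m, groups, ("a", "b"))
        assert stats.kstest(res.p_value, "uniform").pvalue > 0.01
        assert abs((res.p_value < 0.05).mean() - 0.05) < 0.02
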