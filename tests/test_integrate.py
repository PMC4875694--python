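import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirpipe.errors import ValidationError
from mirpipe.expression import log2_fold_change, normalize
from mirpipe.integrate import (
    IntegrationThresholds,
    attach_evidence,
    bh_adjust,
    integrate_pairs,
    pearson_test,
)
from mirpipe.io_formats import ExpressionMatrix
from mirpipe.seedmatch import SeedSite
from mirpipe.synthetic_data import SynthSpec, sample_groups, synth_expression
from mirpipe.targetdb import AggregatedPair


def bh_oracle(p):
    """Independent BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2, 3, 5])
        r, p = pearson_test(x, -x)
        assert r == pytest.approx(-1.0)
        assert p == 0.0

    def test_hand_computed_r(self):
        r, _ = pearson_test([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_matches_t_transform(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = pearson_test(x, y)
        t = r * np.sqrt((30 - 2) / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-10)

    def test_permutation_null_uniform(self):
        rng = np.random.default_rng(17)
        pvals = []
        x = rng.normal(size=20)
        for _ in range(2000):
            y = rng.permutation(x)
            if np.ptp(y) == 0:
                continue
            pvals.append(pearson_test(x, y)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant vector"):
            pearson_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            pearson_test([1, 2], [3, 4])


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.04], [0.01, 0.04]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_step_up_oracle_random(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            p = rng.uniform(size=n)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_monotone_raising_one_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=15)
        q0 = bh_adjust(p)
        p2 = p.copy()
        p2[7] = min(1.0, p2[7] + 0.3)
        q2 = bh_adjust(p2)
        assert (q2 >= q0 - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_property_matches_oracle_and_bounds(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert ((q >= 0) & (q <= 1)).all()
        # q is monotone in the p ranks
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


def _expr(df, unit="cpm"):
    return ExpressionMatrix(pd.DataFrame(df, dtype=float), unit)


class TestIntegratePairs:
    def test_perfect_anticorrelated_pair_retained(self):
        # monotone decreasing miRNA vs increasing mRNA; values chosen so
        # log2(x+1) is exactly linear -> r = -1
        mir = _expr({"s1": [15], "s2": [7], "s3": [3], "s4": [1]})
        mir.values.index = ["m1"]
        mrna = _expr({"s1": [1], "s2": [3], "s3": [7], "s4": [15]})
        mrna.values.index = ["t1"]
        de_m = pd.DataFrame({"feature_id": ["m1"], "log2_fc": [1.0]})
        de_t = pd.DataFrame({"feature_id": ["t1"], "log2_fc": [-1.0]})
        res = integrate_pairs(
            mir, mrna, [("m1", "t1")], de_m, de_t,
            IntegrationThresholds(q_max=0.05),
        )
        assert len(res) == 1
        assert res.r.iloc[0] == pytest.approx(-1.0)

    def test_weak_correlation_dropped_regardless_of_q(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(8, 1, size=n)
        noise = rng.normal(0, 1, size=n)
        # engineer r ~ -0.3: weak anti-correlation
        y = -0.32 * (x - x.mean()) + noise
        y = y - y.min() + 1
        samples = [f"s{i}" for i in range(n)]
        mir = ExpressionMatrix(pd.DataFrame([2.0**x], index=["m1"], columns=samples), "cpm")
        mrna = ExpressionMatrix(pd.DataFrame([2.0**y], index=["t1"], columns=samples), "cpm")
        r, _ = pearson_test(np.log2(2.0**x + 1), np.log2(2.0**y + 1))
        assume_weak = -0.4 < r < 0
        res = integrate_pairs(mir, mrna, [("m1", "t1")], None, None)
        if assume_weak:
            assert len(res) == 0

    def test_thresholds_enforced_exactly(self):
        spec = SynthSpec(seed=6, n_planted_pairs=20, n_null_pairs=80,
                         n_samples_per_group=15)
        mir, mrna, truth = synth_expression(spec)
        groups = sample_groups(spec)
        cm, cr = normalize(mir, "cpm"), normalize(mrna, "cpm")
        de_m = pd.DataFrame({"feature_id": cm.feature_ids,
                             "log2_fc": log2_fold_change(cm, groups, ("a", "b")).values})
        de_t = pd.DataFrame({"feature_id": cr.feature_ids,
                             "log2_fc": log2_fold_change(cr, groups, ("a", "b")).values})
        th = IntegrationThresholds()
        res = integrate_pairs(cm, cr, list(zip(truth.mirna_id, truth.transcript_id)),
                              de_m, de_t, th, mir_counts=mir, mrna_counts=mrna)
        assert (res.r < th.r_max).all()
        assert (res.q_value < th.q_max).all()
        assert (res.mirna_log2fc.abs() >= th.min_abs_log2fc).all()
        assert (res.mrna_log2fc.abs() >= th.min_abs_log2fc).all()
        assert res.r.is_monotonic_increasing

    def test_too_few_shared_samples_rejected(self):
        mir = _expr({"s1": [1], "s2": [2]})
        mir.values.index = ["m1"]
        mrna = _expr({"s1": [1], "s2": [2]})
        mrna.values.index = ["t1"]
        with pytest.raises(ValidationError, match="sample ids"):
            integrate_pairs(mir, mrna, [("m1", "t1")], None, None)

    def test_empty_candidates_rejected(self, count_matrix):
        with pytest.raises(ValidationError, match="empty candidate"):
            integrate_pairs(count_matrix, count_matrix, [], None, None)

    def test_unexpressed_features_dropped_before_testing(self):
        counts = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 50.0], "s2": [0.0, 60.0],
                          "s3": [1.0, 70.0], "s4": [0.0, 80.0]},
                         index=["m1", "m2"]),
            "raw_count",
        )
        mrna = _expr({"s1": [1], "s2": [2], "s3": [3], "s4": [4]})
        mrna.values.index = ["t1"]
        res = integrate_pairs(
            normalize(counts, "cpm"), mrna, [("m1", "t1")], None, None,
            mir_counts=counts,
        )  # m1 never reaches 2 reads -> dropped, nothing tested
        assert len(res) == 0


class TestAttachEvidence:
    def _pairs(self):
        return pd.DataFrame(
            {
                "mirna_id": ["m1", "m2", "m3"],
                "target_transcript_id": ["t1", "t2", "t3"],
                "target_gene_id": ["g1", "g2", "g3"],
                "r": [-0.9, -0.8, -0.7],
                "p_value": [1e-8] * 3,
                "q_value": [1e-7] * 3,
                "mirna_log2fc": [1.0] * 3,
                "mrna_log2fc": [-1.0] * 3,
            }
        )

    def test_join_db_and_sites(self):
        db = [AggregatedPair("m1", "t1", ("srcA", "srcB"), 1, 1, 0.9)]
        sites = [SeedSite("m1", "t1", 10, 18, "8mer", "AAAAAAAA"),
                 SeedSite("m2", "t2", 5, 12, "7mer-m8", "AAAAAAA")]
        out = attach_evidence(self._pairs(), db, sites)
        assert len(out) == 2  # m3 has no evidence -> dropped by default
        row1 = out[out.mirna_id == "m1"].iloc[0]
        assert row1.evidence_sources == "srcA,srcB"
        assert row1.best_site_type == "8mer"
        row2 = out[out.mirna_id == "m2"].iloc[0]
        assert row2.evidence_sources == "" and row2.best_site_type == "7mer-m8"

    def test_weak_sites_do_not_count(self):
        sites = [SeedSite("m3", "t3", 0, 6, "6mer", "AAAAAA")]
        out = attach_evidence(self._pairs(), [], sites)  # min type 7mer-a1
        assert len(out) == 0

    def test_keep_unsupported_flag(self):
        out = attach_evidence(self._pairs(), [], [], keep_unsupported=True)
        assert len(out) == 3
        assert (~out.supported).all()
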