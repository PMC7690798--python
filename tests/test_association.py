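import math

import numpy as np
import pandas as pd
import pytest

from crossdep import (
    call_hits,
    cross_association_scan,
    descriptivity,
    gene_summary,
    median_split,
    platform_correlation,
    predictivity,
    records_to_frame,
    top_efficacy_genes,
    two_group_test,
)
from crossdep.association import AssociationRecord
from conftest import make_matrix, random_panel
from oracles import naive_gene_scores, naive_pearson, naive_pooled_t

EXPR6 = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
EFF6 = [-1.0, -1.0, -1.0, -3.0, -3.0, -3.0]


class TestMedianSplit:
    def test_even_count_midpoint(self):
        s = median_split([1, 2, 3, 4])
        assert s.median == 2.5
        assert sorted(s.high_idx) == [2, 3] and sorted(s.low_idx) == [0, 1]

    def test_ties_at_median_go_low(self):
        s = median_split([1, 2, 2, 3, 9])
        assert s.median == 2
        assert sorted(s.high_idx) == [3, 4] and sorted(s.low_idx) == [0, 1, 2]

    def test_constant_vector_degenerate(self):
        s = median_split([5, 5, 5, 5])
        assert s.status == "degenerate" and s.high_idx.size == 0

    def test_fewer_than_two_observed_insufficient(self):
        assert median_split([3.0, np.nan, np.nan]).status == "insufficient"

    def test_missing_excluded_and_counted(self):
        s = median_split([1.0, np.nan, 3.0, 4.0])
        assert s.n_excluded_missing == 1
        assert set(s.high_idx) | set(s.low_idx) == {0, 2, 3}


class TestTwoGroupTest:
    def test_matches_pooled_variance_closed_form(self):
        t, p = two_group_test([1, 2, 3], [4, 5, 6], variant="student")
        t_ref, p_ref = naive_pooled_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-4)

    def test_identical_groups(self):
        assert two_group_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_swapping_groups_negates_t_only(self):
        t1, p1 = two_group_test([1, 2, 5], [4, 5, 6])
        t2, p2 = two_group_test([4, 5, 6], [1, 2, 5])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        t, p = two_group_test([1, 1], [2, 2])
        assert math.isinf(t) and t < 0 and p == 0.0

    def test_undersized_group_raises(self):
        with pytest.raises(ValueError, match="two values"):
            two_group_test([1], [2, 3])

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(0, 5.0, 40)
        _, p_s = two_group_test(a, b, variant="student")
        _, p_w = two_group_test(a, b, variant="welch")
        assert p_s != p_w


class TestDirectionalScores:
    def test_predictivity_hand_example(self):
        r = predictivity(EXPR6, EFF6)
        assert r.score == pytest.approx(-2.0)
        assert (r.n_high, r.n_low) == (3, 3)

    def test_descriptivity_hand_example(self):
        r = descriptivity(EXPR6, EFF6)
        assert r.score == pytest.approx(-3.0)
        assert (r.n_high, r.n_low) == (3, 3)

    def test_hand_example_scores_sign_concordant(self):
        assert predictivity(EXPR6, EFF6).score < 0
        assert descriptivity(EXPR6, EFF6).score < 0

    def test_constant_contrast_gives_null_result(self):
        r = predictivity(EXPR6, [0.0] * 6)
        assert r.score == 0.0 and r.p == 1.0
        r = descriptivity([2.0] * 6, EFF6)
        assert r.score == 0.0 and r.p == 1.0

    def test_negating_efficacy_negates_predictivity(self, rng):
        expr = rng.normal(size=20)
        eff = rng.normal(size=20)
        r1, r2 = predictivity(expr, eff), predictivity(expr, -eff)
        assert r1.score == pytest.approx(-r2.score)
        assert r1.p == pytest.approx(r2.p)

    def test_expression_shift_leaves_predictivity_unchanged(self, rng):
        expr = rng.normal(size=20)
        eff = rng.normal(size=20)
        r1, r2 = predictivity(expr, eff), predictivity(expr + 7.3, eff)
        assert r1.score == pytest.approx(r2.score)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_expression_flagged(self):
        r = predictivity([1.0] * 6, EFF6)
        assert r.status == "degenerate_expression" and math.isnan(r.score)

    def test_pairwise_missing_dropped_before_split(self):
        # dropping the NaN pair shifts the expression median
        expr = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        eff = [0.0, 0.1, -1.0, np.nan, -2.0, -3.0]
        r = predictivity(expr, eff)
        ref = naive_gene_scores(expr, eff)["predictivity"]
        assert r.score == pytest.approx(ref[0], abs=1e-12)
        assert (r.n_high, r.n_low) == (ref[2], ref[3])


class TestScan:
    def test_matches_brute_force_recomputation(self, rng):
        panel = random_panel(rng, n_genes=50, n_samples=12, missing_rate=0.15)
        records = cross_association_scan(panel)
        for i, rec in enumerate(records):
            ref = naive_gene_scores(
                panel.expression.values[i], panel.efficacy.values[i]
            )
            assert ref is not None and rec.status == "ok"
            for got, want in [
                ((rec.predictivity, rec.predictivity_p), ref["predictivity"]),
                ((rec.descriptivity, rec.descriptivity_p), ref["descriptivity"]),
            ]:
                assert got[0] == pytest.approx(want[0], abs=1e-12)
                assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_constant_expression_gene_flagged_in_isolation(self, rng):
        panel = random_panel(rng, n_genes=5, n_samples=10)
        panel.expression.data.iloc[2] = 3.0
        records = cross_association_scan(panel)
        assert records[2].status == "degenerate_expression"
        assert math.isnan(records[2].predictivity)
        assert all(r.status == "ok" for i, r in enumerate(records) if i != 2)

    def test_sample_order_invariance(self, rng):
        panel = random_panel(rng, n_genes=10, n_samples=12)
        perm = rng.permutation(panel.shared_samples).tolist()
        from crossdep import build_paired_panel

        shuffled = build_paired_panel(
            panel.expression.subset_samples(perm), panel.efficacy.subset_samples(perm)
        )
        r1, r2 = cross_association_scan(panel), cross_association_scan(shuffled)
        for a, b in zip(r1, r2):
            assert a.predictivity == pytest.approx(b.predictivity, abs=1e-12)
            assert a.descriptivity_p == pytest.approx(b.descriptivity_p, abs=1e-12)

    def test_group_counts_sum_to_observed_samples(self, small_panel):
        for i, rec in enumerate(cross_association_scan(small_panel)):
            if rec.status != "ok":
                continue
            n_obs = (~(np.isnan(small_panel.expression.values[i])
                       | np.isnan(small_panel.efficacy.values[i]))).sum()
            assert rec.n_high_exp + rec.n_low_exp == n_obs
            assert rec.n_high_phe + rec.n_low_phe == n_obs


def _rec(gene, p_pred, p_desc, s_pred, s_desc, status="ok"):
    return AssociationRecord(gene, s_pred, p_pred, s_desc, p_desc, 5, 5, 5, 5, status)


class TestCallHits:
    def test_dual_significant_concordant_is_hit(self):
        hits = call_hits([_rec("g", 0.005, 0.003, 1.0, 2.0)])
        assert [(h.gene_id, h.direction) for h in hits] == [("g", "positive")]

    def test_failing_one_threshold_is_not_hit(self):
        assert call_hits([_rec("g", 0.005, 0.02, 1.0, 2.0)]) == []

    def test_discordant_signs_excluded_by_default(self):
        rec = _rec("g", 0.005, 0.003, 1.0, -2.0)
        assert call_hits([rec]) == []
        (h,) = call_hits([rec], require_sign_concordance=False)
        assert h.direction == "discordant"

    def test_both_negative_is_negative_hit(self):
        (h,) = call_hits([_rec("g", 0.001, 0.001, -1.0, -0.5)])
        assert h.direction == "negative"

    def test_flagged_records_never_hits(self):
        assert call_hits([_rec("g", 0.001, 0.001, 1.0, 1.0, status="insufficient_group")]) == []


class TestSummaryAndCorrelation:
    def test_gene_summary_means_ignore_missing(self):
        expr = make_matrix([[2.0, 4.0], [1.0, 1.0]])
        eff = make_matrix([[-2.0, -4.0], [-2.0, np.nan]], assay="shRNA")
        from crossdep import build_paired_panel

        summary = gene_summary(build_paired_panel(expr, eff))
        assert summary["mean_efficacy"].tolist() == [-3.0, -2.0]
        assert summary["mean_expression"].tolist() == [3.0, 1.0]

    def test_top_efficacy_cutoff_is_strict(self):
        summary = pd.DataFrame(
            {"mean_expression": [1.0, 1.0], "mean_efficacy": [-1.6, -1.4]},
            index=["A (1)", "B (2)"],
        )
        assert top_efficacy_genes(summary, -1.5).index.tolist() == ["A (1)"]

    def test_platform_correlation_of_self_and_negation(self, rng):
        s = pd.DataFrame(
            {"mean_expression": rng.normal(size=10),
             "mean_efficacy": rng.normal(size=10)},
            index=[f"G{i}" for i in range(10)],
        )
        assert platform_correlation(s, s)[0] == pytest.approx(1.0)
        neg = s.assign(mean_efficacy=-s["mean_efficacy"])
        assert platform_correlation(s, neg)[0] == pytest.approx(-1.0)

    def test_platform_correlation_matches_covariance_formula(self, rng):
        idx = [f"G{i}" for i in range(100)]
        a = pd.DataFrame({"mean_expression": 0.0, "mean_efficacy": rng.normal(size=100)}, index=idx)
        b = pd.DataFrame(
            {"mean_expression": 0.0,
             "mean_efficacy": 0.5 * a["mean_efficacy"] + rng.normal(size=100)},
            index=idx,
        )
        r, n = platform_correlation(a, b)
        assert n == 100
        assert r == pytest.approx(
            naive_pearson(a["mean_efficacy"].tolist(), b["mean_efficacy"].tolist()),
            abs=1e-12,
        )

    def test_zero_variance_rejected(self):
        s = pd.DataFrame({"mean_expression": [0.0] * 3, "mean_efficacy": [1.0] * 3},
                         index=["a", "b", "c"])
        with pytest.raises(ValueError, match="variance"):
            platform_correlation(s, s)


def test_records_to_frame_schema_and_q_values(small_panel):
    records = cross_association_scan(small_panel)
    hits = call_hits(records, alpha_pred=0.5, alpha_desc=0.5)
    df = records_to_frame(records, hits)
    assert list(df.columns)[:10] == [
        "gene", "predictivity", "predictivity_p", "descriptivity", "descriptivity_p",
        "n_high_exp", "n_low_exp", "n_high_phe", "n_low_phe", "status",
    ]
    ok = df["status"] == "ok"
    # BH never lowers a p-value
    assert (df.loc[ok, "q_pred"] >= df.loc[ok, "predictivity_p"] - 1e-15).all()
    assert set(df.loc[df["direction"] != "", "gene"]) == {h.gene_id for h in hits}
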