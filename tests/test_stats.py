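"""Statistical micro-oracles: Wilcoxon, rank AUC, predictive values, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prostadiff.stats import (
    compare_groups,
    parameter_correlations,
    predictive_value_thresholds,
    rank_auc,
    roc_analysis,
)


def make_table(values_by_class: dict[str, np.ndarray], parameter: str = "x") -> pd.DataFrame:
    rows = []
    for cls, vals in values_by_class.items():
        for i, v in enumerate(vals):
            rows.append(
                dict(patient_id=f"{cls}{i:02d}", tissue_class=cls, parameter=parameter,
                     median=float(v), iqr=0.0)
            )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_five_uniform_sign_pairs_exact_p(self):
        """All 5 paired differences positive: exact two-sided p = 2/2^5 = 0.0625."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = make_table({"TP": a + 1.0, "FP": a})
        res = compare_groups(table, "x", "TP", "FP")
        assert res.p_value == pytest.approx(0.0625)
        assert res.test_name == "wilcoxon"
        assert res.direction == 1

    def test_identical_groups_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = make_table({"TP": a, "FP": a})
        res = compare_groups(table, "x", "TP", "FP")
        assert res.degenerate and res.p_value == 1.0

    def test_unequal_sizes_require_unpaired_flag(self):
        table = make_table({"TP": np.arange(6.0), "FP": np.arange(5.0)})
        with pytest.raises(ValueError, match="unpaired"):
            compare_groups(table, "x", "TP", "FP")
        res = compare_groups(table, "x", "TP", "FP", unpaired=True)
        assert res.test_name == "mann-whitney"
        assert 0.0 <= res.p_value <= 1.0

    def test_minimum_group_size_enforced(self):
        table = make_table({"TP": np.arange(4.0), "FP": np.arange(4.0)})
        with pytest.raises(ValueError, match="at least 5"):
            compare_groups(table, "x", "TP", "FP")

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_p_invariant_under_monotone_transform(self, scale, shift):
        """The signed-rank p depends only on ranks of the paired differences...

        so any strictly increasing affine map of the values leaves it unchanged.
        """
        rng = np.random.default_rng(42)
        a = rng.normal(1.0, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        t1 = make_table({"TP": a, "FP": b})
        t2 = make_table({"TP": scale * a + shift, "FP": scale * b + shift})
        r1 = compare_groups(t1, "x", "TP", "FP")
        r2 = compare_groups(t2, "x", "TP", "FP")
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_shapiro_wilk_reported(self):
        rng = np.random.default_rng(0)
        table = make_table({"TP": rng.normal(size=10), "FP": rng.normal(size=10)})
        res = compare_groups(table, "x", "TP", "FP")
        assert all(0.0 <= p <= 1.0 for p in res.normality_p)


class TestRankAUC:
    def test_perfect_separation(self):
        assert rank_auc([4, 5, 6], [1, 2, 3]) == 1.0

    def test_tie_half_credit_toy_sets(self):
        """Brute-force pair counting: 13 wins + 2 half-credit ties of 16 pairs = 0.875."""
        pos, neg = [3, 4, 5, 6], [1, 2, 3, 4]
        wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        assert wins / 16 == 0.875
        assert rank_auc(pos, neg) == pytest.approx(0.875)

    def test_null_distribution(self):
        rng = np.random.default_rng(43)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert rank_auc(a, b) == pytest.approx(0.5, abs=0.05)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(44)
        a, b = rng.normal(1, 1, 30), rng.normal(0, 1, 20)
        assert rank_auc(a, b) + rank_auc(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(45)
        pos, neg = rng.normal(0.5, 1, 40), rng.normal(0, 1, 35)
        y = np.r_[np.ones(40), np.zeros(35)]
        assert rank_auc(pos, neg) == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)


class TestROCAnalysis:
    def test_trapezoid_equals_rank_auc(self):
        rng = np.random.default_rng(46)
        table = make_table({"TP": rng.normal(1, 1, 15), "FP": rng.normal(0, 1, 15)})
        res = roc_analysis(table, "x", "TP", "FP")
        fpr = 1.0 - res.specificity
        # traverse the staircase properly: within equal fpr, ascending sensitivity
        order = np.lexsort((res.sensitivity, fpr))
        trap = np.trapezoid(res.sensitivity[order], fpr[order])
        assert trap == pytest.approx(res.auc, abs=1e-12)

    def test_orientation_recorded_not_flipped(self):
        table = make_table({"TP": [1.0, 2.0, 3.0], "FP": [4.0, 5.0, 6.0]})
        res = roc_analysis(table, "x", "TP", "FP")
        assert res.orientation == "lower"
        assert res.auc == 1.0

    def test_constant_scores_degenerate(self):
        table = make_table({"TP": [1.0, 1.0, 1.0], "FP": [1.0, 1.0, 1.0]})
        res = roc_analysis(table, "x", "TP", "FP")
        assert res.degenerate and res.auc == 0.5

    def test_row_order_invariance(self):
        rng = np.random.default_rng(47)
        table = make_table({"TP": rng.normal(1, 1, 10), "FP": rng.normal(0, 1, 10)})
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = roc_analysis(table, "x", "TP", "FP")
        b = roc_analysis(shuffled, "x", "TP", "FP")
        assert a.auc == b.auc
        assert a.ppv_max == b.ppv_max
        c1 = compare_groups(table, "x", "TP", "FP")
        c2 = compare_groups(shuffled, "x", "TP", "FP")
        assert c1.p_value == c2.p_value


class TestPredictiveValues:
    def test_separated_sets_exhaustive_sweep(self):
        """PPV = 1 anywhere in the gap (0.2, 0.4); midpoint 0.3 wins the count tie-break."""
        ppv, _npv = predictive_value_thresholds([0.4, 0.5], [0.1, 0.2], "higher")
        assert ppv["ppv"] == 1.0
        assert ppv["threshold"] == pytest.approx(0.3)

    def test_interleaved_scores_max_ppv_is_prevalence(self):
        pos = np.array([1.0, 3.0, 5.0, 7.0])
        neg = np.array([2.0, 4.0, 6.0, 8.0])
        # brute force over every midpoint: classifying everything positive
        # (threshold -inf) is optimal; PPV = prevalence = 0.5... unless a tail
        # threshold isolates the top score, which here is negative.
        ppv, _ = predictive_value_thresholds(pos, neg, "higher")
        assert ppv["ppv"] == pytest.approx(0.5)
        assert ppv["threshold"] == -np.inf

    def test_identical_sets_symmetric(self):
        s = np.array([0.1, 0.4, 0.7])
        ppv, npv = predictive_value_thresholds(s, s, "higher")
        assert ppv["ppv"] == pytest.approx(0.5)
        assert npv["npv"] == pytest.approx(0.5)

    def test_most_conservative_threshold_ppv_one(self):
        """If the single highest score is positive, some threshold reaches PPV 1."""
        pos = np.array([0.2, 0.9])
        neg = np.array([0.3, 0.5])
        ppv, _ = predictive_value_thresholds(pos, neg, "higher")
        assert ppv["ppv"] == 1.0

    def test_lower_direction(self):
        ppv, _ = predictive_value_thresholds([0.1, 0.2], [0.8, 0.9], "lower")
        assert ppv["ppv"] == 1.0

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            predictive_value_thresholds([], [1.0], "higher")


class TestCorrelations:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"D_K": x, "f_IC": 2 * x + 1})
        res = parameter_correlations(df, [("D_K", "f_IC")])
        assert res["r_squared"].iloc[0] == pytest.approx(1.0)
        assert res["sign"].iloc[0] == 1

    def test_independent_null(self):
        rng = np.random.default_rng(48)
        df = pd.DataFrame({"D": rng.normal(size=10_000), "f_EES": rng.normal(size=10_000)})
        res = parameter_correlations(df, [("D", "f_EES")])
        assert res["r_squared"].iloc[0] < 0.01

    def test_zero_variance_flagged_undefined(self):
        df = pd.DataFrame({"K": np.ones(10), "f_IC": np.arange(10.0)})
        res = parameter_correlations(df, [("K", "f_IC")])
        assert res["undefined"].iloc[0]
        assert np.isnan(res["r_squared"].iloc[0])

    def test_too_few_values_rejected(self):
        df = pd.DataFrame({"K": [1.0, 2.0], "f_IC": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            parameter_correlations(df, [("K", "f_IC")])
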