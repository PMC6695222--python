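import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riskpool.errors import DegenerateDataError
from riskpool.metrics import METRIC_VARIABLES
from riskpool.stats import (
    bonferroni_alpha,
    cohens_d,
    condition_pooling_check,
    reproduce_report,
    ttest_independent,
)


class TestTTest:
    def test_identical_groups(self):
        res = ttest_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_closed_form_small_example(self):
        # groups {0,2} vs {1,3}: means 1 and 2, pooled sd = sqrt(2),
        # se = sqrt(2)*sqrt(1/2 + 1/2) = sqrt(2), so t = -1/sqrt(2)
        res = ttest_independent([0.0, 2.0], [1.0, 3.0])
        assert res.t == pytest.approx(-1.0 / math.sqrt(2.0))
        assert res.df == 2
        assert res.p_two_tailed == pytest.approx(
            2 * sps.t.sf(1.0 / math.sqrt(2.0), 2)
        )

    def test_swapping_groups_flips_sign(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        fwd = ttest_independent(a, b)
        rev = ttest_independent(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p_two_tailed == pytest.approx(rev.p_two_tailed)

    def test_welch_flag(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 5, 40)
        student = ttest_independent(a, b, welch=False)
        welch = ttest_independent(a, b, welch=True)
        assert student.df == 48
        assert welch.df < 48
        assert welch.p_two_tailed != student.p_two_tailed

    def test_small_groups_rejected(self):
        with pytest.raises(DegenerateDataError):
            ttest_independent([1.0], [1.0, 2.0])

    def test_zero_variance_flagged_not_nan(self):
        same = ttest_independent([2.0, 2.0], [2.0, 2.0])
        assert same.degenerate and same.t == 0.0 and same.p_two_tailed == 1.0
        diff = ttest_independent([2.0, 2.0], [3.0, 3.0])
        assert diff.degenerate and math.isinf(diff.t) and diff.p_two_tailed == 0.0


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed_example(self):
        assert cohens_d([0.0, 2.0], [1.0, 3.0]) == pytest.approx(1 / math.sqrt(2))

    def test_translation_invariance(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 2, 20)
        assert cohens_d(a, b) == pytest.approx(cohens_d(a + 10, b + 10))

    def test_t_d_identity_pooled(self, rng):
        # |t| = |d| * sqrt(n1 n2 / (n1 + n2)); signs are opposite by
        # convention (t is control - primed, d is primed - control)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1, 158)
        res = ttest_independent(a, b)
        d = cohens_d(a, b)
        assert abs(res.t) == pytest.approx(
            abs(d) * math.sqrt(40 * 158 / (40 + 158))
        )
        assert math.copysign(1, res.t) == -math.copysign(1, d)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 7, 0.007), (0.05, 1, 0.05), (0.10, 5, 0.02)],
    )
    def test_adjusted_alpha(self, alpha, m, expected):
        assert round(bonferroni_alpha(alpha, m), 3) == expected

    def test_full_precision_retained(self):
        assert bonferroni_alpha(0.05, 7) == pytest.approx(0.05 / 7)

    def test_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(DegenerateDataError):
            bonferroni_alpha(0.0, 7)


def make_metrics_frame(rng, shift=None, n=12, conditions=4):
    labels = [f"cond{i}" for i in range(conditions)]
    rows = []
    for i, lab in enumerate(labels):
        mu = shift if (shift is not None and i == 0) else 0.0
        for _ in range(n):
            rows.append({"treatment": lab, "condition": lab,
                         **{v: rng.normal(mu, 1) for v in METRIC_VARIABLES}})
    return pd.DataFrame(rows)


class TestConditionPooling:
    def test_identical_conditions_give_zero_F(self):
        df = pd.DataFrame(
            {
                "treatment": ["x"] * 4 + ["y"] * 4,
                "repetitive_giving": [1.0, 2.0, 3.0, 4.0] * 2,
            }
        )
        out = condition_pooling_check(df, variables=["repetitive_giving"])
        anova = out[out["contrast"] == "ANOVA"].iloc[0]
        assert anova["F"] == pytest.approx(0.0)
        assert anova["p"] == pytest.approx(1.0)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 600
        for _ in range(n_rep):
            df = make_metrics_frame(rng, n=8)
            out = condition_pooling_check(df, variables=["repetitive_giving"])
            rejections += bool(out[out["contrast"] == "ANOVA"].iloc[0]["significant"])
        rate = rejections / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3.5 * se

    def test_scheffe_flags_only_shifted_condition(self):
        rng = np.random.default_rng(6)
        df = make_metrics_frame(rng, shift=4.0, n=12)
        out = condition_pooling_check(df, variables=["repetitive_giving"])
        pairs = out[out["contrast"] != "ANOVA"]
        involving = pairs["contrast"].str.contains("cond0")
        assert pairs[involving]["significant"].all()
        assert not pairs[~involving]["significant"].any()

    def test_tiny_condition_excluded_with_warning(self):
        rng = np.random.default_rng(7)
        df = make_metrics_frame(rng, n=6, conditions=3)
        df = pd.concat([df, df.iloc[[0]].assign(treatment="singleton")])
        with pytest.warns(UserWarning, match="singleton"):
            condition_pooling_check(df, variables=["repetitive_giving"])


class TestReproduceReport:
    def test_seven_rows_and_flags(self, rng):
        df = pd.concat(
            [
                make_metrics_frame(rng, n=20, conditions=1).assign(condition="control"),
                make_metrics_frame(rng, n=30, conditions=1).assign(condition="primed"),
            ]
        )
        report = reproduce_report(df)
        assert len(report) == 7
        assert list(report["variable"]) == METRIC_VARIABLES
        assert np.allclose(report["alpha_bonferroni"], 0.05 / 7)
        assert (report["df"] == 48).all()

    def test_missing_group_rejected(self, rng):
        df = make_metrics_frame(rng, n=10, conditions=1).assign(condition="control")
        with pytest.raises(DegenerateDataError):
            reproduce_report(df)
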