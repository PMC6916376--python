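"""Contingency diagnostics, group comparison, regression, VIF and ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from monotriage import (
    CombinedRule,
    ContingencyTable2x2,
    ValidationError,
    combined_rule,
    diagnostic_metrics,
    logistic_fit,
    roc_auc,
    round_half_up,
    tabulate,
    univariate_compare,
    vif,
)

counts = st.integers(0, 500)


def make_df(y, **cols):
    return pd.DataFrame({"consensus_dx": np.where(y, "CMML", "NONCLONAL"), **cols})


class TestTabulate:
    def test_fixture_monoscore_or_dysplasia(self, fixture_cohort):
        table, n_unknown = tabulate(
            fixture_cohort, lambda r: combined_rule(r, CombinedRule.MS_OR_DYS))
        assert (table.tp, table.fp, table.fn, table.tn) == (60, 73, 0, 63)
        assert n_unknown == 0

    def test_fixture_monoscore_or_cmo(self, fixture_cohort):
        table, _ = tabulate(
            fixture_cohort, lambda r: combined_rule(r, CombinedRule.MS_OR_CMO))
        assert (table.tp, table.fp, table.fn, table.tn) == (59, 79, 1, 57)

    def test_all_positive_predicate(self, fixture_cohort):
        table, _ = tabulate(fixture_cohort, lambda r: True)
        assert table.fn == 0 and table.tn == 0


class TestDiagnosticMetrics:
    def test_ppv_with_wald_ci(self):
        m = diagnostic_metrics(ContingencyTable2x2(60, 73, 0, 63))
        assert round_half_up(m.ppv.percent) == 45
        lo, hi = m.ppv.ci
        assert (round_half_up(lo), round_half_up(hi)) == (37, 54)
        assert m.npv.display() == "100% (95% CI: 100-100)"

    def test_degenerate_perfect_test(self):
        m = diagnostic_metrics(ContingencyTable2x2(10, 0, 0, 10))
        for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert est.percent == 100.0

    def test_zero_denominator_is_undefined_not_zero(self):
        m = diagnostic_metrics(ContingencyTable2x2(0, 0, 0, 5))
        assert not m.ppv.defined and m.ppv.percent is None
        assert "undefined" in m.ppv.display()

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    def test_swap_symmetry(self, tp, fp, fn, tn):
        # exchanging rows and columns swaps sens<->spec and PPV<->NPV
        if tp + fp + fn + tn == 0:
            return
        m = diagnostic_metrics(ContingencyTable2x2(tp, fp, fn, tn))
        s = diagnostic_metrics(ContingencyTable2x2(tp, fp, fn, tn).swapped())
        assert m.sensitivity == s.specificity and m.ppv == s.npv

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    def test_ppv_consistent_with_bayes(self, tp, fp, fn, tn):
        t = ContingencyTable2x2(tp, fp, fn, tn) if tp + fp + fn + tn else None
        if t is None or t.n_disease == 0 or t.n_healthy == 0 or tp + fp == 0:
            return
        m = diagnostic_metrics(t)
        sens = tp / t.n_disease
        spec = t.tn / t.n_healthy
        prev = t.n_disease / t.total
        bayes_ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        assert m.ppv.percent == pytest.approx(100 * bayes_ppv)

    def test_wald_width_shrinks_with_n(self):
        widths = []
        for n in (10, 100, 10_000):
            m = diagnostic_metrics(ContingencyTable2x2(n // 2, n // 2, 1, 1))
            lo, hi = m.ppv.ci
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 2.0


class TestUnivariateCompare:
    def test_identical_distributions(self):
        vals = np.tile(np.arange(20.0), 2)
        df = make_df(np.repeat([True, False], 20), score=vals)
        res = univariate_compare(df, "score")
        assert res.test == "mann-whitney"
        assert res.statistic == pytest.approx(20 * 20 / 2)  # null center
        assert res.pvalue > 0.9

    def test_complete_separation_u_statistic(self):
        # every CMML value below every control value -> U = 0
        df = make_df(np.repeat([True, False], 20),
                     score=np.concatenate([np.arange(20.0), 100 + np.arange(20.0)]))
        res = univariate_compare(df, "score")
        assert res.statistic == 0.0

    def test_categorical_complete_association(self):
        # 2x2 counts 50/0 vs 0/50: chi-square equals n
        df = make_df(np.repeat([True, False], 50), flag=np.repeat([1, 0], 50))
        res = univariate_compare(df, "flag")
        assert res.test == "chi-square"
        assert res.statistic == pytest.approx(100.0)

    def test_constant_variable_flagged(self):
        df = make_df(np.repeat([True, False], 10), x=np.ones(20))
        res = univariate_compare(df, "x")
        assert res.pvalue is None and res.note is not None


class TestLogisticFit:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(12)
        n = 5000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        beta = {"x1": 0.8, "x2": -0.5}
        logit = -0.3 + beta["x1"] * x1 + beta["x2"] * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = logistic_fit(make_df(y, x1=x1, x2=x2), ["x1", "x2"])
        assert res.converged and not res.separation
        for name, b in beta.items():
            assert res.table.loc[name, "or"] == pytest.approx(np.exp(b), rel=0.15)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.normal(size=n)
        y = rng.random(n) < 0.4
        res = logistic_fit(make_df(y, x=x), ["x"])
        assert res.table.loc["x", "or"] == pytest.approx(1.0, abs=0.1)
        assert res.table.loc["x", "pvalue"] > 0.01

    def test_binary_covariate_equals_cross_product_ratio(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.integers(0, 2, n)
        y = rng.random(n) < np.where(x == 1, 0.6, 0.3)
        a = int(((x == 1) & y).sum()); b = int(((x == 1) & ~y).sum())
        c = int(((x == 0) & y).sum()); d = int(((x == 0) & ~y).sum())
        res = logistic_fit(make_df(y, x=x), ["x"])
        assert res.table.loc["x", "or"] == pytest.approx(a * d / (b * c), rel=1e-4)


class TestVif:
    def test_independent_covariates_near_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(5000, 3)), columns=["a", "b", "c"])
        assert (vif(df, ["a", "b", "c"]) < 1.1).all()

    def test_correlated_pair_closed_form(self):
        # corr 0.9 -> VIF ~ 1/(1-0.81) ~ 5.26
        rng = np.random.default_rng(4)
        n = 20_000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        out = vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert out["a"] == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_duplicated_covariate_infinite(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=100)
        out = vif(pd.DataFrame({"a": a, "b": a}), ["a", "b"])
        assert np.isinf(out).all()

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            vif(pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)}), ["a", "b"])


class TestRoc:
    def test_perfect_separation(self):
        df = make_df(np.repeat([True, False], 30),
                     score=np.concatenate([np.ones(30), np.zeros(30)]))
        assert roc_auc(df, "score").auc == 1.0

    def test_uninformative_score(self):
        rng = np.random.default_rng(9)
        df = make_df(rng.random(5000) < 0.5, score=rng.normal(size=5000))
        assert roc_auc(df, "score").auc == pytest.approx(0.5, abs=0.03)

    def test_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(10)
        y = rng.random(300) < 0.4
        score = rng.normal(size=300) + y  # ties impossible, shift present
        df = make_df(y, score=score)
        u, _ = stats.mannwhitneyu(df.loc[y, "score"], df.loc[~y, "score"])
        assert roc_auc(df, "score").auc == pytest.approx(u / (y.sum() * (~y).sum()))

    def test_one_class_errors(self):
        df = make_df(np.ones(10, dtype=bool), score=np.arange(10.0))
        with pytest.raises(ValidationError):
            roc_auc(df, "score")
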