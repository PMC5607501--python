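"""Logistic models, ROC/AUC, tree cut-offs, combined rules, confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cmrmulti.diagnostics import (
    CutoffRule,
    combined_rule_metrics,
    confusion_metrics,
    counts_from_performance,
    fit_logistic,
    model_comparison_report,
    roc_auc,
    tree_cutoff,
)
from cmrmulti.synthetic import CohortSpec, GroupParams, simulate_cohort


def two_by_two_table(a, b, c, d):
    """Patients: a exposed / b unexposed; controls: c exposed / d unexposed."""
    return pd.DataFrame(
        {
            "group": ["patient"] * (a + b) + ["control"] * (c + d),
            "x": [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d,
        }
    )


class TestFitLogistic:
    def test_intercept_only_closed_form_aic(self):
        df = two_by_two_table(1, 1, 1, 1)
        model = fit_logistic(df, [])
        assert model.log_likelihood == pytest.approx(4 * np.log(0.5), abs=1e-6)
        assert model.aic == pytest.approx(2 + 8 * np.log(2), abs=1e-6)

    def test_binary_predictor_slope_is_log_odds_ratio(self):
        a, b, c, d = 30, 10, 8, 25
        model = fit_logistic(two_by_two_table(a, b, c, d), ["x"])
        assert model.coefficients["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame(
            {"group": ["control"] * 10 + ["patient"] * 10, "x": list(range(10)) + list(range(20, 30))}
        )
        model = fit_logistic(df, ["x"])
        assert model.separation

    def test_collinear_predictors_warn_but_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        df = pd.DataFrame(
            {"group": ["control"] * 20 + ["patient"] * 20, "x": x, "x2": 2 * x + 1e-9}
        )
        with pytest.warns(UserWarning, match="collinear"):
            fit_logistic(df, ["x", "x2"])

    def test_missing_predictor_column_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(two_by_two_table(5, 5, 5, 5), ["nope"])


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)].astype(int)
        assert roc_auc(scores, labels).auc == 1.0

    def test_worked_pair_count(self):
        # patients {3,1,2}, controls {2,0}: 4 wins + 1 tie of 6 pairs = 0.75
        scores = np.array([3.0, 1.0, 2.0, 2.0, 0.0])
        labels = np.array([1, 1, 1, 0, 0])
        assert roc_auc(scores, labels).auc == pytest.approx(0.75)

    def test_matches_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            scores = rng.integers(0, 30, size=200).astype(float)  # many ties
            labels = rng.integers(0, 2, size=200)
            if labels.sum() in (0, 200):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            oracle = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_direction_flip(self):
        scores = np.array([-3.0, -1.0, -2.0, -2.0, 0.0])
        labels = np.array([1, 1, 1, 0, 0])
        assert roc_auc(scores, labels, larger_is_abnormal=False).auc == pytest.approx(0.75)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, dtype=int))

    def test_roc_point_matches_rule_classifier(self):
        rng = np.random.default_rng(7)
        scores = np.r_[rng.normal(0, 1, 50), rng.normal(1.5, 1, 50)]
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        curve = roc_auc(scores, labels)
        tau = curve.thresholds[20]
        positive = scores >= tau
        sens = np.mean(positive[labels == 1])
        spec = np.mean(~positive[labels == 0])
        assert curve.tpr[20] == pytest.approx(sens)
        assert 1 - curve.fpr[20] == pytest.approx(spec)


def gini_scan_oracle(values, labels01, min_leaf):
    """Independent exhaustive scan over midpoints (reference implementation)."""

    def gini(y):
        if len(y) == 0:
            return 0.0
        p = np.mean(y)
        return 1 - p**2 - (1 - p) ** 2

    v = np.asarray(values, float)
    y = np.asarray(labels01, int)
    n = len(v)
    parent = gini(y)
    best = (-np.inf, None)
    for thr in (np.sort(np.unique(v))[:-1] + np.sort(np.unique(v))[1:]) / 2:
        left, right = y[v < thr], y[v >= thr]
        if len(left) < min_leaf or len(right) < min_leaf:
            continue
        gain = parent - (len(left) * gini(left) + len(right) * gini(right)) / n
        if gain > best[0] + 1e-12:
            best = (gain, thr)
    return best[1]


class TestTreeCutoff:
    def test_clean_separation_midpoint(self):
        rule = tree_cutoff(
            np.array([1.0, 1, 1, 3, 3, 3]),
            np.array(["control"] * 3 + ["patient"] * 3),
            min_leaf=1,
        )
        assert rule.threshold == 2.0 and rule.direction == "ge"

    def test_lower_abnormal_direction(self):
        rule = tree_cutoff(
            np.array([1.0, 1, 1, 3, 3, 3]),
            np.array(["patient"] * 3 + ["control"] * 3),
            min_leaf=1,
        )
        assert rule.threshold == 2.0 and rule.direction == "le"

    def test_constant_labels_or_values_rejected(self):
        with pytest.raises(ValueError):
            tree_cutoff(np.arange(6.0), np.array(["patient"] * 6), min_leaf=1)
        with pytest.raises(ValueError):
            tree_cutoff(np.ones(6), np.array(["control"] * 3 + ["patient"] * 3), min_leaf=1)

    def test_planted_threshold_recovered_between_straddling_values(self):
        rng = np.random.default_rng(8)
        n = 100
        ctrl = rng.uniform(0.2, 1.75, n // 2)
        pat = rng.uniform(1.85, 5.0, n // 2)
        values = np.r_[ctrl, pat]
        labels = np.array(["control"] * (n // 2) + ["patient"] * (n // 2))
        noise_idx = rng.choice(n, size=n // 10, replace=False)
        labels[noise_idx] = np.where(labels[noise_idx] == "control", "patient", "control")
        rule = tree_cutoff(values, labels, min_leaf=7)
        below = values[values < rule.threshold].max()
        above = values[values >= rule.threshold].min()
        assert below < 1.85 + 0.4 and above > 1.75 - 0.4  # near the planted gap
        assert ctrl.max() - 0.4 <= rule.threshold <= pat.min() + 0.4

    def test_matches_independent_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(20, 60))
            values = np.round(rng.normal(2.0, 1.0, n), 1)  # duplicates likely
            labels01 = (values + rng.normal(0, 1.0, n) > 2.0).astype(int)
            if labels01.sum() in (0, n) or len(np.unique(values)) < 2:
                continue
            min_leaf = 3
            oracle_thr = gini_scan_oracle(values, labels01, min_leaf)
            if oracle_thr is None:
                continue
            labels = np.where(labels01 == 1, "patient", "control")
            rule = tree_cutoff(values, labels, min_leaf=min_leaf)
            assert rule.threshold == pytest.approx(oracle_thr, abs=1e-12)


class TestCombinedRules:
    RULES = [
        CutoffRule("madSD_ms", 1.8, "ge", "ms"),
        CutoffRule("GCS_LV_pct", -25.0, "ge", "%"),
    ]

    def patient_row(self, madsd, gcs, lge):
        return pd.DataFrame(
            {
                "group": ["patient", "control"],
                "madSD_ms": [madsd, 0.5],
                "GCS_LV_pct": [gcs, -30.0],
                "LGE": [lge, 0],
            }
        )

    def test_all_criteria_met_is_positive(self):
        df = self.patient_row(2.0, -20.0, 1)
        m = combined_rule_metrics(df, self.RULES, lge_included=True)
        assert m.tp == 1 and m.fn == 0

    def test_one_failed_criterion_is_negative(self):
        df = self.patient_row(2.0, -30.0, 1)  # GCS more negative than -25: normal
        m = combined_rule_metrics(df, self.RULES, lge_included=True)
        assert m.tp == 0 and m.fn == 1

    def test_everyone_positive_extreme(self):
        df = pd.DataFrame(
            {
                "group": ["patient"] * 3 + ["control"] * 2,
                "madSD_ms": [5.0] * 5,
                "GCS_LV_pct": [-10.0] * 5,
            }
        )
        m = combined_rule_metrics(df, self.RULES)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_adding_criterion_never_raises_sensitivity_nor_lowers_specificity(self):
        df = simulate_cohort(CohortSpec(seed=21))
        m1 = combined_rule_metrics(df, self.RULES[:1])
        m2 = combined_rule_metrics(df, self.RULES)
        m3 = combined_rule_metrics(df, self.RULES, lge_included=True)
        assert m1.sensitivity >= m2.sensitivity >= m3.sensitivity
        assert m1.specificity <= m2.specificity <= m3.specificity

    def test_missing_values_excluded_and_counted(self):
        df = self.patient_row(2.0, -20.0, 1)
        df.loc[1, "madSD_ms"] = np.nan
        df = pd.concat([df, self.patient_row(2.0, -20.0, 1)], ignore_index=True)
        m = combined_rule_metrics(df, self.RULES, lge_included=True)
        assert m.n_excluded == 1


class TestConfusionMetrics:
    def test_reference_performance_row(self):
        # 39 detected / 28 missed patients, all 17 controls negative
        m = confusion_metrics(tp=39, fp=0, tn=17, fn=28)
        pct = m.as_percent_dict()
        assert pct["sensitivity_pct"] == 58
        assert pct["specificity_pct"] == 100
        assert pct["ppv_pct"] == 100
        assert pct["npv_pct"] == 38
        assert pct["accuracy_pct"] == 67

    def test_undefined_ratio_is_none_not_zero(self):
        m = confusion_metrics(tp=0, fp=3, tn=5, fn=0)
        assert m.sensitivity is None
        assert m.as_percent_dict()["sensitivity_pct"] is None

    def test_all_correct_is_all_hundred(self):
        pct = confusion_metrics(tp=10, fp=0, tn=10, fn=0).as_percent_dict()
        assert all(pct[k] == 100 for k in
                   ("sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct", "accuracy_pct"))

    def test_negative_or_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)

    def test_counts_recovered_from_printed_percentages(self):
        m = counts_from_performance(58, 100, n_patients=67, n_controls=17)
        assert (m.tp, m.fn, m.tn, m.fp) == (39, 28, 17, 0)


class TestModelComparison:
    def test_aic_prefers_the_informative_model(self):
        # only predictor A is informative; the AIC penalty should usually
        # rank {A} above {A, B}
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 60
            a = np.r_[rng.normal(0, 1, n // 2), rng.normal(1.0, 1, n // 2)]
            b = rng.normal(size=n)
            df = pd.DataFrame(
                {"group": ["control"] * (n // 2) + ["patient"] * (n // 2), "A": a, "B": b}
            )
            rep = model_comparison_report(df, {"A": ["A"], "AB": ["A", "B"]})
            wins += rep.iloc[0]["model"] == "A"
        assert wins > 70

    def test_duplicate_specs_give_identical_rows(self):
        df = simulate_cohort(CohortSpec(seed=30))
        rep = model_comparison_report(df, {"m1": ["madSD_ms"], "m2": ["madSD_ms"]})
        a, b = rep[rep.model == "m1"].iloc[0], rep[rep.model == "m2"].iloc[0]
        assert a.aic == b.aic and a.auc == b.auc

    def test_empty_spec_is_intercept_baseline(self):
        df = simulate_cohort(CohortSpec(seed=31))
        rep = model_comparison_report(df, {"base": []})
        assert rep.iloc[0].predictors == "(intercept)"
        assert rep.iloc[0].auc == 0.5
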