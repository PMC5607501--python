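"""Diagnostic-rule construction and evaluation on cohort tables.

The statistical layer of the pipeline: logistic classification models
compared by AIC, ROC/AUC analysis, classification-tree cut-off discovery,
combined k-of-k rules (a subject is test-positive only when *every*
criterion is met), and confusion-matrix metrics.

Cohort tables are plain pandas DataFrames with a ``group`` column holding
``control`` / ``patient`` labels and one column per parameter (madSD,
maxT2, strain values, binary LGE, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

__all__ = [
    "LogisticModel",
    "CutoffRule",
    "RocCurve",
    "RuleMetrics",
    "fit_logistic",
    "roc_auc",
    "tree_cutoff",
    "apply_rule",
    "combined_rule_metrics",
    "confusion_metrics",
    "counts_from_performance",
    "model_comparison_report",
]

_SEPARATION_COEF = 20.0  # |coefficient| beyond which we call separation


def _outcome(table: pd.DataFrame, group_col: str = "group") -> np.ndarray:
    y = (table[group_col] == "patient").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be present")
    return y


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """A fitted logistic classification model.

    ``aic = 2k - 2 ln L`` with ``k`` counting the intercept.  ``separation``
    flags (quasi-)perfect separation, where coefficients diverge and the
    AIC comparison is not meaningful.
    """

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    log_likelihood: float
    aic: float
    converged: bool
    separation: bool
    fitted_probabilities: np.ndarray = field(repr=False, default=None)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(
            table[list(self.predictors)].to_numpy(dtype=float), has_constant="add"
        )
        beta = np.array([self.coefficients["const"]] +
                        [self.coefficients[p] for p in self.predictors])
        return 1.0 / (1.0 + np.exp(-X @ beta))


def fit_logistic(
    table: pd.DataFrame,
    predictors: list[str] | tuple[str, ...],
    group_col: str = "group",
) -> LogisticModel:
    """Maximum-likelihood logistic regression of patient status.

    Uses iteratively reweighted least squares (statsmodels ``Logit``).
    Collinear predictors keep fitting but emit a condition-number warning;
    perfect separation is detected and flagged rather than raised.
    """
    predictors = tuple(predictors)
    y = _outcome(table, group_col)
    if len(predictors) == 0:
        X = np.ones((len(y), 1))
        names = ["const"]
    else:
        missing = [p for p in predictors if p not in table.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        Xraw = table[list(predictors)].to_numpy(dtype=float)
        if len(predictors) > 1:
            cond = np.linalg.cond(np.column_stack([np.ones(len(y)), Xraw]))
            if cond > 1e6:
                warnings.warn(
                    f"ill-conditioned design (cond={cond:.2g}); collinear predictors",
                    stacklevel=2,
                )
        X = sm.add_constant(Xraw, has_constant="add")
        names = ["const"] + list(predictors)

    separation = False
    converged = True
    params = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            params = np.asarray(res.params, dtype=float)
        except Exception:
            # separation or a singular design can raise; fall back to a
            # ridge-stabilized fit purely to report finite coefficients
            converged = False
            separation = True
            try:
                res = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
                params = np.asarray(res.params, dtype=float)
            except Exception:
                pass
    if any("erfect separation" in str(w.message) for w in caught):
        separation = True
    if params is None:
        # degenerate design (e.g. constant predictors): intercept-only baseline
        p = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        params = np.zeros(X.shape[1])
        params[0] = np.log(p / (1 - p))
    if np.any(np.abs(params[1:] if len(params) > 1 else params) > _SEPARATION_COEF):
        separation = True
    probs = 1.0 / (1.0 + np.exp(-(X @ params)))
    eps = 1e-12
    llf = float(np.sum(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    aic = 2 * len(params) - 2 * llf
    return LogisticModel(
        predictors=predictors,
        coefficients=dict(zip(names, params)),
        log_likelihood=llf,
        aic=aic,
        converged=converged,
        separation=separation,
        fitted_probabilities=probs,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    auc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_patients: int
    n_controls: int


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    larger_is_abnormal: bool = True,
) -> RocCurve:
    """ROC curve and AUC by the rank (Mann-Whitney) formula.

    The AUC equals the fraction of patient-control pairs in which the
    patient scores more abnormal, counting ties as one half — computed
    exactly via midranks.  ROC points are given at every distinct score
    threshold (test positive when the oriented score >= threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == "patient").astype(int)
    y = y.astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if not larger_is_abnormal:
        s = -s
    ranks = rankdata(s)  # midranks handle ties exactly
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(1 - y_sorted)[idx]
    return RocCurve(
        auc=float(auc),
        thresholds=s_sorted[idx],
        tpr=tp / n_pos,
        fpr=fp / n_neg,
        n_patients=n_pos,
        n_controls=n_neg,
    )


# ---------------------------------------------------------------------------
# classification-tree cut-offs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CutoffRule:
    """A single-parameter decision rule: abnormal when value {>=, <=} threshold."""

    parameter: str
    threshold: float
    direction: str  # "ge" (higher abnormal) or "le" (lower abnormal)
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("ge", "le"):
            raise ValueError("direction must be 'ge' or 'le'")

    def is_abnormal(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return v >= self.threshold if self.direction == "ge" else v <= self.threshold


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p**2))


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def tree_cutoff(
    values: np.ndarray,
    labels: np.ndarray,
    min_leaf: int = 7,
    parameter: str = "",
    units: str = "",
    criterion: str = "gini",
) -> CutoffRule:
    """Optimal single-split cut-off, as a depth-one classification tree.

    Exhaustively scans the midpoints between consecutive sorted distinct
    values, maximizing the impurity decrease (Gini by default,
    ``criterion="information"`` for entropy) subject to both leaves
    holding at least ``min_leaf`` subjects.  Ties break toward the
    smaller threshold.  The direction is set so that the side holding the
    patient majority is called abnormal.
    """
    impurity = _gini if criterion == "gini" else _entropy
    if criterion not in ("gini", "information"):
        raise ValueError("criterion must be 'gini' or 'information'")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == "patient").astype(int)
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; no split exists")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("values are constant; no split exists")
    if len(v) < 2 * min_leaf:
        raise ValueError("not enough subjects for min_leaf on both sides")

    order = np.argsort(v, kind="mergesort")
    v_sorted, y_sorted = v[order], y[order]
    n = len(v)
    total = np.array([np.sum(y == 0), np.sum(y == 1)])
    parent = impurity(total)

    best_gain, best_thr = -np.inf, None
    cum_pos = np.cumsum(y_sorted)
    for i in range(n - 1):
        if v_sorted[i] == v_sorted[i + 1]:
            continue
        n_left = i + 1
        n_right = n - n_left
        if n_left < min_leaf or n_right < min_leaf:
            continue
        left = np.array([n_left - cum_pos[i], cum_pos[i]])
        right = total - left
        gain = parent - (n_left * impurity(left) + n_right * impurity(right)) / n
        if gain > best_gain + 1e-12:  # strict: ties keep the smaller threshold
            best_gain = gain
            best_thr = 0.5 * (v_sorted[i] + v_sorted[i + 1])
    if best_thr is None:
        raise ValueError("no admissible split under the min_leaf constraint")

    right_mask = v >= best_thr
    frac_right = y[right_mask].mean()
    frac_left = y[~right_mask].mean()
    direction = "ge" if frac_right >= frac_left else "le"
    return CutoffRule(parameter=parameter, threshold=float(best_thr), direction=direction, units=units)


# ---------------------------------------------------------------------------
# confusion metrics and combined rules
# ---------------------------------------------------------------------------


@dataclass
class RuleMetrics:
    """Confusion counts with derived diagnostic metrics.

    Fractions are exact; the ``*_pct`` properties round to integer percent
    for display.  Undefined ratios (zero denominator) are ``None``, never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    auc_binary: float | None = None
    n_excluded: int = 0

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    def as_percent_dict(self) -> dict[str, float | None]:
        def pct(x):
            return None if x is None else round(100 * x)

        return {
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "accuracy_pct": pct(self.accuracy),
            "auc": None if self.auc is None else round(self.auc, 2),
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> RuleMetrics:
    """Build :class:`RuleMetrics` from confusion counts."""
    for name, c in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if c < 0:
            raise ValueError(f"{name} must be >= 0")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion table")
    return RuleMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def counts_from_performance(
    sensitivity_pct: float,
    specificity_pct: float,
    n_patients: int,
    n_controls: int,
) -> RuleMetrics:
    """Recover confusion counts from printed sensitivity/specificity.

    Inverts the percentage arithmetic of a published performance table:
    ``TP = round(sens * n_patients)``, ``TN = round(spec * n_controls)``.
    Useful for internal-consistency checks on reported results.
    """
    tp = round(sensitivity_pct / 100.0 * n_patients)
    tn = round(specificity_pct / 100.0 * n_controls)
    return confusion_metrics(tp=tp, fp=n_controls - tn, tn=tn, fn=n_patients - tp)


def apply_rule(table: pd.DataFrame, rule: CutoffRule) -> np.ndarray:
    if rule.parameter not in table.columns:
        raise ValueError(f"missing column {rule.parameter!r}")
    return rule.is_abnormal(table[rule.parameter].to_numpy(dtype=float))


def combined_rule_metrics(
    table: pd.DataFrame,
    rules: list[CutoffRule],
    lge_included: bool = False,
    lge_col: str = "LGE",
    group_col: str = "group",
) -> RuleMetrics:
    """Evaluate a k-of-k combined rule: positive only when ALL criteria hit.

    Sensitivity is the proportion of patients meeting every cut-off;
    specificity the proportion of controls failing at least one.  With
    ``lge_included`` a positive-LGE criterion joins the rule set.  The
    AUC field holds the rank AUC of a logistic model over the same
    (continuous + LGE) predictors; ``auc_binary`` scores the binary rule
    output itself.  Subjects missing any required value are excluded and
    counted in ``n_excluded``.
    """
    if not rules and not lge_included:
        raise ValueError("no criteria given")
    cols = [r.parameter for r in rules] + ([lge_col] if lge_included else [])
    present = table[cols].notna().all(axis=1)
    data = table.loc[present]
    n_excluded = int((~present).sum())

    positive = np.ones(len(data), dtype=bool)
    for rule in rules:
        positive &= apply_rule(data, rule)
    if lge_included:
        positive &= data[lge_col].to_numpy(dtype=float) > 0

    y = _outcome(data, group_col).astype(bool)
    tp = int(np.sum(positive & y))
    fp = int(np.sum(positive & ~y))
    tn = int(np.sum(~positive & ~y))
    fn = int(np.sum(~positive & y))
    metrics = confusion_metrics(tp=tp, fp=fp, tn=tn, fn=fn)
    metrics.n_excluded = n_excluded

    model = fit_logistic(data, cols, group_col)
    metrics.auc = roc_auc(model.fitted_probabilities, y.astype(int)).auc
    metrics.auc_binary = roc_auc(positive.astype(float), y.astype(int)).auc
    return metrics


def model_comparison_report(
    table: pd.DataFrame,
    model_specs: dict[str, list[str]],
    group_col: str = "group",
) -> pd.DataFrame:
    """Fit every candidate predictor set; rank by AIC, attach ROC metrics.

    ``model_specs`` maps a display name to its predictor list (an empty
    list yields the intercept-only baseline).  Returns one row per model,
    sorted by ascending AIC, with AUC from the fitted probabilities.
    """
    if not model_specs:
        raise ValueError("no model specs given")
    y = _outcome(table, group_col).astype(int)
    rows = []
    for name, predictors in model_specs.items():
        model = fit_logistic(table, predictors, group_col)
        auc = (
            roc_auc(model.fitted_probabilities, y).auc if len(predictors) > 0 else 0.5
        )
        rows.append(
            {
                "model": name,
                "predictors": "+".join(predictors) if predictors else "(intercept)",
                "n_predictors": len(predictors),
                "aic": model.aic,
                "auc": auc,
                "log_likelihood": model.log_likelihood,
                "converged": model.converged,
                "separation": model.separation,
            }
        )
    return pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
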