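"""Diagnostic-performance statistics.

2x2 contingency tables with sensitivity/specificity/PPV/NPV and Wald 95%
confidence intervals, univariate group comparison (Mann-Whitney /
chi-square), multivariate logistic regression with Wald CIs on odds
ratios, variance inflation factors and nonparametric ROC analysis.

Predictive-value CIs use the normal (Wald) approximation with z fixed at
1.96 and bounds clipped to [0, 100]; display values round half-up to
integer percent. These conventions are deliberate and bit-stable — the
published tables in this problem area are reproducible only under them.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import Cohort, Diagnosis, PatientRecord, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "ProportionEstimate",
    "DiagnosticMetrics",
    "UnivariateResult",
    "LogisticFitResult",
    "RocResult",
    "tabulate",
    "diagnostic_metrics",
    "univariate_compare",
    "logistic_fit",
    "vif",
    "roc_auc",
    "round_half_up",
]

Z_95 = 1.96  # fixed normal quantile for bit-stable CI reproduction


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (45.5 -> 46), the display convention used
    for all printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Test result (rows) against disease status (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total < 1:
            raise ValidationError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_disease(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    def swapped(self) -> "ContingencyTable2x2":
        """Exchange rows and columns: tn takes tp's role and vice versa."""
        return ContingencyTable2x2(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion as percent with its Wald 95% CI, or undefined when the
    denominator is empty."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def percent(self) -> float | None:
        if not self.defined:
            return None
        return 100.0 * self.numerator / self.denominator

    @property
    def ci(self) -> tuple[float, float] | None:
        if not self.defined:
            return None
        p = self.numerator / self.denominator
        half = Z_95 * np.sqrt(p * (1.0 - p) / self.denominator)
        lo = max(0.0, 100.0 * (p - half))
        hi = min(100.0, 100.0 * (p + half))
        return (lo, hi)

    def display(self) -> str:
        """Paper-style rendering, e.g. ``45% (95% CI: 37-54)``."""
        if not self.defined:
            return "undefined (empty denominator)"
        lo, hi = self.ci
        return (
            f"{round_half_up(self.percent):.0f}% "
            f"(95% CI: {round_half_up(lo):.0f}-{round_half_up(hi):.0f})"
        )

    def to_dict(self) -> dict:
        d: dict = {"numerator": self.numerator, "denominator": self.denominator}
        if self.defined:
            lo, hi = self.ci
            d.update(
                percent=self.percent,
                ci_low=lo,
                ci_high=hi,
                display=self.display(),
            )
        else:
            d.update(percent=None, ci_low=None, ci_high=None, display=self.display())
        return d


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.to_dict(),
            "specificity": self.specificity.to_dict(),
            "ppv": self.ppv.to_dict(),
            "npv": self.npv.to_dict(),
        }


def diagnostic_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    return DiagnosticMetrics(
        sensitivity=ProportionEstimate(table.tp, table.tp + table.fn),
        specificity=ProportionEstimate(table.tn, table.tn + table.fp),
        ppv=ProportionEstimate(table.tp, table.tp + table.fp),
        npv=ProportionEstimate(table.tn, table.tn + table.fn),
    )


def tabulate(
    cohort: Cohort, predicate: Callable[[PatientRecord], bool]
) -> tuple[ContingencyTable2x2, int]:
    """Count a binary test against the consensus diagnosis.

    Records with an UNKNOWN diagnosis are excluded; their number is
    returned alongside the table.
    """
    tp = fp = fn = tn = 0
    n_unknown = 0
    for rec in cohort:
        if rec.consensus_dx is Diagnosis.UNKNOWN:
            n_unknown += 1
            continue
        pos = bool(predicate(rec))
        disease = rec.consensus_dx is Diagnosis.CMML
        if pos and disease:
            tp += 1
        elif pos:
            fp += 1
        elif disease:
            fn += 1
        else:
            tn += 1
    if tp + fp + fn + tn == 0:
        raise ValidationError("no records with a known consensus diagnosis to tabulate")
    return ContingencyTable2x2(tp, fp, fn, tn), n_unknown


# --------------------------------------------------------------------------
# Group comparison, regression, collinearity, ROC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str  # "mann-whitney" or "chi-square"
    statistic: float | None
    pvalue: float | None
    per_class: dict
    note: str | None = None


def _class_arrays(df: pd.DataFrame, variable: str) -> tuple[np.ndarray, np.ndarray]:
    known = df[df["consensus_dx"] != Diagnosis.UNKNOWN.value]
    cmml = known.loc[known["consensus_dx"] == Diagnosis.CMML.value, variable].dropna().to_numpy()
    ctrl = known.loc[known["consensus_dx"] == Diagnosis.NONCLONAL.value, variable].dropna().to_numpy()
    if len(cmml) == 0 or len(ctrl) == 0:
        raise ValidationError(f"both diagnosis classes must be represented for {variable!r}")
    return cmml, ctrl


def univariate_compare(
    cohort: Cohort | pd.DataFrame, variable: str, categorical: bool | None = None
) -> UnivariateResult:
    """Compare one variable between CMML and nonclonal monocytosis.

    Continuous variables get a two-sided Mann-Whitney test with medians and
    ranges per class; categorical (boolean/integer-coded) variables get a
    Pearson chi-square without continuity correction.
    """
    df = cohort.to_dataframe() if isinstance(cohort, Cohort) else cohort
    if variable not in df.columns:
        raise ValidationError(f"unknown variable {variable!r}")
    cmml, ctrl = _class_arrays(df, variable)
    if categorical is None:
        values = np.concatenate([cmml, ctrl])
        categorical = len(np.unique(values)) <= 2
    if np.all(cmml == cmml[0]) and np.all(ctrl == ctrl[0]) and cmml[0] == ctrl[0]:
        return UnivariateResult(variable, "constant", None, None,
                                per_class={}, note="variable is constant; p undefined")
    if categorical:
        levels = np.unique(np.concatenate([cmml, ctrl]))
        counts = np.array([
            [(cmml == lv).sum() for lv in levels],
            [(ctrl == lv).sum() for lv in levels],
        ])
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        per_class = {
            "CMML": {str(lv): int((cmml == lv).sum()) for lv in levels},
            "NONCLONAL": {str(lv): int((ctrl == lv).sum()) for lv in levels},
        }
        return UnivariateResult(variable, "chi-square", float(chi2), float(p), per_class)
    u_stat, p = stats.mannwhitneyu(cmml, ctrl, alternative="two-sided")
    per_class = {
        "CMML": {"n": len(cmml), "median": float(np.median(cmml)),
                 "min": float(cmml.min()), "max": float(cmml.max())},
        "NONCLONAL": {"n": len(ctrl), "median": float(np.median(ctrl)),
                      "min": float(ctrl.min()), "max": float(ctrl.max())},
    }
    return UnivariateResult(variable, "mann-whitney", float(u_stat), float(p), per_class)


@dataclass(frozen=True)
class LogisticFitResult:
    table: pd.DataFrame  # index: covariate; columns: or, ci_low, ci_high, pvalue, coef
    converged: bool
    separation: bool
    n_obs: int

    def summary(self) -> str:
        lines = [f"Logistic regression (n={self.n_obs}, converged={self.converged})"]
        if self.separation:
            lines.append("WARNING: (quasi-)separation detected; odds ratios unreliable")
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def logistic_fit(
    cohort: Cohort | pd.DataFrame, covariates: Sequence[str], target: str = "consensus_dx"
) -> LogisticFitResult:
    """Maximum-likelihood logistic regression of CMML status on covariates,
    reporting odds ratios with Wald 95% CIs and p-values. Separation and
    non-convergence are detected and flagged, never silently ignored."""
    df = cohort.to_dataframe() if isinstance(cohort, Cohort) else cohort
    df = df[df[target] != Diagnosis.UNKNOWN.value] if target == "consensus_dx" else df
    y = (
        (df[target] == Diagnosis.CMML.value).astype(float)
        if df[target].dtype == object
        else df[target].astype(float)
    )
    X = sm.add_constant(df[list(covariates)].astype(float), has_constant="add")
    separation = False
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except PerfectSeparationError:
        raise ValidationError(
            "perfect separation: a covariate (combination) splits the classes exactly; "
            "the MLE does not exist"
        )
    params = fit.params.drop("const")
    se = fit.bse.drop("const")
    if (np.abs(params) > 15).any() or not converged:
        separation = True
    ci = fit.conf_int(alpha=0.05).drop(index="const")
    table = pd.DataFrame(
        {
            "coef": params,
            "or": np.exp(params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "pvalue": fit.pvalues.drop("const"),
            "se": se,
        }
    )
    return LogisticFitResult(table=table, converged=converged,
                             separation=separation, n_obs=int(fit.nobs))


def vif(cohort: Cohort | pd.DataFrame, covariates: Sequence[str]) -> pd.Series:
    """Variance inflation factor per covariate: VIF_j = 1/(1 - R^2_j) from
    the auxiliary regression of covariate j on the others (with intercept).
    Perfect collinearity yields ``inf``."""
    if len(covariates) < 2:
        raise ValidationError("VIF requires at least two covariates")
    df = cohort.to_dataframe() if isinstance(cohort, Cohort) else cohort
    X = df[list(covariates)].astype(float)
    if (X.nunique() <= 1).any():
        bad = list(X.columns[X.nunique() <= 1])
        raise ValidationError(f"constant covariates have undefined VIF: {bad}")
    Xc = sm.add_constant(X, has_constant="add").to_numpy()
    out = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(covariates, start=1):
            v = variance_inflation_factor(Xc, j)
            out[name] = float(v) if np.isfinite(v) else float("inf")
    return pd.Series(out, name="vif")


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(cohort: Cohort | pd.DataFrame, score_field: str) -> RocResult:
    """Nonparametric (empirical) ROC curve and rank-based AUC for a
    continuous score against the consensus diagnosis; ties are handled by
    midranks, so the AUC equals the Mann-Whitney U statistic divided by
    n1*n2."""
    df = cohort.to_dataframe() if isinstance(cohort, Cohort) else cohort
    known = df[df["consensus_dx"] != Diagnosis.UNKNOWN.value]
    y = (known["consensus_dx"] == Diagnosis.CMML.value).to_numpy()
    scores = known[score_field].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValidationError("ROC analysis needs both diagnosis classes present")
    fpr, tpr, thr = roc_curve(y, scores)
    return RocResult(auc=float(roc_auc_score(y, scores)), fpr=fpr, tpr=tpr, thresholds=thr)
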