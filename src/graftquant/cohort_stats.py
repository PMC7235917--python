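"""Cohort-level statistics for fusion outcome and graft uptake.

Small-cohort explorative analysis: descriptives as median [min, max] by
fusion group, univariate logistic regressions of fusion status on single
predictors (odds ratio with Wald 95% CI and p-value), and Spearman rank
correlation of one-month graft uptake against the 12-month-minus-baseline
change in each clinical score.  Missing data are handled per test
(available-case, no imputation), and no multiple-testing correction is
applied — the report records the number of tests run instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SCORE_VARIABLES",
    "LogitResult",
    "SpearmanResult",
    "StatReport",
    "score_change",
    "univariate_logit",
    "spearman_uptake_vs_change",
    "describe",
    "run_cohort_stats",
]

SCORE_VARIABLES = ["WLK_D", "VAS_B", "VAS_L", "TAN", "ODI", "EQ_5D"]
UPTAKE_VARIABLES = ["suv_total", "c_suv_total"]


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class LogitResult:
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    separation: bool = False


@dataclass(frozen=True)
class SpearmanResult:
    uptake_metric: str
    change_variable: str
    rho: float
    p_value: float
    n: int


@dataclass
class StatReport:
    """Everything the analysis produces, plus the number of tests run."""

    descriptives: pd.DataFrame
    logits: list[LogitResult] = field(default_factory=list)
    spearman: list[SpearmanResult] = field(default_factory=list)
    n_tests: int = 0

    def to_text(self) -> str:
        """Human-readable table: variable x timepoint rows; fused, unfused,
        OR [95% CI], p columns."""
        lines = [
            f"{'Variable':<18}{'Fused (median [min, max])':<30}"
            f"{'Unfused (median [min, max])':<30}{'OR [95% CI]':<24}{'p':<8}"
        ]
        logit_by_var = {r.predictor: r for r in self.logits}
        for key, row in self.descriptives.iterrows():
            fused = f"{row['fused_median']:.3g} [{row['fused_min']:.3g}, {row['fused_max']:.3g}]"
            unfused = f"{row['unfused_median']:.3g} [{row['unfused_min']:.3g}, {row['unfused_max']:.3g}]"
            lr = logit_by_var.get(key)
            if lr is None:
                or_s, p_s = "-", "-"
            elif lr.separation:
                or_s, p_s = "separation", "-"
            else:
                or_s = f"{lr.odds_ratio:.3g} [{lr.ci_low:.3g}, {lr.ci_high:.3g}]"
                p_s = f"{lr.p_value:.2g}"
            lines.append(f"{key:<18}{fused:<30}{unfused:<30}{or_s:<24}{p_s:<8}")
        lines.append("")
        lines.append("Spearman rank correlations (uptake vs 12-month change):")
        for s in self.spearman:
            lines.append(
                f"  {s.uptake_metric} vs d{s.change_variable}: "
                f"rho={s.rho:.3f}, p={s.p_value:.3g}, n={s.n}"
            )
        lines.append("")
        lines.append(f"{self.n_tests} univariate tests run; no multiplicity correction applied.")
        return "\n".join(lines)


def score_change(cohort: pd.DataFrame, variable: str) -> pd.Series:
    """12-month score minus baseline score; NaN where either is missing."""
    bs, yr = f"{variable}_bs", f"{variable}_12m"
    if bs not in cohort or yr not in cohort:
        raise KeyError(f"cohort lacks {bs}/{yr}")
    return cohort[yr] - cohort[bs]


def univariate_logit(cohort: pd.DataFrame, predictor: str,
                     outcome: str = "fused") -> LogitResult:
    """Fit fused ~ predictor by maximum likelihood; OR = exp(beta) with Wald CI.

    Records with a missing predictor or outcome are dropped from this test
    only.  Perfect separation is flagged rather than reported as a finite OR.
    """
    data = cohort[[outcome, predictor]].dropna()
    y = data[outcome].astype(float).to_numpy()
    x = data[predictor].astype(float).to_numpy()
    n = len(data)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class (n={n})")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 records per outcome class")

    # detect complete separation: predictor ranges of the classes do not overlap
    x0, x1 = x[y == 0], x[y == 1]
    if x0.max() < x1.min() or x1.max() < x0.min():
        return LogitResult(predictor, float("inf"), float("nan"), float("nan"),
                           float("nan"), n, separation=True)

    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return LogitResult(predictor, float("inf"), float("nan"), float("nan"),
                           float("nan"), n, separation=True)
    beta = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(se) or se > 1e4:
        return LogitResult(predictor, float("inf"), float("nan"), float("nan"),
                           float("nan"), n, separation=True)
    z = stats.norm.ppf(0.975)
    return LogitResult(
        predictor,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[1]),
        n=n,
    )


def spearman_uptake_vs_change(cohort: pd.DataFrame, uptake_metric: str,
                              change_variable: str) -> SpearmanResult:
    """Spearman rho (average-rank ties, two-sided p) of uptake vs score change."""
    delta = score_change(cohort, change_variable)
    pairs = pd.DataFrame({"u": cohort[uptake_metric], "d": delta}).dropna()
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(pairs)}")
    if pairs["u"].nunique() < 2 or pairs["d"].nunique() < 2:
        return SpearmanResult(uptake_metric, change_variable,
                              float("nan"), float("nan"), len(pairs))
    rho, p = stats.spearmanr(pairs["u"], pairs["d"])
    return SpearmanResult(uptake_metric, change_variable,
                          float(rho), float(p), len(pairs))


def _groups(cohort: pd.DataFrame, column: str):
    fused = cohort.loc[cohort["fused"].astype(bool), column].dropna()
    unfused = cohort.loc[~cohort["fused"].astype(bool), column].dropna()
    return fused, unfused


def describe(cohort: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Median [min, max] by fusion group for every variable and timepoint.

    Medians of even-sized samples are the mean of the two central order
    statistics.  Returns one row per column, indexed by column name.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in ("id", "group", "fused")
                     and pd.api.types.is_numeric_dtype(cohort[c])]
    rows = {}
    for col in variables:
        fused, unfused = _groups(cohort, col)
        rows[col] = {
            "fused_median": fused.median(), "fused_min": fused.min(),
            "fused_max": fused.max(), "fused_n": len(fused),
            "unfused_median": unfused.median(), "unfused_min": unfused.min(),
            "unfused_max": unfused.max(), "unfused_n": len(unfused),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_cohort_stats(cohort: pd.DataFrame) -> StatReport:
    """Full analysis: descriptives, per-variable logistic ORs, uptake-vs-change
    Spearman correlations."""
    change_cols = {}
    for var in SCORE_VARIABLES:
        if f"{var}_bs" in cohort and f"{var}_12m" in cohort:
            change_cols[f"{var}_change"] = score_change(cohort, var)
    work = pd.concat([cohort, pd.DataFrame(change_cols, index=cohort.index)], axis=1)

    predictors = [c for c in work.columns
                  if c not in ("id", "group", "fused")
                  and pd.api.types.is_numeric_dtype(work[c])]
    report = StatReport(descriptives=describe(work, predictors))
    n_tests = 0
    for pred in predictors:
        try:
            report.logits.append(univariate_logit(work, pred))
            n_tests += 1
        except ValueError:
            continue
    for metric in UPTAKE_VARIABLES:
        if metric not in work:
            continue
        for var in SCORE_VARIABLES:
            if f"{var}_bs" not in work or f"{var}_12m" not in work:
                continue
            try:
                report.spearman.append(spearman_uptake_vs_change(work, metric, var))
                n_tests += 1
            except ValueError:
                continue
    report.n_tests = n_tests
    return report
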