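"""Evaluation of flagging policies against inspection outcomes.

Inspections are labeled safe/unsafe from their grade and severity-coded
violation counts under a configurable mapping (default: unsafe iff the
grade is Fail or PassWithConditions, or there is at least one critical
violation). Group summaries tabulate unsafe percentages per trigger group
(FINDER / BASELINE / COMPLAINT / ROUTINE, where BASELINE is the union of
COMPLAINT and ROUTINE) overall and per risk level. Effects are estimated
as crude cross-product odds ratios, covariate-adjusted odds ratios from
binomial logistic regression with city and risk-level fixed effects,
adjusted mean violation counts from linear regression (marginal
standardization), Pearson chi-square tests on risk distributions, and
relative-risk ratios from baseline-category multinomial logistic
regression (reference grade Pass).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from foodwatch.exceptions import (
    DegenerateDataError,
    ParameterError,
    SeparationError,
)
from foodwatch.types import GRADES, RISK_LEVELS, InspectionRecord

Z975 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class OutcomeMapping:
    """Configurable safe/unsafe designation from grade and violations."""

    unsafe_grades: tuple[str, ...] = ("Fail", "PassWithConditions")
    critical_threshold: int | None = 1  # critical_count >= t -> unsafe
    major_threshold: int | None = None


@dataclass
class EffectEstimate:
    estimate: float  # OR, RRR, or adjusted mean difference
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    corrected: bool = False  # Haldane-Anscombe +0.5 applied

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p_value": self.p_value,
                "model": self.model, "corrected": self.corrected}


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Outcome labeling and tabulation
# ---------------------------------------------------------------------------

def label_outcome(record: InspectionRecord,
                  mapping: OutcomeMapping | None = None) -> str:
    """Deterministic safe/unsafe designation for one inspection."""
    m = mapping or OutcomeMapping()
    if record.grade not in GRADES:
        raise ParameterError(f"unknown grade {record.grade!r}")
    unsafe = record.grade in m.unsafe_grades
    if m.critical_threshold is not None:
        unsafe = unsafe or record.critical_count >= m.critical_threshold
    if m.major_threshold is not None:
        unsafe = unsafe or record.major_count >= m.major_threshold
    return "unsafe" if unsafe else "safe"


def inspections_frame(records: list[InspectionRecord],
                      mapping: OutcomeMapping | None = None) -> pd.DataFrame:
    """Inspection records as a DataFrame with a boolean ``unsafe`` column."""
    df = pd.DataFrame([{
        "restaurant_id": r.restaurant_id, "date": r.date, "group": r.group,
        "grade": r.grade, "critical_count": r.critical_count,
        "major_count": r.major_count, "city": r.city,
        "risk_level": r.risk_level,
    } for r in records])
    if not df.empty:
        df["unsafe"] = [label_outcome(r, mapping) == "unsafe" for r in records]
    return df


def summary_from_counts(counts: dict[str, dict[str, tuple[int, int]]],
                        ) -> pd.DataFrame:
    """Group summary from precomputed (n, n_unsafe) cells.

    ``counts`` maps group -> stratum -> (n, n_unsafe); stratum "overall"
    plus optional risk levels. Percentages are rounded half-up to one
    decimal, matching conventional tabular reporting.
    """
    rows = []
    for group in counts:
        for stratum, (n, n_unsafe) in counts[group].items():
            if n_unsafe > n:
                raise ParameterError(
                    f"{group}/{stratum}: n_unsafe {n_unsafe} exceeds n {n}")
            pct = round_half_up(100.0 * n_unsafe / n, 1) if n else float("nan")
            rows.append({"group": group, "stratum": stratum, "n": n,
                         "n_unsafe": n_unsafe, "pct_unsafe": pct})
    return pd.DataFrame(rows)


def contingency_summary(df: pd.DataFrame,
                        groups: tuple[str, ...] = ("FINDER", "BASELINE",
                                                   "COMPLAINT", "ROUTINE"),
                        ) -> pd.DataFrame:
    """Tabulate n / n_unsafe / pct_unsafe per group, overall and by risk
    level. BASELINE is synthesized as COMPLAINT + ROUTINE. Empty strata are
    omitted."""
    if df.empty:
        return pd.DataFrame(columns=["group", "stratum", "n", "n_unsafe",
                                     "pct_unsafe"])
    counts: dict[str, dict[str, tuple[int, int]]] = {}
    for group in groups:
        if group == "BASELINE":
            sub = df[df["group"].isin(("COMPLAINT", "ROUTINE"))]
        else:
            sub = df[df["group"] == group]
        if sub.empty:
            continue
        cells = {"overall": (len(sub), int(sub["unsafe"].sum()))}
        for risk in RISK_LEVELS:
            stratum = sub[sub["risk_level"] == risk]
            if len(stratum):
                cells[risk] = (len(stratum), int(stratum["unsafe"].sum()))
        counts[group] = cells
    return summary_from_counts(counts)


# ---------------------------------------------------------------------------
# Effect estimation
# ---------------------------------------------------------------------------

def crude_odds_ratio(a: int, b: int, c: int, d: int) -> EffectEstimate:
    """Cross-product odds ratio from a 2x2 table.

    Cells: a = exposed & event, b = exposed & no event, c = unexposed &
    event, d = unexposed & no event. Wald 95% CI on the log scale; the
    Haldane-Anscombe +0.5 correction is applied to every cell when any cell
    is zero (flagged in the output).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ParameterError("cells must be nonnegative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise DegenerateDataError(
            "odds ratio undefined: an entire margin of the 2x2 table is zero")
    corrected = 0 in cells
    aa, bb, cc, dd = ((x + 0.5 for x in cells) if corrected else cells)
    log_or = math.log(aa * dd / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return EffectEstimate(
        estimate=math.exp(log_or), ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se), p_value=float(p),
        model="crude 2x2 cross-product OR (Wald CI)", corrected=corrected)


def _dummy_design(df: pd.DataFrame, exposure: str,
                  covariates: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "exposure": df[exposure].astype(float)},
                     index=df.index)
    for cov in covariates:
        dummies = pd.get_dummies(df[cov].astype(str), prefix=cov,
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def _check_separation(df: pd.DataFrame, exposure: str, outcome: str,
                      covariates: tuple[str, ...]) -> None:
    """Reject data where an exposure arm has zero events or non-events
    (overall, or within a covariate stratum containing both arms)."""
    tab = pd.crosstab(df[exposure], df[outcome])
    if tab.shape != (2, 2) or (tab == 0).any().any():
        raise SeparationError(
            "logistic model not estimable: an exposure arm has zero events "
            "or zero non-events", stratum="overall")


def _find_sparse_stratum(df: pd.DataFrame, exposure: str, outcome: str,
                         covariates: tuple[str, ...]) -> str | None:
    """Name a covariate stratum with an empty exposure-outcome cell, if any
    (used to annotate separation/non-convergence errors)."""
    for cov in covariates:
        for level, sub in df.groupby(cov):
            t = pd.crosstab(sub[exposure], sub[outcome])
            if t.shape != (2, 2) or (t.to_numpy() == 0).any():
                return f"{cov}={level}"
    return None


def adjusted_odds_ratio(df: pd.DataFrame, exposure: str = "exposure",
                        outcome: str = "unsafe",
                        covariates: tuple[str, ...] = ("city", "risk_level"),
                        ) -> EffectEstimate:
    """Odds ratio for a binary exposure from maximum-likelihood binomial
    logistic regression with dummy-coded categorical fixed effects.

    ``df[exposure]`` must be binary (0/1 or bool); the returned estimate is
    the exponentiated exposure coefficient with its Wald 95% CI. Complete
    separation raises :class:`SeparationError` instead of silently
    returning a huge estimate.
    """
    work = df.copy()
    work[exposure] = work[exposure].astype(int)
    work[outcome] = work[outcome].astype(int)
    if set(work[exposure].unique()) - {0, 1}:
        raise ParameterError("exposure must be binary")
    if work[outcome].nunique() < 2:
        raise DegenerateDataError("outcome has a single observed level")
    _check_separation(work, exposure, outcome, covariates)
    X = _dummy_design(work, exposure, covariates)
    model = sm.Logit(work[outcome].to_numpy(), X.to_numpy())
    stratum = _find_sparse_stratum(work, exposure, outcome, covariates)
    try:
        with warnings.catch_warnings():
            # convergence is checked explicitly below
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparation and kin
        raise SeparationError(f"logistic fit failed: {exc}",
                              stratum=stratum) from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge",
                              stratum=stratum)
    j = list(X.columns).index("exposure")
    beta = float(res.params[j])
    se = float(res.bse[j])
    p = float(res.pvalues[j])
    return EffectEstimate(
        estimate=math.exp(beta), ci_low=math.exp(beta - Z975 * se),
        ci_high=math.exp(beta + Z975 * se), p_value=p,
        model=f"binomial logistic regression, covariates={list(covariates)}")


def adjusted_mean_violations(df: pd.DataFrame, severity: str = "critical",
                             group_col: str = "exposure",
                             covariates: tuple[str, ...] = ("city",
                                                            "risk_level"),
                             method: str = "marginal") -> dict:
    """Adjusted mean violation counts per exposure group from OLS with
    covariate fixed effects.

    ``method="marginal"`` (default) standardizes marginally: the adjusted
    mean for group g is the average model prediction over the pooled
    sample's covariate distribution with the group set counterfactually to
    g. ``method="at_means"`` evaluates the model at covariate means
    instead. Returns per-group adjusted means plus the two-sided p-value
    for the group coefficient.
    """
    if severity not in ("critical", "major"):
        raise ParameterError("severity must be 'critical' or 'major'")
    y = df[f"{severity}_count"].astype(float)
    work = df.copy()
    work[group_col] = work[group_col].astype(int)
    X = _dummy_design(work, group_col, covariates)
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("exposure")
    out_means = {}
    for g in (0, 1):
        Xg = X.copy()
        Xg["exposure"] = float(g)
        if method == "marginal":
            out_means[g] = float(res.predict(Xg.to_numpy()).mean())
        elif method == "at_means":
            out_means[g] = float(res.predict(
                Xg.to_numpy().mean(axis=0, keepdims=True))[0])
        else:
            raise ParameterError(f"unknown method {method!r}")
    return {
        "adjusted_mean_exposed": out_means[1],
        "adjusted_mean_unexposed": out_means[0],
        "difference": float(res.params[j]),
        "p_value": float(res.pvalues[j]),
        "model": f"OLS, covariates={list(covariates)}, method={method}",
    }


def risk_distribution_test(counts_a, counts_b) -> tuple[float, int, float]:
    """Pearson chi-square test comparing two groups' distributions over the
    three risk levels (2x3 table, df = 2)."""
    table = np.asarray([counts_a, counts_b], dtype=float)
    if table.shape != (2, 3) or (table < 0).any():
        raise ParameterError("expected two nonnegative count triples")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateDataError("chi-square undefined: zero row or column")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def multinomial_rrr(df: pd.DataFrame, exposure: str = "exposure",
                    outcome: str = "grade",
                    covariates: tuple[str, ...] = ("city", "risk_level"),
                    reference: str = "Pass") -> dict[str, EffectEstimate]:
    """Relative-risk ratios from a baseline-category multinomial logit.

    The outcome is the three-level inspection grade with ``reference`` as
    the baseline; the RRR for each non-reference grade is the exponentiated
    exposure coefficient in that grade's logit. Empty outcome levels raise
    :class:`DegenerateDataError`.
    """
    work = df.copy()
    work[exposure] = work[exposure].astype(int)
    observed = [g for g in GRADES if (work[outcome] == g).any()]
    if reference not in observed:
        raise DegenerateDataError(f"reference level {reference!r} not observed")
    if len(observed) < 2:
        raise DegenerateDataError("need at least two observed outcome levels")
    levels = [reference] + [g for g in observed if g != reference]
    codes = work[outcome].map({g: i for i, g in enumerate(levels)}).to_numpy()
    X = _dummy_design(work, exposure, covariates)
    model = sm.MNLogit(codes, X.to_numpy())
    res = model.fit(disp=0, maxiter=500, method="newton")
    j = list(X.columns).index("exposure")
    out = {}
    for k, grade in enumerate(levels[1:]):
        beta = float(res.params[j, k])
        se = float(res.bse[j, k])
        p = float(res.pvalues[j, k])
        out[grade] = EffectEstimate(
            estimate=math.exp(beta), ci_low=math.exp(beta - Z975 * se),
            ci_high=math.exp(beta + Z975 * se), p_value=p,
            model=f"multinomial logit vs {reference}, "
                  f"covariates={list(covariates)}")
    return out
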