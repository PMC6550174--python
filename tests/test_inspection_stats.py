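"""Outcome labeling, tabulation, and effect estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from foodwatch.exceptions import (
    DegenerateDataError,
    ParameterError,
    SeparationError,
)
from foodwatch.inspection_stats import (
    OutcomeMapping,
    adjusted_mean_violations,
    adjusted_odds_ratio,
    contingency_summary,
    crude_odds_ratio,
    inspections_frame,
    label_outcome,
    multinomial_rrr,
    risk_distribution_test,
    round_half_up,
    summary_from_counts,
)
from foodwatch.types import InspectionRecord


def _rec(grade="Pass", critical=0, major=0, group="ROUTINE", city="chicago",
         risk="high", rid="r0"):
    return InspectionRecord(restaurant_id=rid, date=1.0, group=group,
                            grade=grade, critical_count=critical,
                            major_count=major, city=city, risk_level=risk)


# ---------------------------------------------------------------------------
# Outcome labeling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("grade,critical,expected", [
    ("Fail", 0, "unsafe"),
    ("PassWithConditions", 0, "unsafe"),
    ("Pass", 0, "safe"),
    ("Pass", 1, "unsafe"),  # critical violation overrides a passing grade
])
def test_default_outcome_mapping(grade, critical, expected):
    assert label_outcome(_rec(grade=grade, critical=critical)) == expected


def test_outcome_mapping_is_configurable():
    strict = OutcomeMapping(unsafe_grades=("Fail",), critical_threshold=None,
                            major_threshold=3)
    assert label_outcome(_rec("PassWithConditions"), strict) == "safe"
    assert label_outcome(_rec("Pass", major=3), strict) == "unsafe"


def test_unknown_grade_rejected():
    with pytest.raises(ParameterError):
        label_outcome(_rec(grade="Incomplete"))


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def test_rounding_is_half_up():
    assert round_half_up(52.25, 1) == 52.3
    assert round_half_up(52.24999, 1) == 52.2
    assert round_half_up(39.35, 1) == 39.4
    assert round_half_up(39.3493, 1) == 39.3


def test_summary_counts_conserve_and_baseline_is_union():
    records = (
        [_rec(group="FINDER", grade="Fail", risk="high")] * 3
        + [_rec(group="FINDER", grade="Pass", risk="medium")] * 2
        + [_rec(group="COMPLAINT", grade="Fail", risk="high")] * 4
        + [_rec(group="ROUTINE", grade="Pass", risk="low")] * 6
    )
    df = inspections_frame(records)
    summary = contingency_summary(df)
    get = lambda g, s: summary[(summary.group == g)
                               & (summary.stratum == s)].iloc[0]
    assert get("FINDER", "overall").n == 5
    assert get("FINDER", "overall").n_unsafe == 3
    assert get("BASELINE", "overall").n == 10
    # strata sum to the group total
    fin = summary[(summary.group == "FINDER") & (summary.stratum != "overall")]
    assert fin.n.sum() == 5
    # empty strata omitted
    assert not ((summary.group == "FINDER")
                & (summary.stratum == "low")).any()


def test_summary_from_counts_validates():
    with pytest.raises(ParameterError):
        summary_from_counts({"G": {"overall": (5, 9)}})


# ---------------------------------------------------------------------------
# Crude odds ratio
# ---------------------------------------------------------------------------

def test_symmetric_table_gives_unit_or():
    est = crude_odds_ratio(10, 10, 10, 10)
    assert est.estimate == pytest.approx(1.0)
    assert est.ci_low < 1.0 < est.ci_high
    assert not est.corrected


def test_crude_or_matches_cross_product():
    est = crude_odds_ratio(69, 63, 2662, 8124)
    assert est.estimate == pytest.approx(69 * 8124 / (63 * 2662), rel=1e-12)
    assert est.estimate == pytest.approx(3.34, abs=0.005)


def test_crude_or_against_statsmodels():
    import statsmodels.api as sm
    a, b, c, d = 30, 70, 15, 85
    est = crude_odds_ratio(a, b, c, d)
    table = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
    assert est.estimate == pytest.approx(table.oddsratio)
    lo, hi = table.oddsratio_confint()
    assert est.ci_low == pytest.approx(lo) and est.ci_high == pytest.approx(hi)


def test_zero_cell_triggers_haldane_correction():
    est = crude_odds_ratio(5, 0, 3, 7)
    assert est.corrected
    assert est.estimate == pytest.approx(5.5 * 7.5 / (0.5 * 3.5))


def test_zero_margin_rejected():
    with pytest.raises(DegenerateDataError):
        crude_odds_ratio(0, 0, 3, 7)


def test_ci_brackets_estimate():
    est = crude_odds_ratio(20, 5, 10, 30)
    assert est.ci_low <= est.estimate <= est.ci_high
    # Wald CI is symmetric on the log scale
    assert math.log(est.estimate) - math.log(est.ci_low) == pytest.approx(
        math.log(est.ci_high) - math.log(est.estimate))


# ---------------------------------------------------------------------------
# Adjusted odds ratio
# ---------------------------------------------------------------------------

def _or_frame(a, b, c, d, city="chicago", risk="high"):
    rows = ([{"exposure": 1, "unsafe": 1}] * a
            + [{"exposure": 1, "unsafe": 0}] * b
            + [{"exposure": 0, "unsafe": 1}] * c
            + [{"exposure": 0, "unsafe": 0}] * d)
    df = pd.DataFrame(rows)
    df["city"] = city
    df["risk_level"] = risk
    return df


def test_adjusted_or_equals_crude_with_constant_covariates():
    a, b, c, d = 40, 60, 25, 175
    est = adjusted_odds_ratio(_or_frame(a, b, c, d), covariates=())
    crude = crude_odds_ratio(a, b, c, d)
    assert est.estimate == pytest.approx(crude.estimate, rel=1e-4)
    assert est.ci_low == pytest.approx(crude.ci_low, rel=1e-3)
    assert est.ci_high == pytest.approx(crude.ci_high, rel=1e-3)


def test_zero_event_arm_raises_separation_error():
    df = _or_frame(0, 50, 25, 175)
    with pytest.raises(SeparationError):
        adjusted_odds_ratio(df, covariates=())


def test_nonbinary_exposure_rejected():
    df = _or_frame(5, 5, 5, 5)
    df.loc[0, "exposure"] = 2
    with pytest.raises(ParameterError):
        adjusted_odds_ratio(df, covariates=())


# ---------------------------------------------------------------------------
# Adjusted mean violations
# ---------------------------------------------------------------------------

def _violation_frame(rng, n=400, balanced=True):
    exposure = rng.integers(0, 2, n)
    if balanced:
        city = rng.choice(["a", "b"], n)
        risk = rng.choice(["high", "medium", "low"], n)
    else:
        city = np.where(exposure == 1, "a", rng.choice(["a", "b"], n))
        risk = rng.choice(["high", "medium", "low"], n)
    counts = rng.poisson(0.5 + 0.4 * exposure + 0.2 * (city == "a"))
    return pd.DataFrame({"exposure": exposure, "city": city,
                         "risk_level": risk, "critical_count": counts,
                         "major_count": counts})


def test_no_covariates_equals_raw_group_means():
    rng = np.random.default_rng(0)
    df = _violation_frame(rng)
    out = adjusted_mean_violations(df, "critical", covariates=())
    raw = df.groupby("exposure")["critical_count"].mean()
    assert out["adjusted_mean_exposed"] == pytest.approx(raw[1])
    assert out["adjusted_mean_unexposed"] == pytest.approx(raw[0])


def test_balanced_covariates_reproduce_raw_means():
    # covariate distribution identical across groups by construction
    df = pd.concat([
        pd.DataFrame({"exposure": e, "city": c, "risk_level": r,
                      "critical_count": k, "major_count": 0}, index=[0])
        for e in (0, 1) for c in ("a", "b")
        for r in ("high", "low") for k in (0, 1, 2)
    ], ignore_index=True)
    df.loc[(df.exposure == 1), "critical_count"] += 1  # pure group effect
    out = adjusted_mean_violations(df, "critical")
    raw = df.groupby("exposure")["critical_count"].mean()
    assert out["adjusted_mean_exposed"] == pytest.approx(raw[1], abs=1e-9)
    assert out["adjusted_mean_unexposed"] == pytest.approx(raw[0], abs=1e-9)


def test_predictions_average_to_overall_mean():
    # OLS identity: fitted values under observed assignment average to the
    # sample mean; marginal means weighted by group shares reproduce it
    rng = np.random.default_rng(1)
    df = _violation_frame(rng, balanced=False)
    out = adjusted_mean_violations(df, "critical")
    share = df["exposure"].mean()
    blended = (share * out["adjusted_mean_exposed"]
               + (1 - share) * out["adjusted_mean_unexposed"])
    # holds exactly when the model contains the group main effect
    assert blended == pytest.approx(df["critical_count"].mean(), abs=1e-9)


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def test_proportional_distributions_give_zero_statistic():
    stat, dof, p = risk_distribution_test((10, 20, 30), (100, 200, 300))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert dof == 2 and p == pytest.approx(1.0)


def test_hand_computed_chi_square():
    a, b = (30, 10, 10), (20, 20, 10)
    stat, dof, p = risk_distribution_test(a, b)
    table = np.array([a, b], dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    by_hand = ((table - expected) ** 2 / expected).sum()
    assert stat == pytest.approx(by_hand)


def test_zero_column_rejected():
    with pytest.raises(DegenerateDataError):
        risk_distribution_test((0, 10, 10), (0, 20, 10))


# ---------------------------------------------------------------------------
# Multinomial RRR
# ---------------------------------------------------------------------------

def _grade_frame(counts):
    """counts: {exposure: {grade: n}} -> long frame."""
    rows = []
    for e, per_grade in counts.items():
        for grade, n in per_grade.items():
            rows += [{"exposure": e, "grade": grade}] * n
    df = pd.DataFrame(rows)
    df["city"] = "chicago"
    df["risk_level"] = "high"
    return df


def test_saturated_rrr_equals_count_ratio_of_ratios():
    counts = {0: {"Pass": 50, "PassWithConditions": 20, "Fail": 10},
              1: {"Pass": 30, "PassWithConditions": 25, "Fail": 15}}
    out = multinomial_rrr(_grade_frame(counts), covariates=())
    rrr_pwc = (25 / 30) / (20 / 50)
    rrr_fail = (15 / 30) / (10 / 50)
    assert out["PassWithConditions"].estimate == pytest.approx(rrr_pwc,
                                                               rel=1e-4)
    assert out["Fail"].estimate == pytest.approx(rrr_fail, rel=1e-4)
    for est in out.values():
        assert est.ci_low <= est.estimate <= est.ci_high


def test_collapsed_multinomial_matches_binary_logit():
    counts = {0: {"Pass": 60, "PassWithConditions": 25, "Fail": 15},
              1: {"Pass": 35, "PassWithConditions": 30, "Fail": 20}}
    df = _grade_frame(counts)
    collapsed = df.assign(unsafe=(df.grade != "Pass").astype(int))
    binary = adjusted_odds_ratio(collapsed, covariates=())
    two_level = df.assign(
        grade=np.where(df.grade == "Pass", "Pass", "Fail"))
    rrr = multinomial_rrr(two_level, covariates=())["Fail"]
    assert rrr.estimate == pytest.approx(binary.estimate, rel=1e-4)
    assert rrr.p_value == pytest.approx(binary.p_value, rel=1e-3, abs=1e-6)


def test_missing_outcome_level_rejected():
    counts = {0: {"PassWithConditions": 20}, 1: {"PassWithConditions": 25}}
    with pytest.raises(DegenerateDataError):
        multinomial_rrr(_grade_frame(counts), covariates=())
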