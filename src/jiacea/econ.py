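"""Incremental cost-utility and cost-benefit analysis.

Compares the two time-to-diagnosis groups (< 6 months vs 6+ months from
actively seeking treatment) on annual and lifetime present-valued outcomes:

* group mean differences with Welch (unequal-variance) t confidence
  intervals and p-values, unadjusted and adjusted for age (spline), gender
  and their interaction;
* net monetary benefit per child, NMB_i = lambda x pv_qalys_i - pv_costs_i at a
  willingness-to-pay lambda per QALY, whose group difference satisfies
  dNMB = lambda x dQALY + dCostSavings exactly;
* a bootstrap cost-effectiveness plane;
* one-way sensitivity scenarios (discount rate, lambda, exclusion of
  recently diagnosed participants); and
* a population budget-impact calculation.

Sign convention (documented per outcome): QALY gains are reported as
positive for the < 6 months group (lt6 - ge6), cost *savings* likewise
positive for the < 6 months group (ge6 - lt6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chu9d import Chu9dValueSet, score_cohort
from .costing import UnitCostSchedule, cost_cohort
from .lifetime import EconParams, LifeTable, present_value_cohort


class GroupSizeError(ValueError):
    """Too few non-missing values in a group for the requested statistic."""


@dataclass(frozen=True)
class IncrementalResult:
    """Between-group mean difference with Welch 95% CI and p-value."""

    outcome: str
    mean_lt6: float
    mean_ge6: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_lt6: int
    n_ge6: int
    convention: str = "lt6_minus_ge6"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.difference + 1e-12 and self.difference <= self.ci_high + 1e-12):
            raise ValueError("difference must lie within its CI")

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "mean_lt6": self.mean_lt6,
            "mean_ge6": self.mean_ge6,
            "difference": self.difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_lt6": self.n_lt6,
            "n_ge6": self.n_ge6,
            "convention": self.convention,
        }


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> dict[str, float]:
    """Welch two-sample t-test from summary statistics (mean, SD, n).

    Returns the difference (1 minus 2), Welch degrees of freedom, t, the
    95% CI and the two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise GroupSizeError("need n >= 2 per group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = float(np.sqrt(v1 + v2))
    diff = mean1 - mean2
    if se == 0:  # both groups constant: the difference is exact
        return {
            "difference": diff,
            "se": 0.0,
            "df": float(n1 + n2 - 2),
            "t": np.inf * np.sign(diff) if diff else 0.0,
            "ci_low": diff,
            "ci_high": diff,
            "p_value": 1.0 if diff == 0 else 0.0,
        }
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = diff / se
    tcrit = stats.t.ppf(0.975, df)
    p = 2 * stats.t.sf(abs(t), df)
    return {
        "difference": diff,
        "se": se,
        "df": df,
        "t": t,
        "ci_low": diff - tcrit * se,
        "ci_high": diff + tcrit * se,
        "p_value": float(p),
    }


def incremental_mean(
    values_lt6: np.ndarray | pd.Series,
    values_ge6: np.ndarray | pd.Series,
    outcome: str = "outcome",
    convention: str = "lt6_minus_ge6",
) -> IncrementalResult:
    """Welch mean difference between groups for any per-participant outcome.

    ``convention`` controls the sign of the reported difference:
    ``"lt6_minus_ge6"`` for outcomes where more is better for the early
    group (utility, QALYs), ``"ge6_minus_lt6"`` for cost savings.
    """
    a = np.asarray(values_lt6, dtype=float)
    b = np.asarray(values_ge6, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise GroupSizeError(
            f"need >= 2 non-missing values per group, got {len(a)} and {len(b)}"
        )
    if convention == "lt6_minus_ge6":
        w = welch_from_summary(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
    elif convention == "ge6_minus_lt6":
        w = welch_from_summary(b.mean(), b.std(ddof=1), len(b), a.mean(), a.std(ddof=1), len(a))
    else:
        raise ValueError(f"unknown sign convention {convention!r}")
    return IncrementalResult(
        outcome=outcome,
        mean_lt6=float(a.mean()),
        mean_ge6=float(b.mean()),
        difference=w["difference"],
        ci_low=w["ci_low"],
        ci_high=w["ci_high"],
        p_value=w["p_value"],
        n_lt6=len(a),
        n_ge6=len(b),
        convention=convention,
    )


DEFAULT_ADJUSTMENT_TERMS: tuple[str, ...] = (
    "bs(age_survey, df=4)",
    "C(sex)",
    "bs(age_survey, df=4):C(sex)",
)


def adjusted_difference(
    cohort: pd.DataFrame,
    outcome: pd.Series | str,
    covariates: Sequence[str] = DEFAULT_ADJUSTMENT_TERMS,
    group_col: str = "delay_group",
    convention: str = "lt6_minus_ge6",
) -> IncrementalResult:
    """Covariate-adjusted group difference from a linear model.

    Regresses the outcome on the group indicator plus flexible covariate
    terms (by default a B-spline in age at survey, gender, and their
    interaction — a spline approximation to a generalized additive model).
    The group coefficient is reported with its Wald 95% CI and p-value.
    """
    import statsmodels.formula.api as smf
    from numpy.linalg import matrix_rank

    df = cohort.copy()
    if isinstance(outcome, str):
        df["_y"] = df[outcome]
    else:
        df["_y"] = np.asarray(outcome, dtype=float)
    df["_grp"] = (df[group_col] == "lt6").astype(float)
    df = df.dropna(subset=["_y"])
    terms = " + ".join(["_grp", *covariates]) if covariates else "_grp"
    formula = f"_y ~ {terms}"
    model = smf.ols(formula, data=df)
    X = model.exog
    if matrix_rank(X) < X.shape[1]:
        names = model.exog_names
        # identify columns not adding rank, in order
        bad, kept = [], []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if X.shape[0] < X.shape[1] + 2:
        raise GroupSizeError("too few participants for the requested adjustment")
    fit = model.fit()
    coef = float(fit.params["_grp"])
    ci = fit.conf_int().loc["_grp"]
    p = float(fit.pvalues["_grp"])
    sign = 1.0 if convention == "lt6_minus_ge6" else -1.0
    lo, hi = sorted((sign * float(ci[0]), sign * float(ci[1])))
    a = df.loc[df["_grp"] == 1, "_y"]
    b = df.loc[df["_grp"] == 0, "_y"]
    return IncrementalResult(
        outcome=f"adjusted {outcome if isinstance(outcome, str) else '_y'}",
        mean_lt6=float(a.mean()),
        mean_ge6=float(b.mean()),
        difference=sign * coef,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_lt6=int(len(a)),
        n_ge6=int(len(b)),
        convention=convention,
    )


def lr_test(
    cohort: pd.DataFrame,
    outcome: str,
    base_terms: Sequence[str],
    extra_terms: Sequence[str],
    group_col: str = "delay_group",
) -> dict[str, float]:
    """Likelihood-ratio test that ``extra_terms`` improve on the base model."""
    import statsmodels.formula.api as smf

    df = cohort.copy()
    df["_grp"] = (df[group_col] == "lt6").astype(float)
    df = df.dropna(subset=[outcome])
    rhs0 = " + ".join(["_grp", *base_terms])
    rhs1 = " + ".join(["_grp", *base_terms, *extra_terms])
    f0 = smf.ols(f"{outcome} ~ {rhs0}", data=df).fit()
    f1 = smf.ols(f"{outcome} ~ {rhs1}", data=df).fit()
    lr = 2 * (f1.llf - f0.llf)
    dof = f1.df_model - f0.df_model
    return {
        "lr_stat": float(lr),
        "df": float(dof),
        "p_value": float(stats.chi2.sf(lr, dof)) if dof > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# Net monetary benefit


def incremental_nmb(
    pv: pd.DataFrame,
    wtp: float,
    aud_usd_rate: float = 1.51,
    group_col: str = "delay_group",
) -> dict:
    """Incremental net monetary benefit of early diagnosis, AUD and USD.

    ``pv`` needs per-participant ``pv_qalys`` and ``pv_costs`` columns and a
    group column.  Per participant NMB_i = wtp x pv_qalys_i - pv_costs_i; the
    group difference (lt6 - ge6, i.e. the benefit of diagnosis within six
    months) is a Welch comparison.  Satisfies exactly
    dNMB = wtp x dQALY + dCostSavings, with dCostSavings = ge6 - lt6.
    """
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    ok = pv.dropna(subset=["pv_qalys", "pv_costs"])
    nmb_i = wtp * ok["pv_qalys"] - ok["pv_costs"]
    grp = ok[group_col]
    res_aud = incremental_mean(
        nmb_i[grp == "lt6"], nmb_i[grp == "ge6plus"], outcome="nmb_aud"
    )
    qaly = incremental_mean(
        ok.loc[grp == "lt6", "pv_qalys"],
        ok.loc[grp == "ge6plus", "pv_qalys"],
        outcome="pv_qalys",
    )
    savings = incremental_mean(
        ok.loc[grp == "lt6", "pv_costs"],
        ok.loc[grp == "ge6plus", "pv_costs"],
        outcome="pv_cost_savings",
        convention="ge6_minus_lt6",
    )
    usd = {
        "difference": res_aud.difference / aud_usd_rate,
        "ci_low": res_aud.ci_low / aud_usd_rate,
        "ci_high": res_aud.ci_high / aud_usd_rate,
    }
    return {
        "nmb_aud": res_aud,
        "nmb_usd": usd,
        "pv_qalys": qaly,
        "pv_cost_savings": savings,
        "wtp": wtp,
        "aud_usd_rate": aud_usd_rate,
    }


# ---------------------------------------------------------------------------
# Full-cohort evaluation (score -> cost -> project -> compare)


def evaluate_cohort(
    cohort: pd.DataFrame,
    value_set: Chu9dValueSet,
    schedule: UnitCostSchedule,
    life_table: LifeTable,
    params: EconParams,
) -> dict:
    """Run the full evaluation pipeline on a cohort table.

    Scores CHU9D utilities, costs utilization, present-values both over
    remaining life expectancy, and returns annual and lifetime incremental
    results plus the NMB block.  Participants without a complete CHU9D are
    excluded from utility/QALY/NMB outcomes (no imputation).
    """
    utility = score_cohort(cohort, value_set)
    costs = cost_cohort(cohort, schedule)
    annual_cost = costs["total_cost"]
    pv = present_value_cohort(cohort, utility, annual_cost, life_table, params)
    pv = pv.assign(delay_group=cohort["delay_group"].to_numpy())
    grp = cohort["delay_group"]
    out = {
        "params": params,
        "n": int(len(cohort)),
        "n_complete": int(utility.notna().sum()),
        "utility": incremental_mean(
            utility[grp == "lt6"], utility[grp == "ge6plus"], outcome="utility"
        ),
        "annual_cost_savings": incremental_mean(
            annual_cost[grp == "lt6"],
            annual_cost[grp == "ge6plus"],
            outcome="annual_cost_savings",
            convention="ge6_minus_lt6",
        ),
        "pv": pv,
        "annual_costs": costs,
    }
    out.update(incremental_nmb(pv, params.wtp_per_qaly, params.aud_usd_rate))
    return out


# ---------------------------------------------------------------------------
# CEA plane


def cea_plane(
    pv: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    group_col: str = "delay_group",
) -> dict:
    """Bootstrap cost-effectiveness plane for early diagnosis.

    Nonparametric bootstrap over participants within each group; each
    replicate yields (dQALY, dCost) with both differences lt6 - ge6, so
    negative dCost means the early group saves money.  Returns the point
    cloud, the analytic point estimate and quadrant fractions.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ok = pv.dropna(subset=["pv_qalys", "pv_costs"])
    a = ok[ok[group_col] == "lt6"][["pv_qalys", "pv_costs"]].to_numpy()
    b = ok[ok[group_col] == "ge6plus"][["pv_qalys", "pv_costs"]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise GroupSizeError("bootstrap needs >= 2 participants per group")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    da = a[ia].mean(axis=1)  # (n_boot, 2)
    db = b[ib].mean(axis=1)
    pts = da - db
    points = pd.DataFrame(pts, columns=["d_qalys", "d_costs"])
    point_estimate = {
        "d_qalys": float(a[:, 0].mean() - b[:, 0].mean()),
        "d_costs": float(a[:, 1].mean() - b[:, 1].mean()),
    }
    q = {
        "qaly_gain_cost_saving": float(
            np.mean((points.d_qalys > 0) & (points.d_costs < 0))
        ),
        "qaly_gain_cost_incurring": float(
            np.mean((points.d_qalys > 0) & (points.d_costs >= 0))
        ),
        "qaly_loss_cost_saving": float(
            np.mean((points.d_qalys <= 0) & (points.d_costs < 0))
        ),
        "qaly_loss_cost_incurring": float(
            np.mean((points.d_qalys <= 0) & (points.d_costs >= 0))
        ),
    }
    return {"points": points, "point_estimate": point_estimate, "quadrants": q}


# ---------------------------------------------------------------------------
# One-way sensitivity


@dataclass(frozen=True)
class SensitivityScenario:
    """A single-parameter deviation from the base case.

    ``overrides`` are EconParams field overrides; ``exclude_within_years``
    drops participants surveyed within that many years of diagnosis.
    """

    label: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    exclude_within_years: float | None = None

    def __post_init__(self) -> None:
        valid = set(EconParams.__dataclass_fields__)
        bad = set(self.overrides) - valid
        if bad:
            raise ValueError(f"scenario {self.label!r} overrides unknown parameters {sorted(bad)}")


def default_scenarios(base: EconParams) -> list[SensitivityScenario]:
    """The pre-specified one-way scenarios: discount 3%/7%, willingness to
    pay 30K/70K, and exclusion of participants surveyed within one year of
    diagnosis."""
    return [
        SensitivityScenario("base case"),
        SensitivityScenario("discount rate 3%", {"discount_rate": 0.03}),
        SensitivityScenario("discount rate 7%", {"discount_rate": 0.07}),
        SensitivityScenario("WTP $30K per QALY", {"wtp_per_qaly": 30_000.0}),
        SensitivityScenario("WTP $70K per QALY", {"wtp_per_qaly": 70_000.0}),
        SensitivityScenario(
            "exclude surveyed < 1y post diagnosis",
            exclude_within_years=base.exclusion_window,
        ),
    ]


def one_way_sensitivity(
    cohort: pd.DataFrame,
    value_set: Chu9dValueSet,
    schedule: UnitCostSchedule,
    life_table: LifeTable,
    base_params: EconParams,
    scenarios: Sequence[SensitivityScenario] | None = None,
) -> pd.DataFrame:
    """Recompute the full pipeline under each scenario.

    Returns one row per scenario with the incremental NMB (AUD), its 95% CI,
    dQALY, dCostSavings and the n analysed.
    """
    if scenarios is None:
        scenarios = default_scenarios(base_params)
    rows = []
    for sc in scenarios:
        params = base_params.override(**dict(sc.overrides))
        sub = cohort
        if sc.exclude_within_years is not None:
            gap = cohort["age_survey"] - cohort["age_diagnosis"]
            sub = cohort[gap >= sc.exclude_within_years]
        res = evaluate_cohort(sub, value_set, schedule, life_table, params)
        nmb: IncrementalResult = res["nmb_aud"]
        rows.append(
            {
                "scenario": sc.label,
                "nmb_aud": nmb.difference,
                "ci_low": nmb.ci_low,
                "ci_high": nmb.ci_high,
                "p_value": nmb.p_value,
                "d_qalys": res["pv_qalys"].difference,
                "d_cost_savings": res["pv_cost_savings"].difference,
                "n": res["n"],
                "n_complete": res["n_complete"],
            }
        )
    return pd.DataFrame(rows).set_index("scenario")


# ---------------------------------------------------------------------------
# Budget impact


@dataclass(frozen=True)
class BudgetInputs:
    """Population inputs for the national budget-impact calculation.

    ``incident_children`` may be given directly (e.g. a published count);
    otherwise it is computed as population x incidence / 100,000.
    """

    population_under16: float = 5_100_000.0
    annual_incidence_per_100k: float = 7.0
    prop_delayed: float = 61 / 163
    nmb_per_child: float = 349_520.0
    incident_children: float | None = None

    def __post_init__(self) -> None:
        if min(self.population_under16, self.annual_incidence_per_100k, self.nmb_per_child) < 0:
            raise ValueError("budget inputs must be >= 0")
        if not (0 <= self.prop_delayed <= 1):
            raise ValueError("prop_delayed must be in [0, 1]")


def budget_impact(inputs: BudgetInputs) -> dict[str, float]:
    """Total annual benefit forgone from delayed diagnosis.

    incident = population x incidence/100,000 (or the supplied count);
    affected = round(incident x prop_delayed);
    total = affected x NMB per child.
    """
    incident = (
        inputs.incident_children
        if inputs.incident_children is not None
        else inputs.population_under16 * inputs.annual_incidence_per_100k / 100_000.0
    )
    affected = round(incident * inputs.prop_delayed)
    return {
        "incident_children": float(incident),
        "affected_children": float(affected),
        "total_benefit_forgone": float(affected * inputs.nmb_per_child),
    }
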