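"""Incremental comparisons, NMB identities, CEA plane, sensitivity, budget."""

import numpy as np
import pandas as pd
import pytest

import jiacea as j
from jiacea.econ import (
    BudgetInputs,
    GroupSizeError,
    SensitivityScenario,
    adjusted_difference,
    budget_impact,
    cea_plane,
    default_scenarios,
    evaluate_cohort,
    incremental_mean,
    incremental_nmb,
    one_way_sensitivity,
    welch_from_summary,
)
from jiacea.lifetime import EconParams


def _welch_oracle(a, b):
    """From-scratch Welch formulas (kept independent of the implementation)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    diff = a.mean() - b.mean()
    tcrit = tdist.ppf(0.975, df)
    p = 2 * tdist.sf(abs(diff / se), df)
    return diff, diff - tcrit * se, diff + tcrit * se, p


def test_incremental_mean_matches_welch_formula_oracle():
    a, b = [1.0, 2.0, 3.5], [2.0, 4.0, 9.0]
    res = incremental_mean(a, b)
    diff, lo, hi, p = _welch_oracle(a, b)
    assert res.difference == pytest.approx(diff, abs=1e-9)
    assert res.ci_low == pytest.approx(lo, abs=1e-9)
    assert res.ci_high == pytest.approx(hi, abs=1e-9)
    assert res.p_value == pytest.approx(p, abs=1e-9)


def test_incremental_mean_trivia_and_errors():
    same = np.array([3.0, 4.0, 5.0])
    res = incremental_mean(same, same)
    assert res.difference == 0.0 and res.p_value == pytest.approx(1.0)
    with pytest.raises(GroupSizeError):
        incremental_mean([1.0], [1.0, 2.0])
    # cost-savings sign convention: positive when the delayed group costs more
    sav = incremental_mean([1.0, 2.0], [5.0, 6.0], convention="ge6_minus_lt6")
    assert sav.difference == pytest.approx(4.0)


def test_annual_cost_difference_from_printed_group_summaries():
    w = welch_from_summary(29_494, 37_034, 61, 18_765, 16_416, 102)
    assert w["difference"] == pytest.approx(10_729)
    assert w["p_value"] < 0.05


def test_nmb_identity_holds_exactly_on_random_cohorts():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = rng.integers(10, 80)
        pv = pd.DataFrame(
            {
                "pv_qalys": rng.normal(10, 3, n),
                "pv_costs": rng.normal(3e5, 1e5, n),
                "delay_group": rng.choice(["lt6", "ge6plus"], n, p=[0.6, 0.4]),
            }
        )
        if (pv.delay_group == "lt6").sum() < 2 or (pv.delay_group == "ge6plus").sum() < 2:
            continue
        wtp = float(rng.uniform(0, 1e5))
        res = incremental_nmb(pv, wtp)
        lhs = res["nmb_aud"].difference
        rhs = wtp * res["pv_qalys"].difference + res["pv_cost_savings"].difference
        assert lhs == pytest.approx(rhs, abs=1e-9 * max(abs(lhs), 1.0))
        # zero willingness to pay: NMB reduces to the cost savings alone
        zero = incremental_nmb(pv, 0.0)
        assert zero["nmb_aud"].difference == pytest.approx(
            zero["pv_cost_savings"].difference, abs=1e-9
        )
    with pytest.raises(ValueError):
        incremental_nmb(pv, -1.0)


def test_usd_conversion_of_printed_net_benefit():
    # delta NMB constructed to equal the printed AUD net benefit exactly
    pv = pd.DataFrame(
        {
            "pv_qalys": [2.82, 2.82, 0.0, 0.0],
            "pv_costs": [0.0, 0.0, 208_520.0, 208_520.0],
            "delay_group": ["lt6", "lt6", "ge6plus", "ge6plus"],
        }
    )
    res = incremental_nmb(pv, 50_000.0, aud_usd_rate=1.51)
    assert res["nmb_aud"].difference == pytest.approx(349_520.0)
    assert round(res["nmb_usd"]["difference"]) == 231_470


def test_budget_impact_examples():
    out = budget_impact(
        BudgetInputs(incident_children=358, prop_delayed=61 / 163, nmb_per_child=349_520)
    )
    assert out["affected_children"] == 134
    assert round(out["total_benefit_forgone"] / 1e6) == 47
    # the incidence formula itself gives 357 incident children
    formula = budget_impact(BudgetInputs())
    assert formula["incident_children"] == pytest.approx(357.0)
    zero = budget_impact(BudgetInputs(prop_delayed=0.0))
    assert zero["affected_children"] == 0 and zero["total_benefit_forgone"] == 0
    with pytest.raises(ValueError):
        BudgetInputs(prop_delayed=1.5)


def _pv_frame(qa, ca, qb, cb, n=4):
    return pd.DataFrame(
        {
            "pv_qalys": [qa] * n + [qb] * n,
            "pv_costs": [ca] * n + [cb] * n,
            "delay_group": ["lt6"] * n + ["ge6plus"] * n,
        }
    )


def test_cea_plane_degenerate_and_point_estimate():
    # within-group-constant cohort: every resample reproduces the point estimate
    pv = _pv_frame(12.0, 1e5, 9.0, 3e5)
    out = cea_plane(pv, n_boot=50, seed=1)
    assert np.allclose(out["points"]["d_qalys"], 3.0)
    assert np.allclose(out["points"]["d_costs"], -2e5)
    assert out["point_estimate"] == {"d_qalys": 3.0, "d_costs": -2e5}
    assert out["quadrants"]["qaly_gain_cost_saving"] == 1.0
    # identical groups: cloud centred at the origin
    null = cea_plane(_pv_frame(10.0, 2e5, 10.0, 2e5), n_boot=20, seed=2)
    assert np.allclose(null["points"], 0.0)
    with pytest.raises(GroupSizeError):
        cea_plane(_pv_frame(1, 1, 1, 1, n=1), n_boot=10, seed=0)


def test_cea_plane_bootstrap_statistics(big_cohort, value_set, schedule, life_table):
    res = evaluate_cohort(big_cohort, value_set, schedule, life_table, EconParams())
    out = cea_plane(res["pv"], n_boot=400, seed=9)
    # point estimate equals the analytic incremental means
    assert out["point_estimate"]["d_qalys"] == pytest.approx(res["pv_qalys"].difference)
    assert out["point_estimate"]["d_costs"] == pytest.approx(
        -res["pv_cost_savings"].difference
    )
    # both printed 95% CIs exclude zero, so the cloud concentrates in the
    # QALY-gaining, cost-saving quadrant
    assert out["quadrants"]["qaly_gain_cost_saving"] >= 0.95


def test_one_way_sensitivity(big_cohort, value_set, schedule, life_table):
    base = EconParams()
    table = one_way_sensitivity(big_cohort, value_set, schedule, life_table, base)
    res = evaluate_cohort(big_cohort, value_set, schedule, life_table, base)
    # the base scenario reproduces the base NMB exactly
    assert table.loc["base case", "nmb_aud"] == pytest.approx(
        res["nmb_aud"].difference, abs=1e-9
    )
    # NMB is linear in the willingness to pay: 70K vs 30K differ by 40K x dQALY
    gap = table.loc["WTP $70K per QALY", "nmb_aud"] - table.loc["WTP $30K per QALY", "nmb_aud"]
    assert gap == pytest.approx(40_000 * res["pv_qalys"].difference, rel=1e-9)
    # monotone decreasing in the discount rate
    assert (
        table.loc["discount rate 3%", "nmb_aud"]
        > table.loc["base case", "nmb_aud"]
        > table.loc["discount rate 7%", "nmb_aud"]
    )
    # the exclusion scenario drops exactly the recently surveyed participants
    gapyears = big_cohort["age_survey"] - big_cohort["age_diagnosis"]
    assert table.loc["exclude surveyed < 1y post diagnosis", "n"] == int(
        (gapyears >= 1.0).sum()
    )
    with pytest.raises(ValueError, match="unknown parameters"):
        SensitivityScenario("bad", {"inflation": 0.02})


def test_adjusted_difference_recovers_truth_under_null_covariates():
    rng = np.random.default_rng(21)
    n = 4000
    grp = rng.random(n) < 0.5
    cohort = pd.DataFrame(
        {
            "delay_group": np.where(grp, "lt6", "ge6plus"),
            "age_survey": rng.uniform(2, 25, n),
            "sex": rng.choice(["female", "male"], n),
        }
    )
    y = 0.15 * grp + rng.normal(0, 0.29, n)  # covariates carry no true effect
    adj = adjusted_difference(cohort, pd.Series(y))
    una = incremental_mean(y[grp], y[~grp])
    se = (una.ci_high - una.ci_low) / (2 * 1.96)
    assert abs(adj.difference - una.difference) < 0.5 * se
    assert abs(adj.difference - 0.15) < 3 * se
    # pure-noise outcome: no group effect detected
    noise = adjusted_difference(cohort, pd.Series(rng.normal(0, 1, n)))
    assert abs(noise.difference) < 3 * (noise.ci_high - noise.ci_low) / (2 * 1.96)


def test_adjusted_difference_reports_collinear_columns():
    rng = np.random.default_rng(3)
    n = 60
    cohort = pd.DataFrame(
        {
            "delay_group": np.where(rng.random(n) < 0.5, "lt6", "ge6plus"),
            "age_survey": rng.uniform(2, 25, n),
            "dup": 0.0,
            "sex": "female",
        }
    )
    cohort["dup"] = cohort["age_survey"] * 2
    with pytest.raises(ValueError, match="collinear"):
        adjusted_difference(
            cohort, pd.Series(rng.normal(size=n)), covariates=("age_survey", "dup")
        )


def test_adjusted_utility_difference_on_calibrated_cohort(
    big_cohort, value_set, schedule, life_table
):
    """The adjusted group utility difference recovers the generator's 0.15
    truth (the survey's adjusted estimate was 0.14)."""
    utility = j.score_cohort(big_cohort, value_set)
    adj = adjusted_difference(big_cohort, utility)
    se = (adj.ci_high - adj.ci_low) / (2 * 1.96)
    assert abs(adj.difference - 0.15) < 3 * se
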