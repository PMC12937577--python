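"""Micro-costing: schedules, medication regimens, cost breakdown identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import jiacea as j
from jiacea.costing import (
    ALLIED_HEALTH_ITEM,
    CARE_PLAN_ITEM,
    CATEGORIES,
    MEDICATION_COMPONENTS,
    MedicationRegimen,
    ScheduleError,
    ScheduleItem,
    UnitCostSchedule,
    UtilizationRecord,
    annual_cost_breakdown,
    annual_medication_cost,
    cost_cohort,
    default_schedule,
)

SCHEDULE = default_schedule()
PRICED = [i for i in SCHEDULE.items]


def _unit_schedule(rows):
    """Schedule pricing each (item, category, component) at exactly 1 AUD."""
    return UnitCostSchedule(
        items={r[0]: ScheduleItem(*r, 1.0) for r in rows}, name="unit"
    )


def test_hospitalization_subtotal_recomputed_from_printed_components():
    # delayed-group hospitalization rows: bone fracture through surgery
    rows = [
        ("bone_fracture", "hospitalization", "bone_fracture"),
        ("infection", "hospitalization", "infection_virus"),
        ("inj", "hospitalization", "injections_infusions"),
        ("pain", "hospitalization", "pain_inflammation_investigative"),
        ("surgery", "hospitalization", "surgery"),
    ]
    sched = _unit_schedule(rows)
    util = UtilizationRecord(
        counts={"bone_fracture": 480, "infection": 2612, "inj": 5657, "pain": 7299, "surgery": 281}
    )
    bd = annual_cost_breakdown(util, sched)
    assert bd.subtotals["hospitalization"] == pytest.approx(16_329)


def test_total_recomputed_from_printed_subtotals():
    rows = [
        ("inv", "investigation", "investigations"),
        ("prof", "professional_visit", "all"),
        ("hosp", "hospitalization", "all"),
        ("med", "medication", "bDMARDS"),
    ]
    sched = _unit_schedule(rows)
    util = UtilizationRecord(counts={"inv": 1753, "prof": 3487, "hosp": 16329, "med": 7925})
    bd = annual_cost_breakdown(util, sched)
    assert bd.total == pytest.approx(29_494)


def test_all_zero_utilization_costs_nothing():
    bd = annual_cost_breakdown(UtilizationRecord(), SCHEDULE)
    assert bd.total == 0.0
    assert all(v == 0.0 for v in bd.subtotals.values())


@settings(max_examples=60, deadline=None)
@given(
    counts=st.dictionaries(
        st.sampled_from(PRICED), st.integers(0, 40), max_size=len(PRICED)
    ),
    safety=st.booleans(),
    care=st.booleans(),
)
def test_aggregation_identity_on_random_utilization(counts, safety, care):
    """total == sum of subtotals == sum of components, whatever the use."""
    bd = annual_cost_breakdown(
        UtilizationRecord(counts=counts, safety_net_reached=safety, care_plan=care),
        SCHEDULE,
    )
    assert bd.total == pytest.approx(sum(bd.subtotals.values()), rel=1e-12)
    assert bd.total == pytest.approx(sum(bd.components.values()), rel=1e-12)
    assert all(v >= 0 for v in bd.components.values())


@settings(max_examples=40, deadline=None)
@given(
    counts=st.dictionaries(st.sampled_from(PRICED), st.integers(0, 20), max_size=8),
    factor=st.floats(0.25, 4.0),
    bump=st.sampled_from(PRICED),
)
def test_homogeneity_and_monotonicity(counts, factor, bump):
    util = UtilizationRecord(counts=counts, safety_net_reached=True, care_plan=True)
    base = annual_cost_breakdown(util, SCHEDULE)
    # doubling every unit cost scales every output by the same factor
    scaled = annual_cost_breakdown(util, SCHEDULE.scaled(factor))
    assert scaled.total == pytest.approx(base.total * factor, rel=1e-9)
    # adding one more unit of any item never decreases the total
    more = dict(counts)
    more[bump] = more.get(bump, 0) + 1
    grown = annual_cost_breakdown(
        UtilizationRecord(counts=more, safety_net_reached=True, care_plan=True),
        SCHEDULE,
    )
    assert grown.total >= base.total - 1e-9


def test_medication_costing_rules():
    # empty regimen list: all four medication rows zero
    assert all(v == 0.0 for v in annual_medication_cost([], SCHEDULE).values())
    # single drug: whole packs per year x unit cost (adalimumab 40 mg
    # fortnightly = 1040 mg/yr over 80 mg packs -> 13 packs)
    reg = MedicationRegimen("adalimumab")
    assert reg.packs_per_year() == 13
    med = annual_medication_cost([reg], SCHEDULE)
    assert med["bDMARDS"] == pytest.approx(13 * SCHEDULE.unit_cost("adalimumab_pack"))
    # dispensing rounds up: 5 mg twice daily tofacitinib needs ceil(3650/280)=14
    assert MedicationRegimen("tofacitinib").packs_per_year() == 14
    # corticosteroid infusions sit in hospitalization costs, not medications
    infused = MedicationRegimen("prednisone", route="infusion")
    assert all(v == 0.0 for v in annual_medication_cost([infused], SCHEDULE).values())
    oral = annual_medication_cost([MedicationRegimen("prednisone")], SCHEDULE)
    assert oral["oral_corticosteroid"] > 0


def test_unknown_drug_and_unpriced_item_errors():
    with pytest.raises(ScheduleError, match="unknown drug"):
        MedicationRegimen("aspirin")
    bare = _unit_schedule([("gp_visit", "professional_visit", "primary_care")])
    with pytest.raises(ScheduleError, match="adalimumab_pack"):
        annual_medication_cost([MedicationRegimen("adalimumab")], bare)
    with pytest.raises(ScheduleError, match="not priced"):
        annual_cost_breakdown(UtilizationRecord(counts={"helicopter": 1}), bare)


def test_negative_or_fractional_counts_rejected():
    with pytest.raises(j.costing.UtilizationError):
        UtilizationRecord(counts={"gp_visit": -1})
    with pytest.raises(j.costing.UtilizationError):
        UtilizationRecord(counts={"gp_visit": 1.5})


def test_safety_net_uplifts_schedule_fees_only():
    counts = {"gp_visit": 10, "hosp_surgery": 1}
    plain = annual_cost_breakdown(UtilizationRecord(counts=counts), SCHEDULE)
    lifted = annual_cost_breakdown(
        UtilizationRecord(counts=counts, safety_net_reached=True), SCHEDULE
    )
    rho = SCHEDULE.safety_net["rebate_fraction"]
    assert lifted.subtotals["professional_visit"] == pytest.approx(
        plain.subtotals["professional_visit"] * (1 + rho)
    )
    assert lifted.subtotals["hospitalization"] == plain.subtotals["hospitalization"]


def test_care_plan_fee_requires_allied_health_use():
    with_allied = annual_cost_breakdown(
        UtilizationRecord(counts={ALLIED_HEALTH_ITEM: 3}, care_plan=True), SCHEDULE
    )
    without = annual_cost_breakdown(
        UtilizationRecord(counts={ALLIED_HEALTH_ITEM: 3}, care_plan=False), SCHEDULE
    )
    fee = SCHEDULE.unit_cost(CARE_PLAN_ITEM)
    assert with_allied.total - without.total == pytest.approx(fee)
    no_use = annual_cost_breakdown(UtilizationRecord(care_plan=True), SCHEDULE)
    assert no_use.total == 0.0


def test_vectorised_costing_matches_record_level(small_cohort):
    table = cost_cohort(small_cohort, SCHEDULE)
    sub = small_cohort.head(25)
    for idx, row in sub.iterrows():
        util = UtilizationRecord(
            counts={
                c[len("use_"):]: int(row[c])
                for c in small_cohort.columns
                if c.startswith("use_")
            },
            safety_net_reached=bool(row["safety_net_reached"]),
            care_plan=bool(row["care_plan"]),
        )
        bd = annual_cost_breakdown(util, SCHEDULE)
        assert table.loc[idx, "total_cost"] == pytest.approx(bd.total, rel=1e-9)
        for cat in CATEGORIES:
            assert table.loc[idx, f"subtotal_{cat}"] == pytest.approx(
                bd.subtotals[cat], rel=1e-9
            )


def test_delayed_group_medication_subtotal_near_calibration_target(big_cohort):
    costs = cost_cohort(big_cohort, SCHEDULE)
    m = (big_cohort["delay_group"] == "ge6plus").to_numpy()
    med = costs.loc[m, "subtotal_medication"].to_numpy()
    se = med.std(ddof=1) / math.sqrt(len(med))
    assert abs(med.mean() - 7_925) < 3 * se
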