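"""Micro-costing of annual healthcare utilization in 2023 Australian dollars.

Reported annual use — medical investigations, health professional visits,
hospitalizations and medications — is converted to costs to the government
health funder by multiplying counts with unit costs from an exogenous
schedule (subsidy item costs for medications, schedule fees for medical
services, efficient prices for hospital stays).  The bundled schedule is a
*synthetic* stand-in with plausible placeholder prices; any schedule in the
same CSV layout can replace it.

Two rules from the survey costing are modelled explicitly:

* the Medicare Safety Net, applied per participant as an increased rebate
  fraction on schedule-fee categories (investigations and professional
  visits) once the participant indicates the out-of-pocket threshold was
  reached; and
* the chronic disease care plan: participants using allied health are
  assumed to have completed a care plan with their primary physician, which
  adds the care-plan rebate item to their primary-care costs.

Corticosteroid injections and infusions are deliberately *not* costed as
medications — they are assumed to be included in hospitalisation costs
(the injections/infusions hospitalization component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES: tuple[str, ...] = (
    "investigation",
    "professional_visit",
    "hospitalization",
    "medication",
)

#: Categories whose prices are schedule fees, hence subject to the safety net.
SCHEDULE_FEE_CATEGORIES: tuple[str, ...] = ("investigation", "professional_visit")

MEDICATION_COMPONENTS: tuple[str, ...] = (
    "csDMARDS",
    "bDMARDS",
    "tsDMARDS",
    "oral_corticosteroid",
)

CARE_PLAN_ITEM = "care_plan_fee"
ALLIED_HEALTH_ITEM = "allied_health_visit"


class ScheduleError(KeyError):
    """Unknown or unpriced item in a unit-cost schedule."""


class UtilizationError(ValueError):
    """Invalid utilization input (e.g. negative count)."""


@dataclass(frozen=True)
class ScheduleItem:
    item: str
    category: str
    component: str
    unit_cost: float


@dataclass(frozen=True)
class UnitCostSchedule:
    """Unit costs per item plus safety-net parameters.

    ``safety_net`` holds ``threshold`` (annual out-of-pocket AUD; informational
    — the survey flag, not the spend, triggers it) and ``rebate_fraction``
    (extra fraction of the schedule fee rebated once reached).
    """

    items: Mapping[str, ScheduleItem]
    safety_net: Mapping[str, float] = field(
        default_factory=lambda: {"threshold": 2250.0, "rebate_fraction": 0.15}
    )
    name: str = "unnamed"

    def __post_init__(self) -> None:
        for it in self.items.values():
            if it.unit_cost < 0:
                raise ScheduleError(f"negative unit cost for {it.item!r}")
            if it.category not in CATEGORIES:
                raise ScheduleError(
                    f"item {it.item!r} has unknown category {it.category!r}"
                )

    def unit_cost(self, item: str) -> float:
        try:
            return self.items[item].unit_cost
        except KeyError:
            raise ScheduleError(
                f"item {item!r} is not priced in schedule {self.name!r}"
            ) from None

    def component_of(self, item: str) -> str:
        if item not in self.items:
            raise ScheduleError(
                f"item {item!r} is not priced in schedule {self.name!r}"
            )
        return self.items[item].component

    def components(self) -> list[tuple[str, str]]:
        """Ordered unique (category, component) pairs in the schedule."""
        seen: list[tuple[str, str]] = []
        for it in self.items.values():
            key = (it.category, it.component)
            if key not in seen:
                seen.append(key)
        return seen

    def scaled(self, factor: float) -> "UnitCostSchedule":
        """Schedule with every unit cost multiplied by ``factor``."""
        return UnitCostSchedule(
            items={
                k: ScheduleItem(v.item, v.category, v.component, v.unit_cost * factor)
                for k, v in self.items.items()
            },
            safety_net=dict(self.safety_net),
            name=f"{self.name} x{factor}",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item": v.item,
                "category": v.category,
                "component": v.component,
                "unit_cost": v.unit_cost,
            }
            for v in self.items.values()
        ]
        rows.append(
            {
                "item": "safety_net_threshold",
                "category": "parameter",
                "component": "safety_net",
                "unit_cost": self.safety_net["threshold"],
            }
        )
        rows.append(
            {
                "item": "safety_net_rebate_fraction",
                "category": "parameter",
                "component": "safety_net",
                "unit_cost": self.safety_net["rebate_fraction"],
            }
        )
        return pd.DataFrame(rows)


def load_schedule(table: pd.DataFrame | str | Path, name: str | None = None) -> UnitCostSchedule:
    """Load a unit-cost schedule from an (item, category, component, unit_cost) table.

    Rows with ``category == "parameter"`` carry the safety-net settings.
    """
    src = ""
    if not isinstance(table, pd.DataFrame):
        src = str(table)
        table = pd.read_csv(table)
    required = {"item", "category", "component", "unit_cost"}
    if not required.issubset(table.columns):
        raise ScheduleError(f"schedule table needs columns {sorted(required)}")
    params = table[table["category"] == "parameter"]
    body = table[table["category"] != "parameter"]
    safety = {"threshold": 2250.0, "rebate_fraction": 0.15}
    for r in params.itertuples():
        if r.item == "safety_net_threshold":
            safety["threshold"] = float(r.unit_cost)
        elif r.item == "safety_net_rebate_fraction":
            safety["rebate_fraction"] = float(r.unit_cost)
    items = {
        r.item: ScheduleItem(r.item, r.category, r.component, float(r.unit_cost))
        for r in body.itertuples()
    }
    if len(items) != len(body):
        raise ScheduleError("duplicate item codes in schedule table")
    return UnitCostSchedule(
        items=items,
        safety_net=safety,
        name=name or (Path(src).stem if src else "in-memory"),
    )


def default_schedule() -> UnitCostSchedule:
    """The bundled synthetic 2023-AUD schedule (placeholder prices)."""
    return load_schedule(
        resources.files("jiacea.data") / "unit_costs_2023_synthetic.csv",
        name="unit_costs_2023_synthetic",
    )


# ---------------------------------------------------------------------------
# Medications


@dataclass(frozen=True)
class DrugInfo:
    drug: str
    drug_class: str  # csDMARD / bDMARD / tsDMARD / oral_corticosteroid
    route: str  # oral / subcutaneous / infusion
    item: str  # schedule item for one dispensed pack
    mg_per_pack: float
    default_dose_mg: float
    default_freq_per_year: float


def _drug(name, cls, route, item, mg_pack, dose, freq):
    return DrugInfo(name, cls, route, item, mg_pack, dose, freq)


#: Dosing assumptions for the survey's medication list (dose x frequency):
#: methotrexate 15 mg weekly (oral or subcutaneous), hydroxychloroquine
#: 200 mg daily, sulfasalazine 1000 mg daily, leflunomide 20 mg daily,
#: adalimumab 40 mg fortnightly, etanercept 50 mg weekly, infliximab 120 mg
#: monthly, tocilizumab 162 mg weekly, abatacept 125 mg weekly, secukinumab
#: 150 mg weekly, tofacitinib 5 mg twice daily, upadacitinib 15 mg daily,
#: baricitinib 4 mg daily, prednisone 25 mg daily.
DRUGS: dict[str, DrugInfo] = {
    d.drug: d
    for d in [
        _drug("methotrexate_oral", "csDMARD", "oral", "methotrexate_oral_pack", 240, 15, 52),
        _drug("methotrexate_sc", "csDMARD", "subcutaneous", "methotrexate_sc_pack", 60, 15, 52),
        _drug("hydroxychloroquine", "csDMARD", "oral", "hydroxychloroquine_pack", 20000, 200, 365),
        _drug("sulfasalazine", "csDMARD", "oral", "sulfasalazine_pack", 50000, 1000, 365),
        _drug("leflunomide", "csDMARD", "oral", "leflunomide_pack", 600, 20, 365),
        _drug("adalimumab", "bDMARD", "subcutaneous", "adalimumab_pack", 80, 40, 26),
        _drug("etanercept", "bDMARD", "subcutaneous", "etanercept_pack", 200, 50, 52),
        _drug("infliximab", "bDMARD", "infusion", "infliximab_pack", 120, 120, 12),
        _drug("tocilizumab", "bDMARD", "subcutaneous", "tocilizumab_pack", 648, 162, 52),
        _drug("abatacept", "bDMARD", "subcutaneous", "abatacept_pack", 500, 125, 52),
        _drug("secukinumab", "bDMARD", "subcutaneous", "secukinumab_pack", 600, 150, 52),
        _drug("tofacitinib", "tsDMARD", "oral", "tofacitinib_pack", 280, 5, 730),
        _drug("upadacitinib", "tsDMARD", "oral", "upadacitinib_pack", 420, 15, 365),
        _drug("baricitinib", "tsDMARD", "oral", "baricitinib_pack", 112, 4, 365),
        _drug("prednisone", "oral_corticosteroid", "oral", "prednisone_pack", 750, 25, 365),
    ]
}

_CLASS_TO_COMPONENT = {
    "csDMARD": "csDMARDS",
    "bDMARD": "bDMARDS",
    "tsDMARD": "tsDMARDS",
    "oral_corticosteroid": "oral_corticosteroid",
}


@dataclass(frozen=True)
class MedicationRegimen:
    """One drug regimen: dose in mg taken ``frequency_per_year`` times a year."""

    drug: str
    dose_mg: float | None = None
    frequency_per_year: float | None = None
    route: str | None = None

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ScheduleError(
                f"unknown drug {self.drug!r}; known: {sorted(DRUGS)}"
            )
        if self.dose_mg is not None and self.dose_mg <= 0:
            raise UtilizationError("dose must be strictly positive")
        if self.frequency_per_year is not None and self.frequency_per_year <= 0:
            raise UtilizationError("frequency must be strictly positive")

    @property
    def info(self) -> DrugInfo:
        return DRUGS[self.drug]

    @property
    def drug_class(self) -> str:
        return self.info.drug_class

    @property
    def effective_route(self) -> str:
        return self.route or self.info.route

    def packs_per_year(self) -> int:
        """Whole dispensed packs needed per year (rounded up)."""
        dose = self.dose_mg if self.dose_mg is not None else self.info.default_dose_mg
        freq = (
            self.frequency_per_year
            if self.frequency_per_year is not None
            else self.info.default_freq_per_year
        )
        return math.ceil(dose * freq / self.info.mg_per_pack - 1e-9)


def annual_medication_cost(
    regimens: Sequence[MedicationRegimen], schedule: UnitCostSchedule
) -> dict[str, float]:
    """Annual medication cost per component row (csDMARDS, bDMARDS, tsDMARDS,
    oral corticosteroid).

    Cost per regimen = whole dispensed packs per year (rounded up) x the pack
    unit cost.  Corticosteroid injections and infusions are excluded here:
    they are assumed to be included in hospitalisation costs.
    """
    totals = {c: 0.0 for c in MEDICATION_COMPONENTS}
    for reg in regimens:
        if reg.drug_class == "oral_corticosteroid" and reg.effective_route != "oral":
            continue  # costed within hospitalizations (injections/infusions)
        totals[_CLASS_TO_COMPONENT[reg.drug_class]] += (
            reg.packs_per_year() * schedule.unit_cost(reg.info.item)
        )
    return totals


# ---------------------------------------------------------------------------
# Utilization -> cost breakdown


@dataclass(frozen=True)
class UtilizationRecord:
    """One participant's annual healthcare use.

    ``counts`` maps schedule item codes to annual counts (integers for
    visits/admissions; medication items are dispensed packs).  ``medications``
    optionally carries richer regimen descriptions costed via
    :func:`annual_medication_cost` in addition to any medication counts.
    """

    counts: Mapping[str, float] = field(default_factory=dict)
    medications: Sequence[MedicationRegimen] = ()
    safety_net_reached: bool = False
    care_plan: bool = False

    def __post_init__(self) -> None:
        for item, n in self.counts.items():
            if n < 0:
                raise UtilizationError(f"negative count for {item!r}")
            if float(n) != int(n):
                raise UtilizationError(
                    f"count for {item!r} must be integer-valued, got {n!r}"
                )


@dataclass(frozen=True)
class CostBreakdown:
    """Annual AUD cost split by component row and category subtotal."""

    components: Mapping[tuple[str, str], float]  # (category, component) -> AUD
    subtotals: Mapping[str, float]  # category -> AUD
    total: float

    def component(self, component: str) -> float:
        return float(
            sum(v for (cat, comp), v in self.components.items() if comp == component)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": cat, "component": comp, "cost": v}
            for (cat, comp), v in self.components.items()
        ]
        return pd.DataFrame(rows)


def annual_cost_breakdown(
    utilization: UtilizationRecord, schedule: UnitCostSchedule
) -> CostBreakdown:
    """Cost one participant's annual utilization against a schedule.

    Per-component cost = count x unit cost; the safety-net rebate uplift
    applies to schedule-fee categories when ``safety_net_reached``; the
    care-plan rebate item is added when ``care_plan`` is set and any allied
    health use is reported.
    """
    components: dict[tuple[str, str], float] = {
        key: 0.0 for key in schedule.components()
    }
    uplift = 1.0 + (
        schedule.safety_net["rebate_fraction"] if utilization.safety_net_reached else 0.0
    )
    for item, n in utilization.counts.items():
        sched_item = schedule.items.get(item)
        if sched_item is None:
            raise ScheduleError(
                f"item {item!r} is not priced in schedule {schedule.name!r}"
            )
        cost = n * sched_item.unit_cost
        if sched_item.category in SCHEDULE_FEE_CATEGORIES:
            cost *= uplift
        components[(sched_item.category, sched_item.component)] += cost
    if utilization.care_plan and utilization.counts.get(ALLIED_HEALTH_ITEM, 0) > 0:
        cp = schedule.items.get(CARE_PLAN_ITEM)
        if cp is not None:
            components[(cp.category, cp.component)] += cp.unit_cost * uplift
    if utilization.medications:
        med = annual_medication_cost(utilization.medications, schedule)
        for comp, v in med.items():
            components[("medication", comp)] = components.get(("medication", comp), 0.0) + v
    subtotals = {cat: 0.0 for cat in CATEGORIES}
    for (cat, comp), v in components.items():
        subtotals[cat] += v
    return CostBreakdown(
        components=components,
        subtotals=subtotals,
        total=float(sum(subtotals.values())),
    )


def cost_cohort(cohort: pd.DataFrame, schedule: UnitCostSchedule) -> pd.DataFrame:
    """Vectorised costing of a cohort table.

    Expects utilization count columns named ``use_<item>``, plus boolean
    ``safety_net_reached`` and ``care_plan`` columns (absent columns are
    treated as all-False).  Returns one row per participant with a column per
    (category, component), ``subtotal_<category>`` columns and ``total_cost``;
    identical to looping :func:`annual_cost_breakdown` row by row.
    """
    n = len(cohort)
    use_cols = [c for c in cohort.columns if c.startswith("use_")]
    safety = (
        cohort["safety_net_reached"].to_numpy(dtype=bool)
        if "safety_net_reached" in cohort.columns
        else np.zeros(n, dtype=bool)
    )
    care = (
        cohort["care_plan"].to_numpy(dtype=bool)
        if "care_plan" in cohort.columns
        else np.zeros(n, dtype=bool)
    )
    uplift = 1.0 + safety * schedule.safety_net["rebate_fraction"]
    comp_cost: dict[tuple[str, str], np.ndarray] = {
        key: np.zeros(n) for key in schedule.components()
    }
    for col in use_cols:
        item = col[len("use_") :]
        sched_item = schedule.items.get(item)
        if sched_item is None:
            raise ScheduleError(
                f"item {item!r} is not priced in schedule {schedule.name!r}"
            )
        counts = cohort[col].to_numpy(dtype=float)
        if (counts < 0).any():
            raise UtilizationError(f"negative count in column {col!r}")
        cost = counts * sched_item.unit_cost
        if sched_item.category in SCHEDULE_FEE_CATEGORIES:
            cost = cost * uplift
        comp_cost[(sched_item.category, sched_item.component)] += cost
    allied_col = f"use_{ALLIED_HEALTH_ITEM}"
    if allied_col in cohort.columns and CARE_PLAN_ITEM in schedule.items:
        cp = schedule.items[CARE_PLAN_ITEM]
        active = care & (cohort[allied_col].to_numpy(dtype=float) > 0)
        comp_cost[(cp.category, cp.component)] += active * cp.unit_cost * uplift
    out = pd.DataFrame(index=cohort.index)
    for (cat, comp), v in comp_cost.items():
        out[f"cost_{cat}__{comp}"] = v
    for cat in CATEGORIES:
        out[f"subtotal_{cat}"] = sum(
            (v for (c, _), v in comp_cost.items() if c == cat), np.zeros(n)
        )
    out["total_cost"] = sum((out[f"subtotal_{c}"] for c in CATEGORIES))
    return out


def cost_table(
    cohort: pd.DataFrame,
    schedule: UnitCostSchedule,
    group_col: str = "delay_group",
) -> pd.DataFrame:
    """Group mean (SD) annual costs per component, subtotal and total, with
    Welch t-test p-values — the survey's cost table shape."""
    from scipy import stats

    costs = cost_cohort(cohort, schedule)
    groups = {
        g: costs[cohort[group_col].to_numpy() == g] for g in ("lt6", "ge6plus")
    }
    rows = []
    for col in costs.columns:
        a = groups["lt6"][col].to_numpy()
        b = groups["ge6plus"][col].to_numpy()
        p = np.nan
        if len(a) > 1 and len(b) > 1 and (a.std(ddof=1) > 0 or b.std(ddof=1) > 0):
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "row": col,
                "mean_lt6": a.mean() if len(a) else np.nan,
                "sd_lt6": a.std(ddof=1) if len(a) > 1 else np.nan,
                "mean_ge6": b.mean() if len(b) else np.nan,
                "sd_ge6": b.std(ddof=1) if len(b) > 1 else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("row")
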