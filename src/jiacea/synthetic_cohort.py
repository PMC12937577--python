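"""Seeded synthetic survey cohorts with the printed group structure.

Generates IMPACT-like participant records for the two time-to-diagnosis
groups (< 6 months vs 6+ months from actively seeking treatment) so every
downstream stage — CHU9D scoring, micro-costing, lifetime projection,
incremental analysis — is testable without the study data.  The generator
is calibrated so that, through the *default* value set and unit-cost
schedule, the scored and costed cohort reproduces the printed group
moments:

* CHU9D utility means 0.59 / 0.44 (SD 0.29) via a common-cutpoint
  cumulative-logit ordinal model on a latent severity, whose location and
  spread are solved numerically per group;
* annual cost means 18,765 / 29,494 AUD (SDs 16,416 / 37,034) via
  zero-inflated Poisson counts per cost component sharing a per-participant
  gamma frailty, whose scale and frailty variance are solved in closed form;
* onset ages 4.4 (3.8) / 5.7 (3.6) years and diagnosis-to-survey gaps
  6.3 (4.9) / 5.1 (4.8) years via truncated normals whose location/scale are
  solved so the *truncated* moments match the printed ones;
* uveitis prevalence 34/102 vs 6/61, 69% female, and a configurable
  fraction (default 21/184) with incomplete CHU9D.

Survey capture quirks are emulated: reported ages are coarsened (months up
to age 1, half-years to age 4, whole years above) and the categorical
time-to-diagnosis measure is recorded in the survey's ordinal bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import chu9d as _chu9d
from . import costing as _costing
from .chu9d import Chu9dResponse, Chu9dValueSet, DIMENSIONS, default_value_set, level_columns, score_cohort
from .costing import UnitCostSchedule, UtilizationRecord, default_schedule, cost_cohort


class ParameterError(ValueError):
    """Invalid cohort parameters."""


class CohortInputError(ValueError):
    """Invalid cohort passed to a reporting operation."""


# ---------------------------------------------------------------------------
# Survey categorical time-to-diagnosis bins

#: (label, low months, high months) of the survey's ordinal delay bins,
#: and the default midpoint (months) used to map bins back to a duration.
DELAY_BINS: tuple[tuple[str, float, float, float], ...] = (
    ("<1 month", 0.0, 1.0, 0.5),
    ("1-2 months", 1.0, 3.0, 1.5),
    ("3-5 months", 3.0, 6.0, 4.0),
    ("6-8 months", 6.0, 9.0, 7.0),
    ("9-12 months", 9.0, 12.0, 10.5),
    ("1-2 years", 12.0, 24.0, 18.0),
    ("3-4 years", 24.0, 60.0, 42.0),
    (">5 years", 60.0, 96.0, 72.0),
)

DELAY_BIN_LABELS: tuple[str, ...] = tuple(b[0] for b in DELAY_BINS)
DELAY_BIN_MIDPOINTS_MONTHS: dict[str, float] = {b[0]: b[3] for b in DELAY_BINS}
_LT6_BINS = DELAY_BIN_LABELS[:3]
_GE6_BINS = DELAY_BIN_LABELS[3:]

#: Default probability of each bin *within* its delay group.
DEFAULT_BIN_PROBS: dict[str, float] = {
    "<1 month": 0.25,
    "1-2 months": 0.40,
    "3-5 months": 0.35,
    "6-8 months": 0.38,
    "9-12 months": 0.27,
    "1-2 years": 0.20,
    "3-4 years": 0.10,
    ">5 years": 0.05,
}

#: Cost-component calibration targets: schedule item ->
#: (target annual mean lt6, target annual mean ge6, zero-inflation prob).
#: Component means follow the printed cost table, with professional-visit
#: rows rescaled so each category subtotal matches its printed subtotal
#: (the printed professional-visit components do not sum to their printed
#: subtotal; see the package methods note).
_PRINTED_COMPONENTS: tuple[tuple[str, float, float, float], ...] = (
    ("imaging_pathology", 1694.0, 1753.0, 0.05),
    ("gp_visit", 459.0, 575.0, 0.05),
    ("specialist_visit", 984.0, 1080.0, 0.10),
    ("rheum_nurse_visit", 464.0, 421.0, 0.60),
    ("allied_health_visit", 1153.0, 1831.0, 0.35),
    ("hosp_bone_fracture", 0.0, 480.0, 0.97),
    ("hosp_infection", 811.0, 2612.0, 0.95),
    ("hosp_injection_infusion", 4750.0, 5657.0, 0.45),
    ("hosp_mental_health", 398.0, 0.0, 0.97),
    ("hosp_pain_inflammation", 1510.0, 7299.0, 0.92),
    ("hosp_surgery", 28.0, 281.0, 0.98),
    ("methotrexate_oral_pack", 397.0, 430.0, 0.25),
    ("adalimumab_pack", 5489.0, 6080.0, 0.55),
    ("tofacitinib_pack", 943.0, 1262.0, 0.93),
    ("prednisone_pack", 148.0, 153.0, 0.50),
)

_PRINTED_SUBTOTALS = {  # (category) -> (lt6, ge6) printed subtotals
    "investigation": (1694.0, 1753.0),
    "professional_visit": (2596.0, 3487.0),
    "hospitalization": (7498.0, 16329.0),
    "medication": (6978.0, 7925.0),
}


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; defaults are the survey's printed group statistics."""

    n_total: int = 163
    p_delayed: float = 61 / 163
    group_utility_means: tuple[float, float] = (0.59, 0.44)  # (lt6, ge6plus)
    utility_sd: float = 0.29
    group_cost_means: tuple[float, float] = (18_765.0, 29_494.0)
    cost_sds: tuple[float, float] = (16_416.0, 37_034.0)
    onset_age_means: tuple[float, float] = (4.4, 5.7)
    onset_age_sds: tuple[float, float] = (3.8, 3.6)
    survey_gap_means: tuple[float, float] = (6.3, 5.1)
    survey_gap_sds: tuple[float, float] = (4.9, 4.8)
    p_female: float = 113 / 163
    uveitis_probs: tuple[float, float] = (34 / 102, 6 / 61)
    missing_chu9d: float = 21 / 184
    p_safety_net: float = 0.25
    seek_lag_mean: float = 0.3  # years from symptom onset to actively seeking
    seek_lag_sd: float = 0.7  # spread chosen so the two delay measures correlate ~0.8
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.p_delayed,
            self.p_female,
            *self.uveitis_probs,
            self.missing_chu9d,
            self.p_safety_net,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ParameterError("all probabilities must be in [0, 1]")
        sds = [
            self.utility_sd,
            *self.cost_sds,
            *self.onset_age_sds,
            *self.survey_gap_sds,
            self.seek_lag_sd,
        ]
        if any(s < 0 for s in sds):
            raise ParameterError("all SDs must be >= 0")
        if self.n_total < 2:
            raise ParameterError("n_total must be >= 2")
        if any(m < 0 for m in self.group_cost_means):
            raise ParameterError("cost means must be >= 0")


# ---------------------------------------------------------------------------
# Age coarsening (survey capture rule)


def coarsen_ages(age_exact):
    """Apply the survey's age-capture rule to exact ages (years).

    Ages up to 1 year are reported in completed months (0.71 y is "8
    months"), up to 4 years to the nearest half-year, and above that to the
    nearest whole year (the rule is silent for ages in (4, 5]; whole years
    are used for continuity with the > 5 rule).  Half-way values round up.
    Idempotent on already-coarsened values.
    """
    arr = np.asarray(age_exact, dtype=float)
    if np.any(arr < 0):
        raise ValueError("age must be non-negative")
    months = np.floor(arr * 12.0 + 1e-9) / 12.0
    halves = np.floor(arr * 2.0 + 0.5) / 2.0
    years = np.floor(arr + 0.5)
    out = np.where(arr <= 1.0, months, np.where(arr <= 4.0, halves, years))
    return float(out) if np.isscalar(age_exact) else out


# ---------------------------------------------------------------------------
# Calibration solvers (deterministic; independent of seed and n)

_CUTPOINTS = np.array([-3.0, -1.0, 1.0, 3.0])
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(64)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _level_probs(s: np.ndarray) -> np.ndarray:
    """(len(s), 5) level probabilities of the cumulative-logit model."""
    cum = special.expit(_CUTPOINTS[None, :] - np.asarray(s)[:, None])
    p = np.empty((len(np.atleast_1d(s)), 5))
    p[:, 0] = cum[:, 0]
    p[:, 1:4] = np.diff(cum, axis=1)
    p[:, 4] = 1.0 - cum[:, 3]
    return p


def _utility_moments(mu: float, tau: float, W: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the scored utility for latent severity N(mu, tau^2)."""
    s = mu + tau * _GH_NODES
    p = _level_probs(s)  # (64, 5)
    dim_mean = p @ W.T  # (64, 9)
    dim_second = p @ (W**2).T
    m = dim_mean.sum(axis=1)
    v = (dim_second - dim_mean**2).sum(axis=1)
    mean = float(_GH_WEIGHTS @ m)
    second = float(_GH_WEIGHTS @ (v + m**2))
    return mean, math.sqrt(max(second - mean**2, 0.0))


@lru_cache(maxsize=32)
def _solve_utility_params(
    target_mean: float, target_sd: float, weights_key: tuple
) -> tuple[float, float]:
    """Solve (mu, tau) of the latent-severity model so the scored utility has
    the target mean and SD under the given value-set weight matrix."""
    W = np.array(weights_key).reshape(9, 5)

    def mean_at(mu, tau):
        return _utility_moments(mu, tau, W)[0]

    def solve_mu(tau):
        return optimize.brentq(
            lambda mu: mean_at(mu, tau) - target_mean, -60.0, 60.0, xtol=1e-10
        )

    def sd_gap(tau):
        mu = solve_mu(tau)
        return _utility_moments(mu, tau, W)[1] - target_sd

    lo, hi = 1e-3, 60.0
    if sd_gap(lo) > 0:
        tau = lo  # target SD below the model floor; keep the mean exact
    else:
        tau = optimize.brentq(sd_gap, lo, hi, xtol=1e-9)
    return solve_mu(tau), tau


def _component_weights(group_idx: int) -> dict[str, tuple[float, float]]:
    """Target component means (rescaled to printed subtotals) and zero-inflation."""
    sched = default_schedule()
    by_cat: dict[str, float] = {}
    for item, m0, m1, p0 in _PRINTED_COMPONENTS:
        cat = sched.items[item].category
        by_cat[cat] = by_cat.get(cat, 0.0) + (m0, m1)[group_idx]
    out: dict[str, tuple[float, float]] = {}
    for item, m0, m1, p0 in _PRINTED_COMPONENTS:
        cat = sched.items[item].category
        target = (m0, m1)[group_idx]
        scale = _PRINTED_SUBTOTALS[cat][group_idx] / by_cat[cat] if by_cat[cat] > 0 else 0.0
        out[item] = (target * scale, p0)
    return out


def _gamma_laplace(t: float | np.ndarray, v: float, order: int = 0):
    """E[g^order exp(-t g)] for g ~ Gamma(mean 1, variance v)."""
    if v <= 1e-12:
        return np.exp(-t) * (1.0 if order == 0 else 1.0)
    base = 1.0 + v * t
    if order == 0:
        return base ** (-1.0 / v)
    if order == 1:
        return base ** (-1.0 / v - 1.0)
    if order == 2:
        return (1.0 + v) * base ** (-1.0 / v - 2.0)
    raise ValueError(order)


def _cost_model_moments(
    lam: Mapping[str, float],
    p0: Mapping[str, float],
    unit: Mapping[str, float],
    is_mbs: Mapping[str, bool],
    v: float,
    rho: float,
    p_s: float,
    care_plan_cost: float,
) -> tuple[float, float]:
    """Exact mean and SD of the costed annual total under the count model.

    Counts are zero-inflated Poisson with participant gamma frailty g
    (mean 1, variance v) shared across components; the safety-net uplift
    (1 + rho) applies to schedule-fee items for the Bernoulli(p_s) flagged
    fraction; the care-plan fee is incurred when the allied-health count is
    positive.
    """
    items = list(lam)
    u = np.array([unit[i] for i in items])
    lm = np.array([lam[i] for i in items])
    z = np.array([p0[i] for i in items])
    mbs = np.array([is_mbs[i] for i in items])
    a_idx = items.index(_costing.ALLIED_HEALTH_ITEM)
    t_a = lm[a_idx] / (1.0 - z[a_idx]) if lm[a_idx] > 0 else 0.0
    oneminus = 1.0 - z[a_idx]
    # closed-form pieces over the gamma frailty
    L1, Lg, L2 = (
        _gamma_laplace(t_a, v, 0),
        _gamma_laplace(t_a, v, 1),
        _gamma_laplace(2 * t_a, v, 0),
    )
    Eq = oneminus * (1.0 - L1) if t_a > 0 else 0.0
    Egq = oneminus * (1.0 - Lg) if t_a > 0 else 0.0
    Eq2 = oneminus**2 * (1.0 - 2 * L1 + L2) if t_a > 0 else 0.0
    Eg2 = 1.0 + v
    mean_total = 0.0
    second_total = 0.0
    for s, ps in ((0, 1.0 - p_s), (1, p_s)):
        mult = np.where(mbs, 1.0 + rho * s, 1.0)
        beta = mult * u
        M1 = float(beta @ lm)
        V1 = float(beta**2 @ lm)
        with np.errstate(divide="ignore", invalid="ignore"):
            excess = np.where(lm > 0, lm**2 * z / (1.0 - z), 0.0)
        V2 = float(beta**2 @ excess)
        cm = care_plan_cost * (1.0 + rho * s)
        mean_s = M1 + cm * Eq
        # second moment: E[E[T|g,S]^2] + E[Var(T|g,S)] over the frailty
        mean_sq = M1**2 * Eg2 + 2 * cm * M1 * Egq + cm**2 * Eq2
        var_within = V1 + Eg2 * V2
        var_within += cm**2 * (Eq - Eq2)  # Bernoulli part of the care-plan fee
        # Cov(allied cost, care-plan fee | g) = beta_a * cm * g * lam_a * (1 - q(g))
        var_within += 2 * beta[a_idx] * cm * lm[a_idx] * (1.0 - Egq)
        mean_total += ps * mean_s
        second_total += ps * (mean_sq + var_within)
    var = second_total - mean_total**2
    return mean_total, math.sqrt(max(var, 0.0))


@lru_cache(maxsize=32)
def _solve_cost_params(
    group_idx: int,
    target_mean: float,
    target_sd: float,
    p_s: float,
) -> tuple[dict, float]:
    """Solve the per-item count means and the frailty variance so the costed
    total has the target mean and SD.  Returns ({item: (lam, p0)}, v)."""
    sched = default_schedule()
    rho = sched.safety_net["rebate_fraction"]
    comp = _component_weights(group_idx)
    cp_cost = sched.unit_cost(_costing.CARE_PLAN_ITEM)
    items = list(comp)
    unit = {i: sched.unit_cost(i) for i in items}
    is_mbs = {
        i: sched.items[i].category in _costing.SCHEDULE_FEE_CATEGORIES for i in items
    }
    p0 = {i: comp[i][1] for i in items}

    def lambdas(phi: float, care_mean: float) -> dict[str, float]:
        lam = {}
        for i in items:
            w = comp[i][0]
            if i == "gp_visit":
                w = max(w - care_mean, 0.0)
            uplift = 1.0 + rho * p_s if is_mbs[i] else 1.0
            lam[i] = phi * w / (unit[i] * uplift)
        return lam

    def solve_phi(v: float) -> tuple[dict[str, float], float]:
        care_mean = 0.0
        phi = 1.0
        for _ in range(6):
            lam = lambdas(phi, care_mean)
            mean, _sd = _cost_model_moments(lam, p0, unit, is_mbs, v, rho, p_s, cp_cost)
            phi *= target_mean / mean
            lam = lambdas(phi, care_mean)
            t_a = lam[_costing.ALLIED_HEALTH_ITEM] / (1.0 - p0[_costing.ALLIED_HEALTH_ITEM])
            p_allied = (1.0 - p0[_costing.ALLIED_HEALTH_ITEM]) * (
                1.0 - _gamma_laplace(t_a, v, 0)
            )
            care_mean = cp_cost * (1.0 + rho * p_s) * p_allied
        return lambdas(phi, care_mean), phi

    def sd_at(v: float) -> float:
        lam, _ = solve_phi(v)
        return _cost_model_moments(lam, p0, unit, is_mbs, v, rho, p_s, cp_cost)[1]

    if sd_at(0.0) >= target_sd:
        v = 0.0  # dispersion floor of the count model exceeds the target
    else:
        v = optimize.brentq(lambda x: sd_at(x) - target_sd, 0.0, 30.0, xtol=1e-9)
    lam, _phi = solve_phi(v)
    return {i: (lam[i], p0[i]) for i in items}, v


def _truncnorm_mixture_moments(loc, scale, uppers):
    a = (0.0 - loc) / scale
    b = (uppers - loc) / scale
    pa, pb = stats.norm.pdf(a), stats.norm.pdf(b)
    # stable tail mass for deep one-sided truncations
    Z = np.where(a > 0, stats.norm.sf(a) - stats.norm.sf(b),
                 stats.norm.cdf(b) - stats.norm.cdf(a))
    Z = np.clip(Z, 1e-300, None)
    mean_i = loc + scale * (pa - pb) / Z
    var_i = scale**2 * (1.0 + (a * pa - b * pb) / Z - ((pa - pb) / Z) ** 2)
    mean = mean_i.mean()
    var = np.maximum(var_i, 0.0).mean() + mean_i.var()
    return mean, math.sqrt(max(var, 0.0))


_TRUNCNORM_MAX_SCALE = 60.0


def _solve_truncnorm(target_mean: float, target_sd: float, uppers: np.ndarray):
    """Location/scale of a [0, upper_i]-truncated normal whose mixture over
    the given upper bounds matches the target mean exactly and the target SD
    as closely as the family allows.

    The mean is solved exactly for every scale (it is monotone in the
    location); the SD is then bracketed over the scale.  When the bounded
    support makes the target SD unattainable the largest-spread member with
    the exact mean is used — the mean is the calibration priority.
    """

    def loc_for(scale: float) -> float:
        lo, hi = -40.0 * scale - 50.0, float(np.max(uppers)) + 5.0 * scale
        return optimize.brentq(
            lambda loc: _truncnorm_mixture_moments(loc, scale, uppers)[0]
            - target_mean,
            lo,
            hi,
            xtol=1e-10,
        )

    def sd_at(scale: float) -> float:
        return _truncnorm_mixture_moments(loc_for(scale), scale, uppers)[1]

    lo, hi = 1e-2, _TRUNCNORM_MAX_SCALE
    if target_sd <= sd_at(lo):
        scale = lo
    elif target_sd >= sd_at(hi):
        scale = hi
    else:
        scale = optimize.brentq(lambda s: sd_at(s) - target_sd, lo, hi, xtol=1e-9)
    return float(loc_for(scale)), float(scale)


# ---------------------------------------------------------------------------
# Generation


def generate_cohort(
    params: CohortParams,
    value_set: Chu9dValueSet | None = None,
) -> pd.DataFrame:
    """Generate a synthetic cohort table, one row per participant.

    Deterministic for fixed ``params`` (the seed lives in the params).  The
    returned table carries demographics, the categorical and age-derived
    delay measures, nine CHU9D level columns, per-item utilization counts
    (``use_<item>``) and the survey flags; it is the canonical input of
    every downstream stage.
    """
    if value_set is None:
        value_set = default_value_set()
    rng = np.random.default_rng(params.seed)
    n = params.n_total

    delayed = rng.random(n) < params.p_delayed
    if n >= 10:  # construction check: keep both arms populated
        if 0 < params.p_delayed < 1 and (delayed.all() or not delayed.any()):
            delayed[rng.integers(0, n)] = not delayed[0]
    group_idx = delayed.astype(int)  # 0 = lt6, 1 = ge6plus
    group = np.where(delayed, "ge6plus", "lt6")

    # --- categorical delay measure and its continuous counterpart ---
    bins_by_group = (_LT6_BINS, _GE6_BINS)
    labels = np.empty(n, dtype=object)
    delay_years = np.empty(n)
    for gi in (0, 1):
        m = group_idx == gi
        if not m.any():
            continue
        bins = bins_by_group[gi]
        probs = np.array([DEFAULT_BIN_PROBS[b] for b in bins])
        probs = probs / probs.sum()
        choice = rng.choice(len(bins), size=int(m.sum()), p=probs)
        labels[m] = np.array(bins, dtype=object)[choice]
        lo = np.array([dict((b[0], b[1]) for b in DELAY_BINS)[l] for l in labels[m]])
        hi = np.array([dict((b[0], b[2]) for b in DELAY_BINS)[l] for l in labels[m]])
        delay_years[m] = (lo + rng.random(int(m.sum())) * (hi - lo)) / 12.0

    # --- ages (coarsened as captured by the survey) ---
    if params.seek_lag_sd > 0:
        shape = (params.seek_lag_mean / params.seek_lag_sd) ** 2
        lag = rng.gamma(shape, params.seek_lag_mean / shape, size=n)
    else:
        lag = np.full(n, params.seek_lag_mean)
    onset = np.empty(n)
    for gi in (0, 1):
        m = group_idx == gi
        if not m.any():
            continue
        uppers = np.minimum(15.49, 15.99 - lag[m] - delay_years[m])
        uppers = np.maximum(uppers, 0.5)
        loc, scale = _solve_truncnorm(
            params.onset_age_means[gi], params.onset_age_sds[gi], uppers
        )
        a, b = (0.0 - loc) / scale, (uppers - loc) / scale
        onset[m] = stats.truncnorm.ppf(rng.random(int(m.sum())), a, b, loc=loc, scale=scale)
    diagnosis_exact = onset + lag + delay_years
    age_onset = coarsen_ages(onset)
    age_diagnosis = np.maximum(coarsen_ages(diagnosis_exact), age_onset)

    gap = np.empty(n)
    for gi in (0, 1):
        m = group_idx == gi
        if not m.any():
            continue
        uppers = np.maximum(25.0 - age_diagnosis[m], 0.05)
        loc, scale = _solve_truncnorm(
            params.survey_gap_means[gi], params.survey_gap_sds[gi], uppers
        )
        a, b = (0.0 - loc) / scale, (uppers - loc) / scale
        gap[m] = stats.truncnorm.ppf(rng.random(int(m.sum())), a, b, loc=loc, scale=scale)
    age_survey = np.minimum(age_diagnosis + gap, 25.0)

    sex = np.where(rng.random(n) < params.p_female, "female", "male")
    uv_p = np.where(delayed, params.uveitis_probs[1], params.uveitis_probs[0])
    uveitis = rng.random(n) < uv_p
    complete = rng.random(n) >= params.missing_chu9d
    safety_net = rng.random(n) < params.p_safety_net

    # --- CHU9D levels from the calibrated latent-severity ordinal model ---
    wkey = tuple(np.round(value_set.as_matrix().ravel(), 12))
    levels = np.zeros((n, 9), dtype=float)
    z = rng.standard_normal(n)
    unif = rng.random((n, 9))
    for gi in (0, 1):
        mu, tau = _solve_utility_params(
            params.group_utility_means[gi], params.utility_sd, wkey
        )
        m = group_idx == gi
        if not m.any():
            continue
        s = mu + tau * z[m]
        cum = special.expit(_CUTPOINTS[None, :] - s[:, None])  # (m, 4)
        levels[m] = 1.0 + (unif[m][:, :, None] > cum[:, None, :]).sum(axis=2)
    levels[~complete] = np.nan

    # --- utilization counts from the calibrated frailty count model ---
    counts: dict[str, np.ndarray] = {}
    frailty = np.ones(n)
    for gi in (0, 1):
        lam_p0, v = _solve_cost_params(
            gi,
            params.group_cost_means[gi],
            params.cost_sds[gi],
            params.p_safety_net,
        )
        m = group_idx == gi
        if not m.any():
            continue
        if v > 1e-12:
            frailty[m] = rng.gamma(1.0 / v, v, size=int(m.sum()))
        for item, (lam, p0) in lam_p0.items():
            col = counts.setdefault(item, np.zeros(n))
            if lam <= 0:
                continue
            active = rng.random(int(m.sum())) >= p0
            pois = rng.poisson(frailty[m] * lam / (1.0 - p0))
            col[m] = active * pois

    df = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "delay_group": group,
            "delay_category": labels,
            "sex": sex,
            "age_onset": age_onset,
            "age_diagnosis": age_diagnosis,
            "age_survey": np.round(age_survey, 6),
            "uveitis": uveitis,
            "chu9d_complete": complete,
            "safety_net_reached": safety_net,
            "care_plan": np.ones(n, dtype=bool),
        }
    )
    for j, d in enumerate(DIMENSIONS):
        df[f"chu9d_{d}"] = levels[:, j]
    for item, col in counts.items():
        df[f"use_{item}"] = col.astype(int)
    return df


# ---------------------------------------------------------------------------
# Participant records (row-level view with invariant checks)


@dataclass(frozen=True)
class ParticipantRecord:
    """One survey respondent, validated against the survey's constraints."""

    id: str
    delay_group: str
    delay_category: str
    sex: str
    age_onset: float
    age_diagnosis: float
    age_survey: float
    chu9d: Chu9dResponse | None
    utilization: UtilizationRecord
    uveitis: bool
    chu9d_complete: bool

    def __post_init__(self) -> None:
        if self.delay_group not in ("lt6", "ge6plus"):
            raise ParameterError(f"unknown delay group {self.delay_group!r}")
        if self.delay_category not in DELAY_BIN_LABELS:
            raise ParameterError(f"unknown delay category {self.delay_category!r}")
        in_lt6 = self.delay_category in _LT6_BINS
        if in_lt6 != (self.delay_group == "lt6"):
            raise ParameterError(
                f"delay category {self.delay_category!r} inconsistent with "
                f"group {self.delay_group!r}"
            )
        if not (0 <= self.age_onset <= self.age_diagnosis <= self.age_survey <= 25):
            raise ParameterError(
                "ages must satisfy 0 <= onset <= diagnosis <= survey <= 25"
            )
        if self.age_onset >= 16:
            raise ParameterError("symptom onset must be before age 16")
        if self.chu9d_complete and self.chu9d is None:
            raise ParameterError("complete flag set but no CHU9D response")


def records_from_frame(cohort: pd.DataFrame) -> list[ParticipantRecord]:
    """Materialise (and thereby validate) row-level records from a cohort table."""
    recs = []
    lev_cols = level_columns()
    use_cols = [c for c in cohort.columns if c.startswith("use_")]
    for _, row in cohort.iterrows():
        complete = bool(row["chu9d_complete"]) and not any(
            pd.isna(row[c]) for c in lev_cols
        )
        resp = (
            Chu9dResponse(
                {d: int(row[f"chu9d_{d}"]) for d in DIMENSIONS}
            )
            if complete
            else None
        )
        util = UtilizationRecord(
            counts={c[len("use_"):]: int(row[c]) for c in use_cols},
            safety_net_reached=bool(row.get("safety_net_reached", False)),
            care_plan=bool(row.get("care_plan", False)),
        )
        recs.append(
            ParticipantRecord(
                id=str(row["id"]),
                delay_group=str(row["delay_group"]),
                delay_category=str(row["delay_category"]),
                sex=str(row["sex"]),
                age_onset=float(row["age_onset"]),
                age_diagnosis=float(row["age_diagnosis"]),
                age_survey=float(row["age_survey"]),
                chu9d=resp,
                utilization=util,
                uveitis=bool(row["uveitis"]),
                chu9d_complete=complete,
            )
        )
    return recs


# ---------------------------------------------------------------------------
# Calibration report


def _se_mean(x: np.ndarray) -> float:
    return x.std(ddof=1) / math.sqrt(len(x))


def _se_sd(x: np.ndarray) -> float:
    """Moment-based standard error of the sample SD (fourth-moment formula)."""
    n = len(x)
    s2 = x.var(ddof=1)
    m4 = np.mean((x - x.mean()) ** 4)
    var_s2 = max(m4 - s2**2 * (n - 3) / (n - 1), 0.0) / n
    return math.sqrt(var_s2) / (2.0 * math.sqrt(s2)) if s2 > 0 else np.nan


def calibration_report(
    cohort: pd.DataFrame,
    params: CohortParams,
    value_set: Chu9dValueSet | None = None,
    schedule: UnitCostSchedule | None = None,
) -> pd.DataFrame:
    """Target-vs-realized group moments, flagging any beyond 3 standard errors.

    Scores and costs the cohort through the (default) value set and
    schedule, then compares realized group means/SDs for utility, annual
    cost, onset age and diagnosis-to-survey gap against the configured
    targets.  ``flag`` marks moments more than 3 SE from target.
    """
    if len(cohort) == 0:
        raise CohortInputError("empty cohort")
    value_set = value_set or default_value_set()
    schedule = schedule or default_schedule()
    utility = score_cohort(cohort, value_set)
    total = cost_cohort(cohort, schedule)["total_cost"]
    gap = cohort["age_survey"] - cohort["age_diagnosis"]
    rows = []
    for gi, g in enumerate(("lt6", "ge6plus")):
        m = (cohort["delay_group"] == g).to_numpy()
        u = utility.to_numpy()[m]
        u = u[~np.isnan(u)]
        c = total.to_numpy()[m]
        quantities = [
            ("utility_mean", u.mean() if len(u) else np.nan, params.group_utility_means[gi], _se_mean(u) if len(u) > 1 else np.nan),
            ("utility_sd", u.std(ddof=1) if len(u) > 1 else np.nan, params.utility_sd, _se_sd(u) if len(u) > 3 else np.nan),
            ("cost_mean", c.mean() if len(c) else np.nan, params.group_cost_means[gi], _se_mean(c) if len(c) > 1 else np.nan),
            ("cost_sd", c.std(ddof=1) if len(c) > 1 else np.nan, params.cost_sds[gi], _se_sd(c) if len(c) > 3 else np.nan),
            ("onset_age_mean", cohort.loc[m, "age_onset"].mean(), params.onset_age_means[gi], _se_mean(cohort.loc[m, "age_onset"].to_numpy()) if m.sum() > 1 else np.nan),
            ("survey_gap_mean", gap[m].mean(), params.survey_gap_means[gi], _se_mean(gap[m].to_numpy()) if m.sum() > 1 else np.nan),
        ]
        for name, realized, target, se in quantities:
            dev = (realized - target) / se if se and se > 0 else np.nan
            rows.append(
                {
                    "group": g,
                    "moment": name,
                    "target": target,
                    "realized": realized,
                    "se": se,
                    "z": dev,
                    "flag": bool(abs(dev) > 3) if np.isfinite(dev) else True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort file I/O


def write_cohort(cohort: pd.DataFrame, path: str | Path, params: CohortParams | None = None) -> None:
    """Write a cohort CSV (stable formatting) plus an adjacent .meta.json
    recording the generator parameters and seed."""
    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.6f")
    if params is not None:
        meta = {"params": asdict(params), "seed": params.seed}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df
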