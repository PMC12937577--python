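"""Child Health Utility 9D (CHU9D) responses and preference-weight scoring.

The CHU9D is a nine-dimension, five-level child health-related quality of
life instrument.  A response assigns each dimension (worry, sadness, pain,
tiredness, annoyance, school work, sleep, daily routine, activities) an
integer level from 1 (no problems) to 5 (worst).  A country-specific value
set maps each (dimension, level) cell to an additive utility contribution;
the utility of a health state is the sum of the nine contributions, anchored
near 1 for perfect health and 0 for being dead.

The bundled default value set is a *synthetic* stand-in for the published
Australian adolescent weights: level-1 and level-5 contributions are pinned
to the per-dimension ranges reported for this instrument in the Australian
JIA survey setting (e.g. worry 0.11-0.22, pain -0.02-0.11) and levels 2-4
are linearly interpolated.  Any published value set in the same CSV layout
(dimension, level, weight) can be dropped in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical dimension order used everywhere (CSV columns, arrays, tables).
DIMENSIONS: tuple[str, ...] = (
    "worry",
    "sadness",
    "pain",
    "tiredness",
    "annoyance",
    "school",
    "sleep",
    "daily_routine",
    "activities",
)

LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Per-dimension (best, worst) utility contributions of the default
#: synthetic value set; level 1 is best, level 5 worst.
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "worry": (0.22, 0.11),
    "sadness": (0.15, 0.02),
    "pain": (0.11, -0.02),
    "tiredness": (0.11, 0.03),
    "annoyance": (0.08, -0.04),
    "school": (0.09, -0.02),
    "sleep": (0.06, -0.05),
    "daily_routine": (0.07, -0.05),
    "activities": (0.13, 0.02),
}


class Chu9dError(ValueError):
    """Invalid CHU9D response or value set."""


@dataclass(frozen=True)
class Chu9dResponse:
    """One participant's CHU9D answers: dimension -> level in 1..5."""

    levels: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(DIMENSIONS) - set(self.levels)
        extra = set(self.levels) - set(DIMENSIONS)
        if missing or extra:
            raise Chu9dError(
                f"response must cover exactly the nine CHU9D dimensions; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for dim, lev in self.levels.items():
            if lev not in LEVELS:
                raise Chu9dError(f"level for {dim!r} must be in 1..5, got {lev!r}")


@dataclass(frozen=True)
class Chu9dValueSet:
    """Additive preference weights: (dimension, level) -> utility contribution.

    ``weights`` must be defined for all 45 cells.  For a well-formed set the
    contribution is weakly decreasing in level within each dimension (level 1
    is the best health state).
    """

    weights: Mapping[tuple[str, int], float]
    name: str = "unnamed"
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [
            (d, k) for d in DIMENSIONS for k in LEVELS if (d, k) not in self.weights
        ]
        if missing:
            raise Chu9dError(f"value set missing cells: {missing[:5]}...")

    def dimension_weights(self, dimension: str) -> np.ndarray:
        """Weights for one dimension as a length-5 array (levels 1..5)."""
        if dimension not in DIMENSIONS:
            raise Chu9dError(f"unknown CHU9D dimension {dimension!r}")
        return np.array([self.weights[(dimension, k)] for k in LEVELS])

    def as_matrix(self) -> np.ndarray:
        """(9, 5) weight matrix in canonical dimension and level order."""
        return np.vstack([self.dimension_weights(d) for d in DIMENSIONS])

    def is_monotone(self) -> bool:
        m = self.as_matrix()
        return bool(np.all(np.diff(m, axis=1) <= 1e-12))

    @property
    def best_utility(self) -> float:
        return float(self.as_matrix()[:, 0].sum())

    @property
    def worst_utility(self) -> float:
        return float(self.as_matrix()[:, -1].sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"dimension": d, "level": k, "weight": self.weights[(d, k)]}
            for d in DIMENSIONS
            for k in LEVELS
        ]
        return pd.DataFrame(rows)


def default_value_set() -> Chu9dValueSet:
    """The bundled synthetic Australian-style value set (see module docstring)."""
    return load_value_set(
        resources.files("jiacea.data") / "chu9d_value_set_synthetic.csv"
    )


def _build_default_frame() -> pd.DataFrame:
    rows = []
    for dim, (best, worst) in _DEFAULT_RANGES.items():
        for k in LEVELS:
            w = best + (worst - best) * (k - 1) / 4.0
            rows.append({"dimension": dim, "level": k, "weight": round(w, 6)})
    return pd.DataFrame(rows)


def load_value_set(
    table: pd.DataFrame | str | Path,
    *,
    name: str | None = None,
    allow_non_monotone: bool = False,
) -> Chu9dValueSet:
    """Load and validate a value set from a (dimension, level, weight) table.

    Parameters
    ----------
    table
        DataFrame or CSV path with columns ``dimension``, ``level``,
        ``weight`` and exactly one row per (dimension, level) cell.
    allow_non_monotone
        If False (default), reject sets whose contribution increases with
        level anywhere (level 1 must be the best state).
    """
    src = ""
    if not isinstance(table, pd.DataFrame):
        src = str(table)
        table = pd.read_csv(table)
    required = {"dimension", "level", "weight"}
    if not required.issubset(table.columns):
        raise Chu9dError(f"value-set table needs columns {sorted(required)}")
    cells = {(r.dimension, int(r.level)): float(r.weight) for r in table.itertuples()}
    if len(cells) != len(table):
        raise Chu9dError("duplicate (dimension, level) rows in value-set table")
    missing = [(d, k) for d in DIMENSIONS for k in LEVELS if (d, k) not in cells]
    if missing:
        raise Chu9dError(f"value-set table missing cells: {missing}")
    vs = Chu9dValueSet(
        weights=cells, name=name or (Path(src).stem if src else "in-memory")
    )
    if not allow_non_monotone and not vs.is_monotone():
        bad = [
            d for d in DIMENSIONS if np.any(np.diff(vs.dimension_weights(d)) > 1e-12)
        ]
        raise Chu9dError(
            f"weights increase with level for dimension(s) {bad}; "
            "pass allow_non_monotone=True to accept"
        )
    return vs


def dimension_score(
    response: Chu9dResponse, dimension: str, value_set: Chu9dValueSet
) -> float:
    """Utility contribution of one dimension of a response."""
    if dimension not in DIMENSIONS:
        raise Chu9dError(f"unknown CHU9D dimension {dimension!r}")
    return float(value_set.weights[(dimension, response.levels[dimension])])


def score_utility(
    response: Chu9dResponse | None, value_set: Chu9dValueSet
) -> float:
    """Utility of a full response: the sum of the nine dimension scores.

    An absent/incomplete response yields ``nan`` (the participant is excluded
    downstream), never a silent zero — zero is a meaningful utility (dead).
    """
    if response is None:
        return float("nan")
    return float(
        sum(dimension_score(response, d, value_set) for d in DIMENSIONS)
    )


def level_columns() -> list[str]:
    """Cohort-table column names holding the nine response levels."""
    return [f"chu9d_{d}" for d in DIMENSIONS]


def score_cohort(cohort: pd.DataFrame, value_set: Chu9dValueSet) -> pd.Series:
    """Vectorised scoring of a cohort table.

    Expects integer level columns ``chu9d_<dimension>``; rows with any
    missing level (or ``chu9d_complete == False``) score ``nan``.
    """
    cols = level_columns()
    absent = [c for c in cols if c not in cohort.columns]
    if absent:
        raise Chu9dError(f"cohort table missing CHU9D columns: {absent}")
    levels = cohort[cols].to_numpy(dtype=float)
    ok = ~np.isnan(levels).any(axis=1)
    if "chu9d_complete" in cohort.columns:
        ok &= cohort["chu9d_complete"].to_numpy(dtype=bool)
    util = np.full(len(cohort), np.nan)
    if ok.any():
        lev = levels[ok].astype(int)
        if lev.min() < 1 or lev.max() > 5:
            raise Chu9dError("CHU9D levels outside 1..5 in cohort table")
        w = value_set.as_matrix()  # (9, 5)
        util[ok] = np.sum(w[np.arange(9)[None, :], lev - 1], axis=1)
    return pd.Series(util, index=cohort.index, name="utility")


def dimension_summary(
    cohort: pd.DataFrame,
    value_set: Chu9dValueSet,
    group_col: str = "delay_group",
) -> pd.DataFrame:
    """Per-dimension group mean (SD) contributions with Welch t-test p-values.

    One row per dimension plus an ``overall`` utility row, computed over
    participants with complete CHU9D responses.  Groups with fewer than two
    complete responses get missing statistics rather than an error.
    """
    cols = level_columns()
    complete = cohort
    if "chu9d_complete" in cohort.columns:
        complete = cohort[cohort["chu9d_complete"].astype(bool)]
    complete = complete.dropna(subset=cols)
    groups = ["lt6", "ge6plus"]
    w = value_set.as_matrix()
    rows = []
    per_group_scores: dict[str, dict[str, np.ndarray]] = {}
    for g in groups:
        sub = complete[complete[group_col] == g]
        lev = sub[cols].to_numpy(dtype=int)
        scores = {
            d: w[i, lev[:, i] - 1] if len(lev) else np.array([])
            for i, d in enumerate(DIMENSIONS)
        }
        scores["overall"] = (
            np.vstack(list(scores.values())).sum(axis=0) if len(lev) else np.array([])
        )
        per_group_scores[g] = scores
    for d in ("overall", *DIMENSIONS):
        a = per_group_scores["lt6"][d]
        b = per_group_scores["ge6plus"][d]
        row = {
            "dimension": d,
            "n_lt6": len(a),
            "n_ge6": len(b),
            "mean_lt6": a.mean() if len(a) else np.nan,
            "sd_lt6": a.std(ddof=1) if len(a) > 1 else np.nan,
            "mean_ge6": b.mean() if len(b) else np.nan,
            "sd_ge6": b.std(ddof=1) if len(b) > 1 else np.nan,
        }
        if len(a) >= 2 and len(b) >= 2:
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            row["p_value"] = p
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("dimension")
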