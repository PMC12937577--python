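"""Descriptive cohort characterisation, delay-measure concordance, and the
end-to-end report runner.

``descriptive_table`` reproduces the shape of the survey's demographic
table: mean (SD) and median (IQR) with Welch t-tests for continuous
characteristics, count (%) with chi-squared tests (small-cell exact
fallback, flagged) for categorical ones.  ``time_measure_concordance``
correlates the two time-to-diagnosis measures — the ordinal
actively-seeking-to-diagnosis bins (mapped to configurable midpoints) and
the age-derived onset-to-diagnosis delay.  ``run_full_analysis`` chains
simulate -> score -> cost -> project -> evaluate -> sensitivity -> budget
and writes a reproducible report bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chu9d import default_value_set, dimension_summary, load_value_set, score_cohort
from .costing import cost_cohort, cost_table, default_schedule, load_schedule
from .econ import (
    BudgetInputs,
    adjusted_difference,
    budget_impact,
    cea_plane,
    evaluate_cohort,
    incremental_mean,
    one_way_sensitivity,
)
from .lifetime import EconParams, default_life_table, load_life_table
from .synthetic_cohort import (
    DELAY_BIN_MIDPOINTS_MONTHS,
    CohortParams,
    calibration_report,
    generate_cohort,
    read_cohort,
    write_cohort,
)


class ReportConfigError(ValueError):
    """A characteristic or input file referenced by the config is missing."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class DescriptiveRow:
    characteristic: str
    kind: str  # continuous / categorical
    summary_lt6: str
    summary_ge6: str
    p_value: float
    test: str


def _fmt_cont(x: np.ndarray) -> str:
    med, q1, q3 = np.percentile(x, [50, 25, 75])
    return f"{x.mean():.1f} (±{x.std(ddof=1):.1f}); median {med:.1f} ({q1:.1f}-{q3:.1f})"


def descriptive_table(
    cohort: pd.DataFrame,
    characteristics: Sequence[str],
    group_col: str = "delay_group",
    continuity_correction: bool = False,
    exact_threshold: float = 5.0,
) -> pd.DataFrame:
    """Group summaries with tests, one block per characteristic.

    Continuous characteristics get mean (SD), median (IQR) and a Welch
    t-test; categorical ones count (%) per level and a chi-squared test
    without continuity correction by default (2x2 tables with an expected
    cell below ``exact_threshold`` fall back to Fisher's exact test,
    flagged in the ``test`` column).  Percentages are recomputed from
    counts at render time.  Missing values are excluded row-wise and
    counted.
    """
    if len(cohort) == 0:
        raise ReportConfigError("empty cohort")
    missing_cols = [c for c in characteristics if c not in cohort.columns]
    if missing_cols:
        raise ReportConfigError(f"characteristics absent from cohort: {missing_cols}")
    ga = cohort[cohort[group_col] == "lt6"]
    gb = cohort[cohort[group_col] == "ge6plus"]
    rows = []
    for ch in characteristics:
        col = cohort[ch]
        n_missing = int(col.isna().sum())
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            a = ga[ch].dropna().to_numpy(dtype=float)
            b = gb[ch].dropna().to_numpy(dtype=float)
            if len(a) > 1 and len(b) > 1 and (a.std() > 0 or b.std() > 0):
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                test = "welch_t"
            else:
                p, test = 1.0, "skipped (constant or undersized)"
            rows.append(
                {
                    "characteristic": ch,
                    "level": "",
                    "kind": "continuous",
                    "summary_lt6": _fmt_cont(a) if len(a) else "",
                    "summary_ge6": _fmt_cont(b) if len(b) else "",
                    "n_missing": n_missing,
                    "p_value": p,
                    "test": test,
                }
            )
        else:
            levels = sorted(col.dropna().unique(), key=str)
            counts = np.array(
                [
                    [int((ga[ch] == lv).sum()) for lv in levels],
                    [int((gb[ch] == lv).sum()) for lv in levels],
                ]
            )
            if len(levels) < 2 or counts.sum(axis=0).min() == 0:
                p, test = 1.0, "skipped (constant)"
            else:
                expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
                if counts.shape == (2, 2) and expected.min() < exact_threshold:
                    p = float(stats.fisher_exact(counts)[1])
                    test = "fisher_exact (small cells)"
                else:
                    p = float(
                        stats.chi2_contingency(
                            counts, correction=continuity_correction
                        )[1]
                    )
                    test = "chi_squared"
            na, nb = counts.sum(axis=1)
            for j, lv in enumerate(levels):
                rows.append(
                    {
                        "characteristic": ch,
                        "level": str(lv),
                        "kind": "categorical",
                        "summary_lt6": f"{counts[0, j]} ({100 * counts[0, j] / max(na, 1):.1f}%)",
                        "summary_ge6": f"{counts[1, j]} ({100 * counts[1, j] / max(nb, 1):.1f}%)",
                        "n_missing": n_missing,
                        "p_value": p,
                        "test": test,
                    }
                )
    return pd.DataFrame(rows)


def time_measure_concordance(
    cohort: pd.DataFrame,
    midpoints_months: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Pearson correlation between the two time-to-diagnosis measures.

    The categorical actively-seeking delay is mapped to bin midpoints (in
    months, configurable); the second measure is the onset-to-diagnosis
    delay derived from reported ages.  Returns r with a Fisher-z 95% CI.
    """
    mids = dict(midpoints_months or DELAY_BIN_MIDPOINTS_MONTHS)
    x = cohort["delay_category"].map(mids).to_numpy(dtype=float)
    y = (cohort["age_diagnosis"] - cohort["age_onset"]).to_numpy(dtype=float) * 12.0
    if np.isnan(x).any():
        raise ReportConfigError("unmapped delay category in cohort")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroDivisionError("undefined correlation: a delay measure is constant")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n - 3)
    return {
        "r": r,
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "n": n,
    }


# ---------------------------------------------------------------------------
# End-to-end report bundle


_DEFAULT_CHARACTERISTICS = (
    "age_onset",
    "age_diagnosis",
    "age_survey",
    "sex",
    "uveitis",
)


def run_full_analysis(config: Mapping | str | Path) -> dict:
    """Execute the whole pipeline from a config mapping (or YAML path).

    Config keys (all optional): ``seed``, ``n_total``, ``cohort`` (CSV path;
    otherwise a cohort is simulated), ``value_set``/``schedule``/
    ``life_table`` (CSV paths; defaults bundled), ``econ`` (EconParams
    overrides), ``budget`` (BudgetInputs overrides), ``n_boot``, ``outdir``.

    Writes CSV tables, a JSON results file and a plain-text run log to
    ``outdir`` and returns the results dict.  Outputs are byte-identical
    under a fixed seed.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    if not isinstance(config, Mapping):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config or {})
    outdir = Path(cfg.get("outdir", "results/report"))
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        log.append(f"stage: {name}")
        return name

    try:
        stage("inputs")
        value_set = (
            load_value_set(cfg["value_set"]) if "value_set" in cfg else default_value_set()
        )
        schedule = (
            load_schedule(cfg["schedule"]) if "schedule" in cfg else default_schedule()
        )
        life_table = (
            load_life_table(cfg["life_table"])
            if "life_table" in cfg
            else default_life_table()
        )
        params = EconParams(**cfg.get("econ", {}))
    except Exception as e:
        raise StageError(f"stage 'inputs' failed: {e}") from e

    try:
        stage("cohort")
        if "cohort" in cfg and cfg["cohort"]:
            cohort = read_cohort(cfg["cohort"])
            cparams = None
            log.append(f"cohort: loaded {len(cohort)} records from {cfg['cohort']}")
        else:
            cparams = CohortParams(
                n_total=int(cfg.get("n_total", 163)), seed=int(cfg.get("seed", 0))
            )
            cohort = generate_cohort(cparams, value_set)
            write_cohort(cohort, outdir / "cohort.csv", cparams)
            log.append(
                f"cohort: simulated n={len(cohort)} seed={cparams.seed}"
            )
    except StageError:
        raise
    except Exception as e:
        raise StageError(f"stage 'cohort' failed: {e}") from e

    results: dict = {"n": int(len(cohort))}
    try:
        stage("descriptives")
        chars = [
            c for c in cfg.get("characteristics", _DEFAULT_CHARACTERISTICS)
            if c in cohort.columns
        ]
        desc = descriptive_table(cohort, chars)
        desc.to_csv(outdir / "table1_descriptives.csv", index=False)
        conc = time_measure_concordance(cohort)
        results["concordance"] = conc
        log.append(f"concordance: r={conc['r']:.3f} ({conc['ci_low']:.3f}, {conc['ci_high']:.3f})")
    except Exception as e:
        raise StageError(f"stage 'descriptives' failed: {e}") from e

    try:
        stage("score")
        dim = dimension_summary(cohort, value_set)
        dim.to_csv(outdir / "table2_chu9d_dimensions.csv")
        utility = score_cohort(cohort, value_set)
        adj = adjusted_difference(cohort, utility)
        results["utility_adjusted"] = adj.to_dict()
    except Exception as e:
        raise StageError(f"stage 'score' failed: {e}") from e

    try:
        stage("cost")
        ct = cost_table(cohort, schedule)
        ct.to_csv(outdir / "table4_costs.csv")
    except Exception as e:
        raise StageError(f"stage 'cost' failed: {e}") from e

    try:
        stage("evaluate")
        res = evaluate_cohort(cohort, value_set, schedule, life_table, params)
        for key in ("utility", "annual_cost_savings", "pv_qalys", "pv_cost_savings", "nmb_aud"):
            results[key] = res[key].to_dict()
        results["nmb_usd"] = res["nmb_usd"]
        lifetime_rows = pd.DataFrame(
            [results[k] for k in ("pv_cost_savings", "pv_qalys", "nmb_aud")]
        )
        lifetime_rows.to_csv(outdir / "table6_lifetime.csv", index=False)
        log.append(
            "lifetime: savings={:.0f} qalys={:.2f} nmb={:.0f}".format(
                res["pv_cost_savings"].difference,
                res["pv_qalys"].difference,
                res["nmb_aud"].difference,
            )
        )
        if cparams is not None:
            calib = calibration_report(cohort, cparams, value_set, schedule)
            calib.to_csv(outdir / "calibration_report.csv", index=False)
    except Exception as e:
        raise StageError(f"stage 'evaluate' failed: {e}") from e

    try:
        stage("plane")
        plane = cea_plane(
            res["pv"], n_boot=int(cfg.get("n_boot", 2000)), seed=int(cfg.get("seed", 0))
        )
        plane["points"].to_csv(outdir / "cea_plane.csv", index=False)
        results["cea_quadrants"] = plane["quadrants"]
    except Exception as e:
        raise StageError(f"stage 'plane' failed: {e}") from e

    try:
        stage("sensitivity")
        sens = one_way_sensitivity(cohort, value_set, schedule, life_table, params)
        sens.to_csv(outdir / "sensitivity.csv")
        results["sensitivity"] = {
            k: float(v) for k, v in sens["nmb_aud"].items()
        }
    except Exception as e:
        raise StageError(f"stage 'sensitivity' failed: {e}") from e

    try:
        stage("budget")
        budget = budget_impact(
            BudgetInputs(
                **{
                    **{"nmb_per_child": res["nmb_aud"].difference},
                    **cfg.get("budget", {}),
                }
            )
        )
        results["budget"] = budget
        (outdir / "budget_impact.json").write_text(
            json.dumps(budget, indent=2, sort_keys=True) + "\n"
        )
    except Exception as e:
        raise StageError(f"stage 'budget' failed: {e}") from e

    log.append(f"econ params: {asdict(params)}")
    log.append(f"seed: {cfg.get('seed', 0)}")
    import jiacea

    log.append(f"jiacea version: {jiacea.__version__}")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    (outdir / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float) + "\n"
    )
    return results
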