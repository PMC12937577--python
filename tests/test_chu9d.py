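"""CHU9D response validation and additive utility scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from jiacea.chu9d import (
    Chu9dError,
    Chu9dResponse,
    Chu9dValueSet,
    DIMENSIONS,
    dimension_score,
    dimension_summary,
    load_value_set,
    score_cohort,
    score_utility,
)

# per-dimension (best, worst) contributions the bundled set must reproduce
PRINTED_RANGES = {
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


import jiacea

_DEFAULT_SET = jiacea.default_value_set()


def _response(level: int) -> Chu9dResponse:
    return Chu9dResponse({d: level for d in DIMENSIONS})


def _zero_set() -> Chu9dValueSet:
    return Chu9dValueSet(
        {(d, k): 0.0 for d in DIMENSIONS for k in range(1, 6)}, name="zero"
    )


@pytest.mark.parametrize("dimension", DIMENSIONS)
def test_default_set_reproduces_published_range_endpoints(value_set, dimension):
    best, worst = PRINTED_RANGES[dimension]
    w = value_set.dimension_weights(dimension)
    assert w[0] == pytest.approx(best, abs=1e-9)
    assert w[-1] == pytest.approx(worst, abs=1e-9)
    assert np.all(np.diff(w) <= 1e-12)  # level 1 is the best state


def test_scoring_extremes_and_additivity(value_set):
    # best state scores the sum of printed maxima (1.02, not renormalised to 1)
    assert score_utility(_response(1), value_set) == pytest.approx(1.02, abs=1e-9)
    # worst state scores exactly 0 (the printed minima cancel)
    assert score_utility(_response(5), value_set) == pytest.approx(0.0, abs=1e-9)
    # additivity over the 9x5 grid: per-dimension extremes give the global ones
    m = value_set.as_matrix()
    assert m.min(axis=1).sum() == pytest.approx(0.0, abs=1e-9)
    assert m.max(axis=1).sum() == pytest.approx(1.02, abs=1e-9)


def test_dimension_score_examples(value_set):
    assert dimension_score(_response(1), "pain", value_set) == pytest.approx(0.11)
    assert dimension_score(_response(5), "sleep", value_set) == pytest.approx(-0.05)
    assert dimension_score(_response(3), "pain", _zero_set()) == 0.0
    with pytest.raises(Chu9dError):
        dimension_score(_response(1), "appetite", value_set)


@settings(max_examples=100, deadline=None)
@given(
    levels=st.lists(st.integers(1, 5), min_size=9, max_size=9),
    dim_idx=st.integers(0, 8),
    new_level=st.integers(1, 5),
)
def test_single_dimension_change_moves_utility_by_weight_delta(
    levels, dim_idx, new_level
):
    value_set = _DEFAULT_SET
    resp = Chu9dResponse(dict(zip(DIMENSIONS, levels)))
    changed = dict(zip(DIMENSIONS, levels))
    d = DIMENSIONS[dim_idx]
    changed[d] = new_level
    delta = score_utility(Chu9dResponse(changed), value_set) - score_utility(
        resp, value_set
    )
    expected = value_set.weights[(d, new_level)] - value_set.weights[(d, levels[dim_idx])]
    assert delta == pytest.approx(expected, abs=1e-12)
    # monotone set: worsening a single dimension never increases utility
    if new_level >= levels[dim_idx]:
        assert delta <= 1e-12


def test_response_validation():
    with pytest.raises(Chu9dError):
        Chu9dResponse({d: 1 for d in DIMENSIONS[:-1]})
    with pytest.raises(Chu9dError):
        Chu9dResponse({**{d: 1 for d in DIMENSIONS}, "pain": 6})


def test_load_value_set_rejects_missing_cell_and_non_monotone(value_set):
    frame = value_set.to_frame()
    with pytest.raises(Chu9dError, match="missing cells"):
        load_value_set(frame[~((frame.dimension == "pain") & (frame.level == 3))])
    bad = frame.copy()
    bad.loc[(bad.dimension == "worry") & (bad.level == 5), "weight"] = 0.5
    with pytest.raises(Chu9dError, match="increase with level"):
        load_value_set(bad)
    vs = load_value_set(bad, allow_non_monotone=True)
    assert vs.weights[("worry", 5)] == 0.5
    # constant-zero table is a valid degenerate set scoring everything 0
    zero = frame.assign(weight=0.0)
    assert score_utility(_response(3), load_value_set(zero)) == 0.0


def test_incomplete_response_scores_missing_not_zero(value_set):
    assert np.isnan(score_utility(None, value_set))
    df = pd.DataFrame(
        [
            {"chu9d_complete": True, **{f"chu9d_{d}": 1 for d in DIMENSIONS}},
            {"chu9d_complete": False, **{f"chu9d_{d}": np.nan for d in DIMENSIONS}},
        ]
    )
    scored = score_cohort(df, value_set)
    assert scored.iloc[0] == pytest.approx(1.02)
    assert np.isnan(scored.iloc[1])


def test_dimension_summary_degenerate_groups(value_set):
    base = {f"chu9d_{d}": 2 for d in DIMENSIONS}
    df = pd.DataFrame(
        [
            {"delay_group": "lt6", "chu9d_complete": True, **base},
            {"delay_group": "lt6", "chu9d_complete": True, **base},
            {"delay_group": "ge6plus", "chu9d_complete": True, **base},
            {"delay_group": "ge6plus", "chu9d_complete": True, **base},
        ]
    )
    out = dimension_summary(df, value_set)
    # identical groups: zero differences, p = 1 everywhere
    assert np.allclose(out["mean_lt6"], out["mean_ge6"])
    assert np.allclose(out["p_value"], 1.0)
    # single-participant groups: means reported, p missing
    single = dimension_summary(df.iloc[[0, 2]], value_set)
    assert single["p_value"].isna().all()
    assert single["mean_lt6"].notna().all()


def test_dimension_summary_recovers_calibrated_group_means(big_cohort, value_set):
    out = dimension_summary(big_cohort, value_set)
    row = out.loc["overall"]
    se_lt6 = row.sd_lt6 / np.sqrt(row.n_lt6)
    se_ge6 = row.sd_ge6 / np.sqrt(row.n_ge6)
    assert abs(row.mean_lt6 - 0.59) < 3 * se_lt6
    assert abs(row.mean_ge6 - 0.44) < 3 * se_ge6
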