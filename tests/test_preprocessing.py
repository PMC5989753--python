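import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogebm.battery import BiomarkerSpec, DECREASING, INCREASING
from cogebm.exceptions import ConfigurationError, PreprocessingError
from cogebm.preprocessing import (
    fit_residual_model,
    impute_performance_scores,
    impute_questionnaire_items,
    preprocess,
    residualize,
)

TWO_TESTS = (
    BiomarkerSpec("fluency", 0, np.inf, DECREASING, "direct_test"),
    BiomarkerSpec(
        "srt_mean_latency", 0, np.inf, INCREASING, "direct_test", integer_valued=False
    ),
)


def make_cohort(rows):
    defaults = {
        "participant_id": None,
        "age_group": "YA",
        "id_level": "mild",
        "fluency": np.nan,
        "fluency__engagement": "completed",
        "srt_mean_latency": np.nan,
        "srt_mean_latency__engagement": "completed",
    }
    records = []
    for i, row in enumerate(rows):
        record = dict(defaults)
        record["participant_id"] = f"P{i}"
        record.update(row)
        records.append(record)
    return pd.DataFrame(records)


# --- performance-score imputation ------------------------------------------


def test_not_understood_scores_zero():
    cohort = make_cohort(
        [
            {"fluency": 12.0},
            {"fluency__engagement": "attempted_not_understood"},
            {"srt_mean_latency": 900.0},
        ]
    )
    out = impute_performance_scores(cohort, TWO_TESTS)
    assert out.loc[1, "fluency"] == 0.0


def test_not_understood_srt_gets_worst_recorded_latency():
    cohort = make_cohort(
        [
            {"srt_mean_latency": 1800.0},
            {"srt_mean_latency": 2500.0},
            {"srt_mean_latency__engagement": "attempted_not_understood"},
        ]
    )
    out = impute_performance_scores(cohort, TWO_TESTS)
    assert out.loc[2, "srt_mean_latency"] == 2500.0


def test_all_completed_is_identity():
    cohort = make_cohort([{"fluency": 5.0, "srt_mean_latency": 700.0}] * 4)
    out = impute_performance_scores(cohort, TWO_TESTS)
    pd.testing.assert_frame_equal(out, cohort)


def test_not_attempted_stays_missing():
    cohort = make_cohort(
        [{"fluency": 3.0}, {"fluency__engagement": "not_attempted"}]
    )
    out = impute_performance_scores(cohort, TWO_TESTS)
    assert np.isnan(out.loc[1, "fluency"])


def test_srt_imputation_without_completed_latencies_errors():
    cohort = make_cohort(
        [{"srt_mean_latency__engagement": "attempted_not_understood"}]
    )
    with pytest.raises(PreprocessingError):
        impute_performance_scores(cohort, TWO_TESTS)


# --- questionnaire item imputation ------------------------------------------


def test_single_missing_item_imputed_to_nearest_integer():
    items = [3, 4, 3, 4, 3, 4, 3, 4, 3, np.nan]
    completed_mean = np.nanmean(items)  # independently: 31/9 = 3.44...
    out = impute_questionnaire_items(items)
    assert out[-1] == round(completed_mean) == 3


def test_mean_of_three_point_four_rounds_to_three():
    items = [3.4] * 9 + [np.nan]
    out = impute_questionnaire_items(items)
    assert out[-1] == 3.0


def test_half_rounds_away_from_zero():
    out = impute_questionnaire_items([2, 3, np.nan], max_missing_frac=0.5)  # mean 2.5
    assert out[-1] == 3.0
    out = impute_questionnaire_items([-2, -3, np.nan], max_missing_frac=0.5)
    assert out[-1] == -3.0


def test_thirty_percent_missing_marks_domain_missing():
    items = [1, 2, 3, 4, 5, 6, 7, np.nan, np.nan, np.nan]
    assert impute_questionnaire_items(items) is None


def test_exactly_fifteen_percent_is_allowed():
    items = [2.0] * 17 + [np.nan] * 3  # 3/20 = 15%
    out = impute_questionnaire_items(items)
    assert out is not None
    assert (out[-3:] == 2.0).all()


def test_no_missing_is_identity():
    items = np.array([1.0, 2.0, 3.0])
    out = impute_questionnaire_items(items)
    np.testing.assert_array_equal(out, items)


def test_all_missing_marks_domain_missing():
    assert impute_questionnaire_items([np.nan, np.nan]) is None


def test_bad_threshold_rejected():
    with pytest.raises(ConfigurationError):
        impute_questionnaire_items([1.0, np.nan], max_missing_frac=0.0)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=6), min_size=4, max_size=20),
    st.integers(min_value=0, max_value=2),
)
def test_completed_items_never_change(values, n_missing):
    items = np.array(values, dtype=float)
    items[:n_missing] = np.nan
    out = impute_questionnaire_items(items, max_missing_frac=0.5)
    if out is not None:
        np.testing.assert_array_equal(out[n_missing:], items[n_missing:])


# --- residual model ----------------------------------------------------------

ONE_TEST = (BiomarkerSpec("score", 0, 100, DECREASING, "direct_test"),)


def residual_cohort(levels, scores, age_group="YA"):
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(len(levels))],
            "age_group": age_group,
            "id_level": levels,
            "score": scores,
            "score__engagement": "completed",
        }
    )


def test_closed_form_simple_regression():
    # mild: 10,10  moderate: 6,6  severe: 2,2 under coding 1/2/3
    cohort = residual_cohort(
        ["mild", "mild", "moderate", "moderate", "severe", "severe"],
        [10.0, 10.0, 6.0, 6.0, 2.0, 2.0],
    )
    model = fit_residual_model(cohort, ONE_TEST)
    intercept, slope = model.coefficients["score"]
    assert intercept == pytest.approx(14.0)
    assert slope == pytest.approx(-4.0)


def test_perfectly_linear_scores_reproduced():
    cohort = residual_cohort(["mild", "moderate", "severe"], [9.0, 7.0, 5.0])
    model = fit_residual_model(cohort, ONE_TEST)
    for level, score in zip(["mild", "moderate", "severe"], [9.0, 7.0, 5.0]):
        assert model.predict("score", level) == pytest.approx(score)


def test_constant_scores_zero_slope():
    cohort = residual_cohort(["mild", "moderate", "severe", "mild"], [4.0] * 4)
    model = fit_residual_model(cohort, ONE_TEST)
    intercept, slope = model.coefficients["score"]
    assert intercept == pytest.approx(4.0)
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_too_few_rows_errors_with_biomarker_name():
    cohort = residual_cohort(["mild", "severe"], [4.0, 2.0])
    with pytest.raises(PreprocessingError, match="score"):
        fit_residual_model(cohort, ONE_TEST)


def test_single_level_errors():
    cohort = residual_cohort(["mild"] * 5, [4.0, 5.0, 4.0, 5.0, 4.0])
    with pytest.raises(PreprocessingError, match="distinct ID levels"):
        fit_residual_model(cohort, ONE_TEST)


def test_only_ya_rows_used():
    ya = residual_cohort(["mild", "moderate", "severe"], [9.0, 7.0, 5.0])
    oa = residual_cohort(["mild", "moderate", "severe"], [0.0, 0.0, 0.0], "OA")
    cohort = pd.concat([ya, oa], ignore_index=True)
    model = fit_residual_model(cohort, ONE_TEST)
    assert model.predict("score", "mild") == pytest.approx(9.0)
    assert model.fitted_on == "YA"


def test_dummy_coding_predicts_level_means():
    cohort = residual_cohort(
        ["mild", "mild", "moderate", "moderate", "severe", "severe"],
        [10.0, 12.0, 6.0, 8.0, 2.0, 2.0],
    )
    model = fit_residual_model(cohort, ONE_TEST, coding="dummy")
    assert model.predict("score", "mild") == pytest.approx(11.0)
    assert model.predict("score", "moderate") == pytest.approx(7.0)
    assert model.predict("score", "severe") == pytest.approx(2.0)


# --- residualization ---------------------------------------------------------


def test_residual_arithmetic():
    ya = residual_cohort(["mild", "moderate", "severe"], [9.0, 7.0, 5.0])
    oa = residual_cohort(["mild"], [5.0], "OA")
    oa["participant_id"] = ["Q0"]
    cohort = pd.concat([ya, oa], ignore_index=True)
    model = fit_residual_model(cohort, ONE_TEST)
    out = residualize(cohort, model, ONE_TEST)
    # OA participant scores 5 where the model predicts 9 at mild
    assert out.loc[3, "score"] == pytest.approx(-4.0)
    # YA rows on the fitted line have residual 0
    assert out.loc[0, "score"] == pytest.approx(0.0, abs=1e-12)


def test_ya_per_level_residual_means_are_zero():
    rng = np.random.default_rng(0)
    levels = rng.choice(["mild", "moderate", "severe"], size=60)
    scores = 10.0 - 2.0 * np.array(
        [{"mild": 1, "moderate": 2, "severe": 3}[lv] for lv in levels]
    ) + rng.normal(0, 1, 60)
    cohort = residual_cohort(levels, scores)
    model = fit_residual_model(cohort, ONE_TEST, coding="dummy")
    out = residualize(cohort, model, ONE_TEST)
    for level in ("mild", "moderate", "severe"):
        assert out.loc[out.id_level == level, "score"].mean() == pytest.approx(
            0.0, abs=1e-9
        )


def test_missingness_pattern_and_row_count_preserved():
    cohort = residual_cohort(
        ["mild", "moderate", "severe", "mild"], [9.0, 7.0, np.nan, 8.0]
    )
    model = fit_residual_model(cohort, ONE_TEST)
    out = residualize(cohort, model, ONE_TEST)
    assert len(out) == len(cohort)
    pd.testing.assert_series_equal(out["score"].isna(), cohort["score"].isna())


def test_unknown_id_level_gives_missing_residual(caplog):
    cohort = residual_cohort(["mild", "moderate", "severe", "unknown"],
                             [9.0, 7.0, 5.0, 6.0])
    model = fit_residual_model(cohort, ONE_TEST)
    with caplog.at_level(logging.WARNING):
        out = residualize(cohort, model, ONE_TEST)
    assert np.isnan(out.loc[3, "score"])
    assert "unknown ID level" in caplog.text


def test_preprocess_chains_imputation_and_residualization():
    cohort = residual_cohort(
        ["mild", "moderate", "severe", "mild"], [9.0, 7.0, 5.0, np.nan]
    )
    cohort.loc[3, "score__engagement"] = "attempted_not_understood"
    out, model = preprocess(cohort, ONE_TEST)
    # the imputed zero is residualized like any other score
    assert out.loc[3, "score"] == pytest.approx(0.0 - model.predict("score", "mild"))
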