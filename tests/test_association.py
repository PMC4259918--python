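import numpy as np
import pandas as pd
import pytest

from portalusage import (
    CensusSpec,
    HurdleLogit,
    build_hurdle_cohort,
    compare_to_reference,
    eliminate_factors,
    fit_factor_model,
)
from portalusage.association import derive_covariates
from portalusage.errors import SeparationError, ValidationError

from conftest import CENSUS


def _two_by_two(a, b, c, d):
    """Outcome x binary covariate table:
    exposed:   a events / b non-events; unexposed: c events / d non-events."""
    y = pd.Series([1] * a + [0] * b + [1] * c + [0] * d, name="outcome")
    x = pd.DataFrame(
        {"patient_id": [f"p{i}" for i in range(a + b + c + d)],
         "exposed": ["yes"] * (a + b) + ["no"] * (c + d)}
    )
    return y, x


def test_or_equals_cross_product_example():
    # OR = (10*30)/(20*40) = 0.375
    y, x = _two_by_two(10, 20, 40, 30)
    res = fit_factor_model(y, x, references={"exposed": "no"})
    assert res.odds_ratio("exposed", "yes") == pytest.approx(0.375, rel=1e-6)


def test_or_equals_cross_product_random_tables():
    rng = np.random.default_rng(55)
    for _ in range(15):
        a, b, c, d = rng.integers(1, 50, 4)
        y, x = _two_by_two(int(a), int(b), int(c), int(d))
        res = fit_factor_model(y, x, references={"exposed": "no"})
        assert res.odds_ratio("exposed", "yes") == pytest.approx(
            (a * d) / (b * c), rel=1e-5
        )


def test_wald_ci_contains_point_estimate():
    y, x = _two_by_two(12, 33, 21, 44)
    res = fit_factor_model(y, x, references={"exposed": "no"})
    row = res.table.iloc[0]
    assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]


def test_separation_detected_and_named():
    y = pd.Series([1, 1, 1, 0, 0, 0], name="outcome")
    x = pd.DataFrame({"patient_id": list("abcdef"),
                      "grp": ["u", "u", "u", "v", "v", "v"]})
    with pytest.raises(SeparationError, match="grp"):
        fit_factor_model(y, x)


def test_constant_outcome_rejected():
    y = pd.Series([1, 1, 1, 1], name="outcome")
    x = pd.DataFrame({"patient_id": list("abcd"), "grp": ["u", "v", "u", "v"]})
    with pytest.raises(SeparationError):
        fit_factor_model(y, x)


def _simulated(n, rng, beta_signal=1.2):
    signal = rng.integers(0, 2, n)
    noise = rng.choice(["x", "y", "z"], n)
    p = 1 / (1 + np.exp(-(-1.0 + beta_signal * signal)))
    y = pd.Series((rng.random(n) < p).astype(int), name="outcome")
    x = pd.DataFrame(
        {"patient_id": [f"p{i}" for i in range(n)],
         "signal": np.where(signal == 1, "hi", "lo"),
         "noise": noise}
    )
    return y, x


def test_elimination_drops_noise_keeps_signal():
    y, x = _simulated(3000, np.random.default_rng(11))
    res = eliminate_factors(y, x, references={"signal": "lo", "noise": "x"})
    assert "noise" in res.removed
    assert res.retained == ["signal"]
    assert res.removed["noise"] > 0.05


def test_elimination_all_null_gives_intercept_only():
    y, x = _simulated(2000, np.random.default_rng(7), beta_signal=0.0)
    res = eliminate_factors(y, x, references={"signal": "lo", "noise": "x"})
    assert res.retained == []
    assert set(res.removed) == {"signal", "noise"}


def test_elimination_threshold_extremes():
    y, x = _simulated(1500, np.random.default_rng(31))
    # alpha = 0: every removal p exceeds it -> everything is eliminated
    strip = eliminate_factors(y, x, references={"signal": "lo", "noise": "x"}, alpha=0.0)
    assert strip.retained == []
    # alpha = 1: no p can exceed it -> the full model is retained
    keep = eliminate_factors(y, x, references={"signal": "lo", "noise": "x"}, alpha=1.0)
    assert set(keep.retained) == {"signal", "noise"}


def test_compare_to_reference_equal_proportions():
    out = compare_to_reference([20, 40], [100, 200])
    assert out["chi_square"] == pytest.approx(0.0, abs=1e-9)
    assert out["p"] == pytest.approx(1.0)


def test_compare_to_reference_hand_computed():
    out = compare_to_reference([30, 10], [100, 100])
    assert out["chi_square"] == pytest.approx(12.5)
    assert out["df"] == 1
    assert np.allclose(out["proportions"], [0.3, 0.1])


def test_compare_to_reference_single_stratum_and_validation():
    out = compare_to_reference([30], [100])
    assert out["df"] == 0 and out["chi_square"] is None and out["p"] is None
    with pytest.raises(ValidationError):
        compare_to_reference([101], [100])


def test_hurdle_cohorts_from_fixture(printed_fixture):
    from portalusage import ClassificationParams, CohortRestriction, classify_cohort

    classes = classify_cohort(
        printed_fixture, CENSUS,
        ClassificationParams(cohort_restriction=CohortRestriction.FIRST_LOGON_3M),
    )
    y1, x1 = build_hurdle_cohort(classes, printed_fixture.patients,
                                 "not_complete_first_logon")
    assert int(y1.sum()) == 2634 and len(y1) == 11352
    y2, _ = build_hurdle_cohort(classes, printed_fixture.patients, "early_lapse")
    assert int(y2.sum()) == 822 and len(y2) == 8249
    y3, _ = build_hurdle_cohort(classes, printed_fixture.patients, "late_lapse")
    assert int(y3.sum()) == 1404 and len(y3) == 1404 + 6023


def test_complete_case_drop_shrinks_n_only(printed_fixture):
    from portalusage import ClassificationParams, CohortRestriction, classify_cohort

    classes = classify_cohort(
        printed_fixture, CENSUS,
        ClassificationParams(cohort_restriction=CohortRestriction.FIRST_LOGON_3M),
    )
    patients = printed_fixture.patients.copy()
    y_full, _ = build_hurdle_cohort(classes, patients, "late_lapse")
    # blank treatment for a slice of persistent users (the tail of the table)
    patients.loc[patients.index[-500:], "treatment"] = None
    y_cc, x_cc = build_hurdle_cohort(classes, patients, "late_lapse")
    assert len(y_cc) < len(y_full)
    # outcome construction unchanged: rates agree up to the dropped rows
    assert set(x_cc.columns) >= {"patient_id", "treatment", "age_band"}


def test_hurdle_logit_end_to_end(printed_fixture):
    from portalusage import ClassificationParams, CohortRestriction, classify_cohort

    classes = classify_cohort(
        printed_fixture, CENSUS,
        ClassificationParams(cohort_restriction=CohortRestriction.FIRST_LOGON_3M),
    )
    model = HurdleLogit(classes, printed_fixture.patients, "late_lapse")
    res = model.fit(eliminate=False)
    assert res.n_complete_case == 1404 + 6023
    assert (res.table["odds_ratio"] > 0).all()
    assert (res.table["ci_low"] <= res.table["odds_ratio"]).all()
    assert "Hurdle logistic model" in res.summary()


def test_derive_covariates_center_factors(printed_fixture):
    cov = derive_covariates(printed_fixture.patients, printed_fixture.centers, CENSUS)
    assert set(cov["center_rate_quartile"].dropna()) <= {"Q1", "Q2", "Q3", "Q4"}
    assert cov["assisted_start"].dtype == bool
    assert {"age_band", "deprivation_group"} <= set(cov.columns)
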