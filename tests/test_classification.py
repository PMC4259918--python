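import numpy as np
import pandas as pd
import pytest

from portalusage import (
    ClassificationParams,
    CohortRestriction,
    UsageClass,
    classify_cohort,
    classify_user,
    completed_first_logon,
    first_logon_date,
)
from portalusage.errors import ValidationError

from conftest import CENSUS, build_cohort

REG = pd.Timestamp("2008-09-07")  # 12 months before census
PATIENT = pd.Series({"patient_id": "p1", "registration_date": REG})


def _classify(logons, results, params=ClassificationParams(), patient=PATIENT):
    return classify_user(
        patient,
        pd.to_datetime(pd.Series(logons, dtype="datetime64[ns]")),
        pd.to_datetime(pd.Series(results, dtype="datetime64[ns]")),
        CENSUS,
        params,
    )


def test_first_logon_date():
    assert first_logon_date(np.array([], dtype="datetime64[ns]")) is None
    stream = pd.to_datetime(["2008-01-05 10:00"]).to_numpy()
    assert first_logon_date(stream) == pd.Timestamp("2008-01-05")
    stream = pd.to_datetime(
        ["2008-01-05 10:00", "2008-02-01 08:00", "2008-03-02 12:00"]
    ).to_numpy()
    assert first_logon_date(stream) == pd.Timestamp("2008-01-05")


def test_completed_first_logon():
    assert not completed_first_logon(np.array([], dtype="datetime64[ns]"))
    assert completed_first_logon(pd.to_datetime(["2008-01-05"]).to_numpy())


def test_never_logged_on():
    assert _classify([], ["2009-01-01", "2009-04-01"]) is UsageClass.NEVER_LOGGED_ON


def test_early_lapser_first_month_only():
    # logons on days 2 and 20 post-registration, 4 later results
    cls = _classify(
        ["2008-09-09 10:00", "2008-09-27 18:00"],
        ["2008-11-01", "2009-01-01", "2009-03-01", "2009-05-01"],
    )
    assert cls is UsageClass.EARLY_LAPSER


def test_early_window_day_30_inclusive():
    cls = _classify(["2008-09-09 10:00", "2008-10-07 10:00"], ["2009-01-01", "2009-05-01"])
    assert cls is UsageClass.EARLY_LAPSER  # day 30 still counts as first month
    cls = _classify(["2008-09-09 10:00", "2008-10-08 10:00"], [])
    assert cls is not UsageClass.EARLY_LAPSER  # day 31 does not


def test_late_lapser_boundary_on_result_count():
    # last logon 7 months before census
    logons = ["2008-09-20 09:00", "2009-02-07 09:00"]
    late = _classify(logons, ["2009-04-01", "2009-06-01"])
    assert late is UsageClass.LATE_LAPSER  # exactly 2 results after last logon
    persistent = _classify(logons, ["2009-04-01"])
    assert persistent is UsageClass.PERSISTENT_USER  # only 1 result after


def test_result_on_last_logon_day_does_not_count():
    logons = ["2008-09-20 09:00", "2009-02-07 09:00"]
    cls = _classify(logons, ["2009-02-07", "2009-06-01"])
    assert cls is UsageClass.PERSISTENT_USER


def test_six_month_gap_boundary_inclusive():
    # gap of exactly 6 analysis months (182.625 days -> 183 whole days) lapses
    last = CENSUS.census_date - pd.Timedelta(days=183)
    cls = _classify(
        ["2008-09-20 09:00", last.strftime("%Y-%m-%d %H:%M")],
        ["2009-05-01", "2009-07-01"],
    )
    assert cls is UsageClass.LATE_LAPSER


def test_priority_early_beats_late():
    """A single first-month logon with >= 2 later results and a long gap
    satisfies both the early and late rules; early wins by rule order."""
    cls = _classify(["2008-09-09 10:00"], ["2009-01-01", "2009-03-01"])
    assert cls is UsageClass.EARLY_LAPSER


def test_insufficient_follow_up_registration_rule():
    patient = pd.Series(
        {"patient_id": "p1",
         "registration_date": CENSUS.census_date - pd.Timedelta(days=100)}
    )
    cls = _classify(["2009-06-15 10:00"], [], patient=patient)
    assert cls is UsageClass.INSUFFICIENT_FOLLOW_UP


def test_first_logon_restriction():
    params = ClassificationParams(cohort_restriction=CohortRestriction.FIRST_LOGON_3M)
    # first logon 2 months before census -> insufficient
    cls = _classify(["2009-07-07 10:00"], [], params=params)
    assert cls is UsageClass.INSUFFICIENT_FOLLOW_UP
    # zero logons remain classifiable as never under this restriction
    assert _classify([], [], params=params) is UsageClass.NEVER_LOGGED_ON


def test_census_before_registration_rejected():
    patient = pd.Series(
        {"patient_id": "p1", "registration_date": pd.Timestamp("2010-01-01")}
    )
    with pytest.raises(ValidationError):
        _classify([], [], patient=patient)


def _toy_cohort():
    return build_cohort(
        [
            ("never", "2008-01-01", 50.0, "male", "transplant", 5, "C0"),
            ("early", "2008-01-01", 50.0, "male", "transplant", 5, "C0"),
            ("late", "2008-01-01", 50.0, "male", "transplant", 5, "C0"),
            ("persistent", "2008-01-01", 50.0, "male", "transplant", 5, "C0"),
        ],
        [
            ("early", "2008-01-05 10:00"),
            ("late", "2008-01-05 10:00"), ("late", "2008-06-01 10:00"),
            ("persistent", "2008-01-05 10:00"), ("persistent", "2009-08-01 10:00"),
        ],
        [
            ("late", "2009-01-01"), ("late", "2009-05-01"),
            ("persistent", "2009-01-01"),
        ],
    )


def test_classify_cohort_partition_and_counts():
    classes = classify_cohort(_toy_cohort(), CENSUS)
    assert len(classes) == 4
    expected = {
        "never": UsageClass.NEVER_LOGGED_ON.value,
        "early": UsageClass.EARLY_LAPSER.value,
        "late": UsageClass.LATE_LAPSER.value,
        "persistent": UsageClass.PERSISTENT_USER.value,
    }
    got = dict(zip(classes["patient_id"], classes["usage_class"]))
    assert got == expected
    assert sum(classes.attrs["counts"].values()) == 4


def test_classify_cohort_order_independent():
    cohort = _toy_cohort()
    shuffled = build_cohort(
        list(cohort.patients.iloc[::-1].itertuples(index=False, name=None)),
        list(cohort.logons.iloc[::-1].itertuples(index=False, name=None)),
        list(cohort.results.iloc[::-1].itertuples(index=False, name=None)),
    )
    a = classify_cohort(cohort, CENSUS).set_index("patient_id")["usage_class"]
    b = classify_cohort(shuffled, CENSUS).set_index("patient_id")["usage_class"]
    assert a.sort_index().equals(b.sort_index())


def test_monotonicity_recent_logon_rescues_late_lapser():
    logons = ["2008-09-20 09:00", "2009-01-07 09:00"]
    results = ["2009-04-01", "2009-06-01"]
    assert _classify(logons, results) is UsageClass.LATE_LAPSER
    rescued = _classify(logons + ["2009-08-15 09:00"], results)
    assert rescued is UsageClass.PERSISTENT_USER


def test_empty_cohort_all_counts_zero():
    cohort = build_cohort([], [], [])
    classes = classify_cohort(cohort, CENSUS)
    assert len(classes) == 0
    assert all(v == 0 for v in classes.attrs["counts"].values())
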