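"""Five-way lifecycle classification of portal registrants.

Every registrant is assigned exactly one label from their logon and
result streams relative to the census date:

1. ``insufficient_follow_up`` — too little observation time to call a
   pattern (see ``cohort_restriction`` below);
2. ``never_logged_on`` — registered but zero logons;
3. ``early_lapser`` — all logons within the first month (30 days,
   inclusive) after registration;
4. ``late_lapser`` — no logon in the 6 months before census AND at least
   2 result uploads strictly after the last logon (continued arrival of
   results implies the patient was alive and still monitored, so silence
   is read as abandonment);
5. ``persistent_user`` — everyone else, i.e. still in use at census.

Rules are applied in that priority order: a patient with a single
first-week logon, nothing since and many later results satisfies both (3)
and (4) and is an early lapser.

Two observation-window restrictions exist and are selected by
``ClassificationParams.cohort_restriction``:

* ``registration_6m`` — registrants enrolled within 6 months of census
  are insufficient-follow-up (the flow-diagram rule);
* ``first_logon_3m`` — registrants whose *first logon* falls within 3
  months of census are insufficient-follow-up (the rule used for all
  lapse analyses; patients with zero logons are still ``never_logged_on``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import (
    DAY,
    FIRST_MONTH_DAYS,
    MONTH_DAYS,
    CensusSpec,
    Cohort,
)


class UsageClass(str, enum.Enum):
    INSUFFICIENT_FOLLOW_UP = "insufficient_follow_up"
    NEVER_LOGGED_ON = "never_logged_on"
    EARLY_LAPSER = "early_lapser"
    LATE_LAPSER = "late_lapser"
    PERSISTENT_USER = "persistent_user"


class CohortRestriction(str, enum.Enum):
    REGISTRATION_6M = "registration_6m"
    FIRST_LOGON_3M = "first_logon_3m"


@dataclass(frozen=True)
class ClassificationParams:
    """Tunable rule boundaries for the lifecycle classification.

    All windows are measured with the 30.4375-day analysis month except
    ``early_window_days`` which is exact days. Boundary conventions:
    enrolment exactly at the follow-up limit counts as insufficient
    ("within"); a logon on day 30 is still first-month; a last-logon gap of
    exactly 6 months counts as lapsed; a result dated the same day as the
    last logon does not count toward ``late_min_results``.
    """

    min_followup_months: float = 6.0
    early_window_days: float = FIRST_MONTH_DAYS
    late_gap_months: float = 6.0
    late_min_results: int = 2
    cohort_restriction: CohortRestriction = CohortRestriction.REGISTRATION_6M
    first_logon_window_months: float = 3.0
    month_days: float = MONTH_DAYS


def first_logon_date(logons: np.ndarray | pd.Series) -> pd.Timestamp | None:
    """Date of the earliest logon in a sorted stream, or None if empty."""
    arr = np.asarray(logons)
    if arr.size == 0:
        return None
    return pd.Timestamp(arr[0]).normalize()


def completed_first_logon(logons: np.ndarray | pd.Series) -> bool:
    """True iff the registrant ever logged on."""
    return np.asarray(logons).size > 0


def _classify_stream(
    registration: np.datetime64,
    logon_times: np.ndarray,
    result_dates: np.ndarray,
    census: np.datetime64,
    params: ClassificationParams,
) -> UsageClass:
    # Core rule engine on raw numpy datetimes; callers pre-sort streams.
    if census < registration:
        raise ValidationError("census date precedes registration date")
    month = params.month_days

    if params.cohort_restriction is CohortRestriction.REGISTRATION_6M:
        if (census - registration) / DAY <= params.min_followup_months * month:
            return UsageClass.INSUFFICIENT_FOLLOW_UP

    if logon_times.size == 0:
        return UsageClass.NEVER_LOGGED_ON

    # interval arithmetic on calendar dates (registration and census are
    # date-valued; logon times-of-day do not move rule boundaries)
    first = np.datetime64(pd.Timestamp(logon_times[0]).normalize())
    last_date = np.datetime64(pd.Timestamp(logon_times[-1]).normalize())

    if params.cohort_restriction is CohortRestriction.FIRST_LOGON_3M:
        if (census - first) / DAY <= params.first_logon_window_months * month:
            return UsageClass.INSUFFICIENT_FOLLOW_UP

    if (last_date - registration) / DAY <= params.early_window_days:
        return UsageClass.EARLY_LAPSER

    gap_days = (census - last_date) / DAY
    n_results_after = int(np.sum(result_dates > last_date))
    if gap_days >= params.late_gap_months * month and n_results_after >= params.late_min_results:
        return UsageClass.LATE_LAPSER
    return UsageClass.PERSISTENT_USER


def classify_user(
    patient: pd.Series,
    logons: np.ndarray | pd.Series,
    results: np.ndarray | pd.Series,
    census: CensusSpec,
    params: ClassificationParams = ClassificationParams(),
) -> UsageClass:
    """Classify one registrant.

    ``patient`` is a row of the patients table (needs
    ``registration_date``); ``logons``/``results`` are that patient's
    sorted streams (datetime64 arrays or datetime Series).
    """
    logon_times = pd.to_datetime(pd.Series(np.asarray(logons))).to_numpy()
    result_dates = pd.to_datetime(pd.Series(np.asarray(results))).dt.normalize().to_numpy()
    return _classify_stream(
        np.datetime64(pd.Timestamp(patient["registration_date"])),
        np.sort(logon_times),
        np.sort(result_dates),
        np.datetime64(census.census_date),
        params,
    )


def classify_cohort(
    cohort: Cohort,
    census: CensusSpec,
    params: ClassificationParams = ClassificationParams(),
) -> pd.DataFrame:
    """Classify every registrant in a cohort.

    Returns a DataFrame indexed like the patients table with columns
    ``patient_id`` and ``usage_class``. Per-class counts and percentages
    (to 2 decimals, of the whole cohort) are attached as
    ``result.attrs["counts"]`` / ``attrs["percentages"]``; counts always
    sum to the number of patients.
    """
    logon_map = cohort.logons_by_patient()
    result_map = cohort.results_by_patient()
    census_dt = np.datetime64(census.census_date)
    empty = np.array([], dtype="datetime64[ns]")

    labels = []
    for pid, reg in zip(
        cohort.patients["patient_id"].to_numpy(),
        cohort.patients["registration_date"].to_numpy(),
    ):
        cls = _classify_stream(
            reg,
            logon_map.get(pid, empty),
            result_map.get(pid, empty),
            census_dt,
            params,
        )
        labels.append(cls.value)

    out = pd.DataFrame(
        {"patient_id": cohort.patients["patient_id"].to_numpy(), "usage_class": labels}
    )
    counts = {c.value: int((out["usage_class"] == c.value).sum()) for c in UsageClass}
    n = len(out)
    out.attrs["counts"] = counts
    out.attrs["percentages"] = {
        k: round(100.0 * v / n, 2) if n else 0.0 for k, v in counts.items()
    }
    return out


def class_counts(classes: pd.DataFrame) -> dict[str, int]:
    """Per-class counts from a classify_cohort output (recomputed, not cached)."""
    return {c.value: int((classes["usage_class"] == c.value).sum()) for c in UsageClass}
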