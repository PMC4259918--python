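"""Logon-intensity metrics: rates, log-scale quartiles, heavy-user flag,
and weekday / hour-of-day profiles.

Intensity is logons per 30.4375-day month under one of two denominators:

* ``registration_to_census`` — total logons / months from registration to
  census (defined for any registrant with >= 1 logon);
* ``first_to_last_logon`` — total logons / months spanned by the logon
  stream itself, restricted to users with at least three logons over at
  least 3 months (the "span-eligible" established users).

Because log(logons per month) is close to normal across a cohort, users
are ranked into quartiles Q1-Q4 of log intensity (Q4 heaviest); the top
5% by raw rate are flagged separately.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import DAY, MONTH_DAYS, CensusSpec, Cohort


class Denominator(str, enum.Enum):
    REGISTRATION_TO_CENSUS = "registration_to_census"
    FIRST_TO_LAST_LOGON = "first_to_last_logon"


@dataclass(frozen=True)
class ActivityProfile:
    patient_id: str
    logons_total: int
    denominator_months: float
    logons_per_month: float
    log_lpm: float
    quartile: str | None = None
    top5: bool | None = None


def logons_per_month(
    patient: pd.Series,
    logons: np.ndarray | pd.Series,
    census: CensusSpec,
    denominator: Denominator = Denominator.REGISTRATION_TO_CENSUS,
    min_span_months: float = 3.0,
    min_logons: int = 3,
    month_days: float = MONTH_DAYS,
) -> float:
    """Logon rate for one registrant under the chosen denominator.

    Under ``first_to_last_logon`` the eligibility precondition (>=
    ``min_logons`` logons spanning >= ``min_span_months`` months) is
    enforced and a :class:`ValidationError` marks ineligible patients —
    an exclusion signal for the caller, not a data corruption.
    """
    times = np.sort(pd.to_datetime(pd.Series(np.asarray(logons))).to_numpy())
    if times.size == 0:
        raise ValidationError("logons_per_month needs at least one logon")
    if denominator is Denominator.REGISTRATION_TO_CENSUS:
        months = (
            np.datetime64(census.census_date)
            - np.datetime64(pd.Timestamp(patient["registration_date"]))
        ) / DAY / month_days
    else:
        months = (times[-1] - times[0]) / DAY / month_days
        if times.size < min_logons or months < min_span_months:
            raise ValidationError(
                f"patient ineligible for span denominator: "
                f"{times.size} logons over {months:.2f} months"
            )
    if months <= 0:
        raise ValidationError("zero-length denominator; patient excluded")
    return float(times.size / months)


def span_eligible(
    logons: np.ndarray,
    min_logons: int = 3,
    min_span_months: float = 3.0,
    month_days: float = MONTH_DAYS,
) -> bool:
    """True iff a sorted logon stream has >= min_logons logons spanning
    >= min_span_months months (first to last)."""
    if logons.size < min_logons:
        return False
    return (logons[-1] - logons[0]) / DAY / month_days >= min_span_months


def activity_profiles(
    cohort: Cohort,
    census: CensusSpec,
    denominator: Denominator = Denominator.REGISTRATION_TO_CENSUS,
    min_span_months: float = 3.0,
    min_logons: int = 3,
    month_days: float = MONTH_DAYS,
) -> pd.DataFrame:
    """Per-patient activity table for all eligible registrants.

    Ineligible patients (no logons; or failing the span-denominator
    precondition) are silently excluded — their ids are available via
    ``result.attrs["excluded"]``. Columns: patient_id, logons_total,
    denominator_months, logons_per_month, log_lpm.
    """
    logon_map = cohort.logons_by_patient()
    census_dt = np.datetime64(census.census_date)
    reg = cohort.patients.set_index("patient_id")["registration_date"]
    rows, excluded = [], []
    for pid in cohort.patients["patient_id"]:
        times = logon_map.get(pid)
        if times is None or times.size == 0:
            excluded.append(pid)
            continue
        if denominator is Denominator.REGISTRATION_TO_CENSUS:
            months = (census_dt - np.datetime64(reg.loc[pid])) / DAY / month_days
        else:
            if not span_eligible(times, min_logons, min_span_months, month_days):
                excluded.append(pid)
                continue
            months = (times[-1] - times[0]) / DAY / month_days
        if months <= 0:
            excluded.append(pid)
            continue
        lpm = times.size / months
        rows.append((pid, int(times.size), float(months), float(lpm), float(np.log(lpm))))
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "logons_total", "denominator_months",
                 "logons_per_month", "log_lpm"],
    )
    out.attrs["denominator"] = denominator.value
    out.attrs["excluded"] = excluded
    return out


def quartile_classify(profiles: pd.DataFrame) -> pd.DataFrame:
    """Assign activity quartiles Q1-Q4 of log(logons per month).

    Rank-based realization of the 25/50/75 empirical percentile cuts:
    patients are stably ordered by (log_lpm, patient_id) and split into
    four parts whose sizes differ by at most one; a patient exactly at a
    cut point therefore lands in the lower quartile, and ties are broken
    by patient id. Q4 is the heaviest-use quartile.
    """
    n = len(profiles)
    if n < 4:
        raise ValidationError("quartile classification needs a cohort of >= 4")
    out = profiles.reset_index(drop=True).copy()
    order = out.sort_values(
        ["log_lpm", "patient_id"], kind="stable"
    ).index.to_numpy()
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    out["quartile"] = [f"Q{q + 1}" for q in (4 * ranks) // n]
    return out


def top_fraction_flag(profiles: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Flag the ceil(fraction * n) heaviest users by raw logons per month.

    Ties at the threshold resolve by patient id (stable), so the flagged
    set is invariant to input row order.
    """
    n = len(profiles)
    if n < 1.0 / fraction:
        raise ValidationError(
            f"cohort of {n} too small for a top-{fraction:.0%} flag"
        )
    k = int(np.ceil(fraction * n))
    out = profiles.reset_index(drop=True).copy()
    order = out.sort_values(
        ["logons_per_month", "patient_id"], ascending=[False, True], kind="stable"
    ).index.to_numpy()
    flag = np.zeros(n, dtype=bool)
    flag[order[:k]] = True
    out["top5"] = flag
    return out


def time_histograms(logons: pd.DataFrame | pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Weekday (Mon..Sun, 7 bins) and hour-of-day (0..23, 24 bins) counts.

    Each histogram sums to the number of logons. Raises
    :class:`ValidationError` for the hour histogram when every timestamp
    sits at exactly midnight, the signature of date-only data (a genuine
    all-midnight stream is indistinguishable from one and refused too).
    """
    ts = logons["timestamp"] if isinstance(logons, pd.DataFrame) else logons
    ts = pd.to_datetime(pd.Series(np.asarray(ts)))
    if ts.empty:
        return np.zeros(7, dtype=int), np.zeros(24, dtype=int)
    weekday = np.bincount(ts.dt.dayofweek.to_numpy(), minlength=7)
    if (ts.dt.hour.eq(0) & ts.dt.minute.eq(0) & ts.dt.second.eq(0)).all():
        raise ValidationError(
            "timestamps appear date-only (all midnight); hour histogram refused"
        )
    hour = np.bincount(ts.dt.hour.to_numpy(), minlength=24)
    return weekday, hour
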