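"""Persistence of portal use as a survival problem.

A registrant's "use" begins at first logon and ends at last logon. The
last logon is an *event* (abandonment) only when the data can support
that reading; otherwise the duration is right-censored as consistent
with continuing use. Specifically a duration is censored when

* the last logon is within 6 months of the census date (the patient may
  simply not have needed the portal yet), or
* fewer than 2 result uploads postdate the last logon (infrequent
  follow-up — or death — so silence is uninformative).

The second clause also censors patients who used the portal up to death;
no separate death flag exists.

Survival of use is then estimated with the Kaplan–Meier product-limit
estimator with Greenwood-based 95% pointwise confidence intervals
(log-transformed, as implemented by lifelines). At tied times events
precede censorings, the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ValidationError
from .registry import DAY, MONTH_DAYS, CensusSpec, Cohort


@dataclass(frozen=True)
class UseDuration:
    """First-to-last-logon span for one registrant.

    ``censored`` is True when the last logon is judged consistent with
    continuing use at census (still "alive" in the survival sense).
    """

    patient_id: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    duration_months: float
    censored: bool


@dataclass
class SurvivalCurve:
    """A step survival function with pointwise 95% bounds.

    ``event_times`` are months since first logon, ascending; ``survival``
    is non-increasing with S(0) = 1. ``n_risk`` is the at-risk count just
    before each time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray

    def probability_at(self, t_months: float) -> float:
        """S(t) of the right-continuous step function."""
        if t_months < 0:
            raise ValidationError("time must be non-negative")
        idx = np.searchsorted(self.event_times, t_months, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.event_times,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_risk": self.n_risk,
            }
        )

    def plot(self, ax=None, label: str | None = None):
        """Step plot with shaded 95% band (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.event_times, self.survival, where="post", label=label)
        ax.fill_between(
            self.event_times, self.ci_low, self.ci_high, step="post", alpha=0.25
        )
        ax.set_xlabel("months since first logon")
        ax.set_ylabel("probability of continuing use")
        ax.set_ylim(0, 1.02)
        if label:
            ax.legend()
        return ax


def use_duration(
    patient: pd.Series,
    logons: np.ndarray | pd.Series,
    results: np.ndarray | pd.Series,
    census: CensusSpec,
    censor_gap_months: float = 6.0,
    censor_min_results: int = 2,
    month_days: float = MONTH_DAYS,
) -> UseDuration:
    """Build the use-duration record for one registrant with >= 1 logon.

    Raises :class:`ValidationError` on an empty logon stream — callers
    filter never-logged-on registrants out before survival analysis.
    """
    times = np.sort(pd.to_datetime(pd.Series(np.asarray(logons))).to_numpy())
    if times.size == 0:
        raise ValidationError("use_duration needs at least one logon")
    result_dates = pd.to_datetime(pd.Series(np.asarray(results))).dt.normalize().to_numpy()
    first, last = pd.Timestamp(times[0]), pd.Timestamp(times[-1])
    gap_days = (np.datetime64(census.census_date) - np.datetime64(last)) / DAY
    n_after = int(np.sum(result_dates > np.datetime64(last.normalize())))
    censored = (gap_days <= censor_gap_months * month_days) or (
        n_after < censor_min_results
    )
    duration = (np.datetime64(last) - np.datetime64(first)) / DAY / month_days
    return UseDuration(
        patient_id=str(patient["patient_id"]),
        start_date=first,
        end_date=last,
        duration_months=float(duration),
        censored=bool(censored),
    )


def cohort_durations(
    cohort: Cohort,
    census: CensusSpec,
    censor_gap_months: float = 6.0,
    censor_min_results: int = 2,
    month_days: float = MONTH_DAYS,
) -> pd.DataFrame:
    """Use durations for every registrant with at least one logon.

    Returns one row per such registrant: patient_id, start_date, end_date,
    duration_months, censored.
    """
    logon_map = cohort.logons_by_patient()
    result_map = cohort.results_by_patient()
    census_dt = np.datetime64(census.census_date)
    rows = []
    for pid, times in logon_map.items():
        last = times[-1]
        last_date = np.datetime64(pd.Timestamp(last).normalize())
        res = result_map.get(pid)
        n_after = int(np.sum(res > last_date)) if res is not None else 0
        gap_days = (census_dt - last) / DAY
        censored = (gap_days <= censor_gap_months * month_days) or (
            n_after < censor_min_results
        )
        rows.append(
            (
                pid,
                pd.Timestamp(times[0]),
                pd.Timestamp(last),
                float((last - times[0]) / DAY / month_days),
                bool(censored),
            )
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "start_date", "end_date", "duration_months", "censored"]
    )


def km_estimate(durations: pd.DataFrame | Iterable[UseDuration]) -> SurvivalCurve:
    """Product-limit survival of use from a duration table.

    Accepts the frame from :func:`cohort_durations` (columns
    ``duration_months``, ``censored``) or an iterable of
    :class:`UseDuration`. A censored-only input yields the flat curve
    S(t) = 1.
    """
    df = _as_duration_frame(durations)
    if df.empty:
        raise ValidationError("km_estimate needs a non-empty duration collection")
    kmf = KaplanMeierFitter()
    kmf.fit(df["duration_months"], event_observed=~df["censored"].to_numpy())
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    times = sf.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return SurvivalCurve(
        event_times=times,
        survival=sf.iloc[:, 0].to_numpy(),
        ci_low=ci.iloc[:, 0].to_numpy(),
        ci_high=ci.iloc[:, 1].to_numpy(),
        n_risk=at_risk,
    )


def _as_duration_frame(durations) -> pd.DataFrame:
    if isinstance(durations, pd.DataFrame):
        return durations
    rows = list(durations)
    return pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in rows],
            "duration_months": [d.duration_months for d in rows],
            "censored": [d.censored for d in rows],
        }
    )


def survival_by_group(
    durations: pd.DataFrame,
    patients: pd.DataFrame,
    factor: str,
    levels: Sequence[str] | None = None,
) -> Mapping[str, SurvivalCurve]:
    """One Kaplan–Meier curve per level of a patient covariate.

    ``factor`` must be a column of ``patients``; patients missing the
    factor are dropped (complete-case). Group sizes are exposed on each
    curve as ``curve.n_risk[0]``.
    """
    if factor not in patients.columns:
        raise ValidationError(f"unknown factor {factor!r}")
    merged = durations.merge(
        patients[["patient_id", factor]], on="patient_id", how="left"
    ).dropna(subset=[factor])
    if levels is None:
        levels = sorted(merged[factor].unique())
    out: dict[str, SurvivalCurve] = {}
    for level in levels:
        sub = merged[merged[factor] == level]
        if len(sub):
            out[str(level)] = km_estimate(sub)
    return out


def attrition_rate(curve: SurvivalCurve, from_months: float, to_months: float) -> float:
    """Average yearly loss of the survival probability over a window:
    (S(from) - S(to)) / ((to - from) / 12)."""
    if not from_months < to_months:
        raise ValidationError("require from_months < to_months")
    support = float(curve.event_times[-1])
    if to_months > support:
        raise ValidationError(
            f"window end {to_months} exceeds curve support {support}"
        )
    s0 = curve.probability_at(from_months)
    s1 = curve.probability_at(to_months)
    return (s0 - s1) / ((to_months - from_months) / 12.0)


def curve_from_points(
    times_months: Sequence[float], survival: Sequence[float]
) -> SurvivalCurve:
    """Wrap an externally reported survival series (e.g. published
    checkpoint probabilities) as a :class:`SurvivalCurve` so that
    :func:`attrition_rate` and plotting apply. CI bounds are set equal to
    the point estimates and at-risk counts to NaN."""
    t = np.asarray(times_months, dtype=float)
    s = np.asarray(survival, dtype=float)
    if t.ndim != 1 or t.shape != s.shape or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly ascending and match survival")
    if np.any(np.diff(s) > 0) or np.any((s < 0) | (s > 1)):
        raise ValidationError("survival must be non-increasing within [0, 1]")
    return SurvivalCurve(
        event_times=t,
        survival=s,
        ci_low=s.copy(),
        ci_high=s.copy(),
        n_risk=np.full_like(t, np.nan),
    )
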