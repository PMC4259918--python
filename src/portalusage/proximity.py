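"""Temporal proximity of logons to blood-test results.

For every logon the signed whole-day interval to the *closest* result
date of the same patient is computed (positive = logon after the result,
negative = logon before it; an exact equidistant tie is assigned the
positive interval, since post-result viewing is the object of study).
Intervals are computed on calendar dates — the logon's time-of-day is
ignored because result events are date-only.

Pooled intervals feed a 1-day-bin proportion histogram over [-W, +W]
(default W = 28) and headline fractions (share of logons 0-1 days after
a result, 0-3 days after, in the 3 days before, within 14 days after).

Significance is assessed against a permutation null: per permutation
each patient's logon times (or result dates) are redrawn uniformly at
random within that patient's observation window (first logon to census),
preserving per-patient event counts, and the histogram is recomputed.
The null envelope is the pointwise 2.5-97.5 percentile band; per-bin
exceedance p-values use the standard (1 + #{null >= observed}) /
(1 + n_permutations) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import DAY, CensusSpec, Cohort

# Patients are embedded on a common integer-day axis separated by a gap
# far larger than any real observation span, so one global searchsorted
# resolves nearest-result queries for the whole cohort at once.
_PATIENT_OFFSET_DAYS = 10_000_000


@dataclass
class ProximityHistogram:
    """Proportion of logons by signed day-interval to the closest result.

    ``proportions[i]`` is the share of *all* interval-defined logons
    falling in the 1-day bin [bin_edges[i], bin_edges[i]+1); bins cover
    [-window, +window]. ``n_logons_total`` counts every logon supplied
    (including those of patients without any result, which have no
    interval); ``n_in_window`` counts logons landing inside the window,
    so the proportions sum to n_in_window / n_logons_total.
    """

    bin_edges: np.ndarray
    proportions: np.ndarray
    n_logons_total: int
    n_in_window: int

    @property
    def window_days(self) -> int:
        return int(-self.bin_edges[0])

    def normalized(self) -> np.ndarray:
        """Proportions renormalized to sum to 1 over the window."""
        total = self.proportions.sum()
        return self.proportions / total if total > 0 else self.proportions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start_days": self.bin_edges, "proportion": self.proportions}
        )


@dataclass
class ShuffleNull:
    """Permutation-null summary for a proximity histogram."""

    n_permutations: int
    seed: int
    mode: str
    observed: ProximityHistogram
    null_mean: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    p_values: np.ndarray
    null_histograms: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_days": self.observed.bin_edges,
                "proportion": self.observed.proportions,
                "null_mean": self.null_mean,
                "null_lo": self.null_lo,
                "null_hi": self.null_hi,
                "p": self.p_values,
            }
        )


def nearest_result_interval(
    logon_time, result_dates: np.ndarray | pd.Series
) -> int | None:
    """Signed days from the closest result to a single logon.

    ``result_dates`` must be the patient's sorted result dates. Returns
    None when the patient has no results. Positive means the logon
    follows the result; equidistant ties go positive.
    """
    dates = pd.to_datetime(pd.Series(np.asarray(result_dates))).dt.normalize().to_numpy()
    if dates.size == 0:
        return None
    ld = np.datetime64(pd.Timestamp(logon_time).normalize())
    idx = int(np.searchsorted(dates, ld))
    after = (ld - dates[idx - 1]) / DAY if idx > 0 else np.inf      # logon after result
    before = (ld - dates[idx]) / DAY if idx < dates.size else -np.inf  # logon before result
    # tie (|after| == |before|) resolves to the positive interval
    return int(after) if abs(after) <= abs(before) else int(before)


def _encode(cohort_like_patients, logons: pd.DataFrame, results: pd.DataFrame, census_date):
    """Place logon dates, result dates and windows on the offset day axis."""
    pids = pd.Index(sorted(set(logons["patient_id"]) | set(results["patient_id"])))
    code = pd.Series(np.arange(len(pids)), index=pids)
    epoch = np.datetime64("1970-01-01")

    def days(series):
        return ((pd.to_datetime(series).dt.normalize().to_numpy() - epoch) / DAY).astype(np.int64)

    lg_days = days(logons["timestamp"]) + code.loc[logons["patient_id"]].to_numpy() * _PATIENT_OFFSET_DAYS
    rs_days = days(results["sample_date"]) + code.loc[results["patient_id"]].to_numpy() * _PATIENT_OFFSET_DAYS
    census_day = int((np.datetime64(pd.Timestamp(census_date).normalize()) - epoch) / DAY)
    return code, np.sort(lg_days), np.sort(rs_days), census_day


def _intervals(logon_days: np.ndarray, result_days_sorted: np.ndarray) -> np.ndarray:
    """Signed nearest-result intervals on the offset axis; NaN = no result
    for that patient (nearest candidate lies across an offset gap)."""
    idx = np.searchsorted(result_days_sorted, logon_days)
    big = _PATIENT_OFFSET_DAYS // 2
    after = np.where(
        idx > 0, logon_days - result_days_sorted.take(idx - 1, mode="clip"), big
    ).astype(np.float64)
    before = np.where(
        idx < result_days_sorted.size,
        logon_days - result_days_sorted.take(idx, mode="clip"),
        -big,
    ).astype(np.float64)
    out = np.where(np.abs(after) <= np.abs(before), after, before)
    out[np.abs(out) >= big] = np.nan
    return out


def pooled_intervals(
    logons: pd.DataFrame, results: pd.DataFrame, census: CensusSpec
) -> np.ndarray:
    """Nearest-result interval (signed days, NaN if undefined) for every
    logon in the cohort, pooled over patients."""
    _, lg, rs, _ = _encode(None, logons, results, census.census_date)
    return _intervals(lg, rs)


def _histogram(intervals: np.ndarray, window_days: int, n_total: int) -> ProximityHistogram:
    finite = intervals[np.isfinite(intervals)]
    in_win = finite[(finite >= -window_days) & (finite <= window_days)]
    counts = np.bincount(
        (in_win + window_days).astype(int), minlength=2 * window_days + 1
    )
    return ProximityHistogram(
        bin_edges=np.arange(-window_days, window_days + 1),
        proportions=counts / n_total if n_total else counts.astype(float),
        n_logons_total=n_total,
        n_in_window=int(in_win.size),
    )


def proximity_histogram(
    logons: pd.DataFrame,
    results: pd.DataFrame,
    census: CensusSpec,
    window_days: int = 28,
) -> ProximityHistogram:
    """Cohort-wide 1-day-bin proportion histogram of logon-to-nearest-result
    intervals over [-window_days, +window_days]."""
    if results.empty:
        raise ValidationError("no patient has any result event")
    iv = pooled_intervals(logons, results, census)
    return _histogram(iv, window_days, n_total=len(logons))


def headline_fractions(intervals: np.ndarray) -> dict[str, float]:
    """Headline shares of logons by proximity to the nearest result.

    Denominator is the logons with a defined interval (patients with at
    least one result); ``n_total`` in the output carries the all-logons
    count so the alternative denominator can be formed by the caller.
    Bin conventions: after_0_1 = [0, 1) days, after_0_3 = [0, 3),
    pre_3 = [-3, 0), within_14 = [0, 14).
    """
    iv = np.asarray(intervals, dtype=float)
    defined = iv[np.isfinite(iv)]
    if defined.size == 0:
        raise ValidationError("no logon has a defined nearest-result interval")
    n = defined.size
    return {
        "frac_after_0_1": float(np.sum((defined >= 0) & (defined < 1)) / n),
        "frac_after_0_3": float(np.sum((defined >= 0) & (defined < 3)) / n),
        "frac_pre_3": float(np.sum((defined >= -3) & (defined < 0)) / n),
        "frac_within_14": float(np.sum((defined >= 0) & (defined < 14)) / n),
        "n_defined": float(n),
        "n_total": float(iv.size),
    }


def shuffle_null(
    logons: pd.DataFrame,
    results: pd.DataFrame,
    census: CensusSpec,
    n_permutations: int = 999,
    seed: int = 0,
    mode: str = "shuffle_logons",
    window_days: int = 28,
) -> ShuffleNull:
    """Permutation null for the proximity histogram.

    Per permutation, each patient's logon times (``shuffle_logons``) or
    result dates (``shuffle_results``) are redrawn uniformly within that
    patient's observation window (first logon to census), preserving
    per-patient counts; the histogram is recomputed against the fixed
    other stream. Patients without logons contribute no window.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    if mode not in ("shuffle_logons", "shuffle_results"):
        raise ValidationError(f"unknown mode {mode!r}")
    code, lg, rs, census_day = _encode(None, logons, results, census.census_date)

    # per-patient windows on the offset axis: [first logon, census]
    pid_of = (lg // _PATIENT_OFFSET_DAYS).astype(np.int64)
    order_first = np.unique(pid_of, return_index=True)
    first_by_pid = dict(zip(order_first[0], lg[order_first[1]]))

    if mode == "shuffle_logons":
        shuffled_base, fixed_sorted = lg, rs
    else:
        shuffled_base, fixed_sorted = rs, np.sort(lg)
    pid_shuf = (shuffled_base // _PATIENT_OFFSET_DAYS).astype(np.int64)
    starts = np.array([first_by_pid.get(p, np.nan) for p in pid_shuf])
    keep = np.isfinite(starts)  # events of patients with no logon window drop out
    starts = starts[keep].astype(np.int64)
    ends = (pid_shuf[keep] * _PATIENT_OFFSET_DAYS) + census_day
    if not len(starts) or np.all(ends < starts):
        raise ValidationError("all patients have zero-length observation windows")

    observed = _histogram(_intervals(lg, rs), window_days, n_total=len(logons))
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_permutations, 2 * window_days + 1))
    widths = (ends - starts + 1).astype(np.float64)
    for i in range(n_permutations):
        draw = starts + np.floor(rng.random(starts.size) * widths).astype(np.int64)
        if mode == "shuffle_logons":
            iv = _intervals(np.sort(draw), fixed_sorted)
        else:
            iv = _intervals(fixed_sorted, np.sort(draw))
        nulls[i] = _histogram(iv, window_days, n_total=observed.n_logons_total).proportions

    ge = (nulls >= observed.proportions[None, :]).sum(axis=0)
    return ShuffleNull(
        n_permutations=n_permutations,
        seed=seed,
        mode=mode,
        observed=observed,
        null_mean=nulls.mean(axis=0),
        null_lo=np.percentile(nulls, 2.5, axis=0),
        null_hi=np.percentile(nulls, 97.5, axis=0),
        p_values=(1 + ge) / (1 + n_permutations),
        null_histograms=nulls,
    )
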