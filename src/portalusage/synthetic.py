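"""Synthetic portal registries with known ground truth.

Two kinds of dataset are produced:

* :func:`generate_cohort` — a stochastic cohort whose event streams have
  the statistical structure the analyses assume: blood-test results on
  treatment-dependent schedules (about monthly for in-center
  hemodialysis, 3-12-monthly otherwise); logons as a superposition of
  piecewise-constant-intensity Poisson components (a per-patient
  baseline scaled by a log-normal activity multiplier, an initial
  post-registration burst, an excess in the days after each result and a
  small bump in the days before it); and a lifecycle class per patient
  (never / early lapser / late lapser / persistent) that truncates the
  logon stream accordingly. The drawn class and stop date are emitted as
  ground truth so that classification can be scored.

* :func:`make_printed_cohort_fixture` / :func:`make_activity_fixture` —
  deterministic cohorts constructed so that the classification rules
  reproduce, exactly, a published cohort flow (11,352 registrants of
  whom 2,634 never logged on, 469 with too-recent first logons, and
  8,249 lapse-analyzable completers splitting 822 / 1,404 / 6,023 into
  early lapsers, late lapsers and persistent users; and 5,808
  span-eligible established users splitting 5,085 / 723).

All generation is reproducible: one integer seed drives a single
``numpy`` Generator, and identical config + seed yields byte-identical
CSV output through :func:`portalusage.registry.write_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .registry import MONTH_DAYS, CensusSpec, Cohort

_CLASSES = ("never", "early_lapser", "late_lapser", "persistent")

#: map from generator ground-truth labels to the classification labels
#: they should be recovered as
GROUND_TRUTH_TO_USAGE = {
    "never": "never_logged_on",
    "early_lapser": "early_lapser",
    "late_lapser": "late_lapser",
    "persistent": "persistent_user",
}

_DEFAULT_COVARIATES: dict[str, dict] = {
    # marginal frequencies shaped like a renal-portal registry: middle-aged
    # and older adults dominate, ~60% male, transplant and non-RRT CKD are
    # the largest treatment groups
    "age_band": {"lt18": 0.016, "a18_34": 0.116, "a35_54": 0.379,
                 "a55_74": 0.389, "gt75": 0.100},
    "gender": {"male": 0.599, "female": 0.401},
    "treatment": {"hospital_hd": 0.194, "home_hd_pd": 0.067,
                  "transplant": 0.329, "not_rrt": 0.410},
    "deprivation_decile": {str(d): 0.1 for d in range(1, 11)},
}

_AGE_RANGES = {
    "lt18": (2.0, 17.5), "a18_34": (18.0, 34.5), "a35_54": (35.0, 54.5),
    "a55_74": (55.0, 74.5), "gt75": (75.0, 92.0),
}

#: hour-of-day sampling weights: waking hours 08:00-21:59 dominate
_DEFAULT_HOUR_WEIGHTS = np.array([0.1] * 8 + [1.0] * 14 + [0.1] * 2)


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Rates are per day; windows and margins in days unless named
    ``*_months``. ``class_mixture`` is either a probability map over
    {never, early_lapser, late_lapser, persistent} or a callable mapping
    a patient's covariate dict (including center ``assisted_start``) to
    such a map, which is how covariate-dependent participation is
    injected. ``registration_window_months`` bounds how long before
    census patients register (uniform).
    """

    n_patients: int = 2000
    census_date: str | pd.Timestamp = "2009-09-07"
    seed: int = 0

    covariate_frequencies: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COVARIATES.items()}
    )
    n_centers: int = 12
    assisted_center_fraction: float = 0.1
    registration_window_months: tuple[float, float] = (1.0, 42.0)

    class_mixture: Mapping[str, float] | Callable[[dict], Mapping[str, float]] = field(
        default_factory=lambda: {
            "never": 0.23, "early_lapser": 0.08,
            "late_lapser": 0.13, "persistent": 0.56,
        }
    )

    # result schedules: per-treatment uniform inter-result interval (days)
    result_schedule: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hospital_hd": (25.0, 35.0),
            "home_hd_pd": (90.0, 365.0),
            "transplant": (90.0, 365.0),
            "not_rrt": (90.0, 365.0),
        }
    )

    # logon point process (superposed piecewise-constant Poisson components)
    baseline_rate: float = 0.066          # ~2 logons / month
    initial_burst_rate: float = 0.4
    initial_burst_days: float = 14.0
    post_result_excess_rate: float = 0.6
    post_result_window_days: float = 3.0
    pre_result_bump_rate: float = 0.12
    pre_result_window_days: float = 3.0
    rate_multiplier_sigma: float = 0.6    # log-normal per-patient activity spread

    lapse_hazard: float = 0.06            # per-month stop probability, late lapsers
    late_stop_margin_months: float = 7.0  # stop at least this far before census
    early_max_day: float = 25.0           # early lapsers stay inside day 25

    hour_weights: np.ndarray = field(
        default_factory=lambda: _DEFAULT_HOUR_WEIGHTS.copy()
    )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for name, freqs in self.covariate_frequencies.items():
            vals = np.array(list(freqs.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1) or abs(vals.sum() - 1) > 1e-9:
                raise ConfigError(f"covariate_frequencies[{name!r}] must sum to 1")
        if not callable(self.class_mixture):
            vals = np.array([self.class_mixture.get(c, 0.0) for c in _CLASSES])
            if np.any(vals < 0) or abs(vals.sum() - 1) > 1e-9:
                raise ConfigError("class_mixture must be a probability map summing to 1")
        for rate in (self.baseline_rate, self.initial_burst_rate,
                     self.post_result_excess_rate, self.pre_result_bump_rate):
            if rate < 0:
                raise ConfigError("rates must be non-negative")
        for window in (self.initial_burst_days, self.post_result_window_days,
                       self.pre_result_window_days):
            if window < 0:
                raise ConfigError("windows must be non-negative")
        lo, hi = self.registration_window_months
        if not (0 < lo <= hi):
            raise ConfigError("registration_window_months must satisfy 0 < lo <= hi")


def _mixture_for(config: GeneratorConfig, covariates: dict) -> np.ndarray:
    mix = (
        config.class_mixture(covariates)
        if callable(config.class_mixture)
        else config.class_mixture
    )
    p = np.array([mix.get(c, 0.0) for c in _CLASSES], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1) > 1e-6:
        raise ConfigError("class mixture must be a probability map summing to 1")
    return p


def _poisson_times(rng, start: float, end: float, rate: float) -> np.ndarray:
    """Homogeneous Poisson event times (day offsets) on [start, end)."""
    span = end - start
    if span <= 0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return start + rng.random(n) * span


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, pd.DataFrame]:
    """Draw a synthetic registry and its ground-truth labels.

    Returns ``(cohort, ground_truth)`` where ``ground_truth`` has one row
    per patient: ``patient_id``, ``true_class`` and ``true_stop_date``
    (the truncation date of late lapsers, NaT otherwise). A sampled class
    that is infeasible for the patient's registration date (a late
    lapser registered too close to census to fit the >= 2-results,
    >= 6-month-gap pattern) is downgraded to ``persistent``; the emitted
    label is the class actually realized in the streams.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    census = pd.Timestamp(config.census_date)
    census64 = np.datetime64(census)

    centers = pd.DataFrame(
        {
            "center_id": [f"C{j:02d}" for j in range(config.n_centers)],
            "rpv_start_date": pd.to_datetime(
                [census - pd.Timedelta(days=float(d))
                 for d in rng.uniform(400, 1500, config.n_centers)]
            ).normalize(),
            "assisted_start": rng.random(config.n_centers) < config.assisted_center_fraction,
            "rrt_population": rng.integers(200, 1500, config.n_centers),
        }
    )

    hour_p = np.asarray(config.hour_weights, dtype=float)
    hour_p = hour_p / hour_p.sum()

    lo_m, hi_m = config.registration_window_months
    patient_rows, gt_rows, logon_rows, result_rows = [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        cov: dict = {}
        for name, freqs in config.covariate_frequencies.items():
            keys = list(freqs)
            cov[name] = keys[rng.choice(len(keys), p=np.array(list(freqs.values())))]
        center_idx = int(rng.integers(config.n_centers))
        cov["assisted_start"] = bool(centers["assisted_start"].iloc[center_idx])

        reg_days_before = rng.uniform(lo_m, hi_m) * MONTH_DAYS
        reg = (census - pd.Timedelta(days=float(reg_days_before))).normalize()
        reg64 = np.datetime64(reg)
        horizon = float((census64 - reg64) / np.timedelta64(1, "D"))

        cls = _CLASSES[rng.choice(4, p=_mixture_for(config, cov))]
        if cls == "late_lapser" and horizon < 14 * MONTH_DAYS:
            cls = "persistent"

        a_lo, a_hi = _AGE_RANGES[cov["age_band"]]
        age = round(float(rng.uniform(a_lo, a_hi)), 1)

        # --- result stream: schedule runs registration -> census ---------
        interval_lo, interval_hi = config.result_schedule.get(
            cov["treatment"], (90.0, 365.0)
        )
        res_days: list[float] = []
        t = rng.uniform(3.0, interval_hi / 3.0)
        while t < horizon:
            res_days.append(t)
            t += rng.uniform(interval_lo, interval_hi)

        # --- late-lapser stop date ---------------------------------------
        stop_day: float | None = None
        if cls == "late_lapser":
            months_active = 2.0 + float(rng.geometric(min(config.lapse_hazard, 0.999)))
            stop_day = min(
                months_active * MONTH_DAYS,
                horizon - config.late_stop_margin_months * MONTH_DAYS,
            )
            stop_day = max(stop_day, 45.0)
            # guarantee >= 2 results strictly after the stop date
            after = [d for d in res_days if d > stop_day + 1]
            need = 2 - len(after)
            nxt = stop_day + 1
            while need > 0 and nxt < horizon - 3:
                nxt += float(rng.uniform(20, 60))
                if nxt < horizon - 3:
                    res_days.append(nxt)
                    need -= 1
            res_days.sort()

        # --- logon window by class ---------------------------------------
        if cls == "never":
            w_end = None
        elif cls == "early_lapser":
            w_end = min(config.early_max_day, horizon)
        elif cls == "late_lapser":
            w_end = stop_day
        else:
            w_end = horizon

        logon_days = np.empty(0)
        if w_end is not None:
            mult = float(np.exp(rng.normal(0.0, config.rate_multiplier_sigma)))
            parts = [
                _poisson_times(rng, 0.0, w_end, config.baseline_rate * mult),
                _poisson_times(
                    rng, 0.0, min(config.initial_burst_days, w_end),
                    config.initial_burst_rate * mult,
                ),
            ]
            for r in res_days:
                parts.append(
                    _poisson_times(
                        rng, max(r, 0.0), min(r + config.post_result_window_days, w_end),
                        config.post_result_excess_rate * mult,
                    )
                )
                parts.append(
                    _poisson_times(
                        rng, max(r - config.pre_result_window_days, 0.0), min(r, w_end),
                        config.pre_result_bump_rate * mult,
                    )
                )
            logon_days = np.concatenate(parts)

            # class-guaranteeing touches (streams must realize the label)
            if cls == "early_lapser" and logon_days.size == 0:
                logon_days = np.array([float(rng.uniform(0.0, min(10.0, w_end)))])
            if cls == "late_lapser":
                if not np.any(logon_days > 35.0):
                    logon_days = np.append(logon_days, stop_day)
                else:
                    logon_days = np.append(logon_days, stop_day)
            if cls == "persistent":
                recent = logon_days[logon_days > horizon - 150.0]
                if recent.size == 0:
                    logon_days = np.append(
                        logon_days, horizon - float(rng.uniform(20.0, 140.0))
                    )
                if logon_days.size == 0 or not np.any(logon_days <= 35.0):
                    logon_days = np.append(logon_days, float(rng.uniform(1.0, 20.0)))
            logon_days = np.sort(np.clip(logon_days, 0.0, horizon))

        for d in logon_days:
            hour = int(rng.choice(24, p=hour_p))
            minute = int(rng.integers(60))
            logon_rows.append(
                (pid, reg + pd.Timedelta(days=float(np.floor(d)),
                                         hours=hour, minutes=minute))
            )
        for d in res_days:
            result_rows.append((pid, reg + pd.Timedelta(days=float(np.floor(d)))))

        patient_rows.append(
            (
                pid, reg, age, cov["gender"], cov["treatment"],
                int(cov["deprivation_decile"]), centers["center_id"].iloc[center_idx],
            )
        )
        stop_date = (
            reg + pd.Timedelta(days=float(np.floor(stop_day)))
            if stop_day is not None else pd.NaT
        )
        gt_rows.append((pid, cls, stop_date))

    patients = pd.DataFrame(
        patient_rows,
        columns=["patient_id", "registration_date", "age_years", "gender",
                 "treatment", "deprivation_decile", "center_id"],
    )
    logons = pd.DataFrame(logon_rows, columns=["patient_id", "timestamp"])
    logons = logons.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)
    results = pd.DataFrame(result_rows, columns=["patient_id", "sample_date"])
    results["sample_date"] = pd.to_datetime(results["sample_date"]).dt.normalize()
    results = results.sort_values(["patient_id", "sample_date"], kind="stable").reset_index(drop=True)
    ground_truth = pd.DataFrame(
        gt_rows, columns=["patient_id", "true_class", "true_stop_date"]
    )
    return Cohort(patients, centers, logons, results), ground_truth


# ---------------------------------------------------------------------------
# deterministic fixtures realizing a published cohort flow
# ---------------------------------------------------------------------------

def _fixture_patient(pid, reg, rng, center_ids):
    age = round(float(rng.uniform(18.0, 88.0)), 1)
    gender = "male" if rng.random() < 0.6 else "female"
    treatment = ["hospital_hd", "home_hd_pd", "transplant", "not_rrt"][
        rng.choice(4, p=[0.19, 0.07, 0.33, 0.41])
    ]
    decile = int(rng.integers(1, 11))
    center = center_ids[int(rng.integers(len(center_ids)))]
    return (pid, reg, age, gender, treatment, decile, center)


def _fixture_centers(census: pd.Timestamp) -> pd.DataFrame:
    ids = [f"C{j:02d}" for j in range(10)]
    return pd.DataFrame(
        {
            "center_id": ids,
            "rpv_start_date": [census - pd.Timedelta(days=400 + 110 * j) for j in range(10)],
            "assisted_start": [j < 2 for j in range(10)],
            "rrt_population": [1200 - 70 * j for j in range(10)],
        }
    )


def make_printed_cohort_fixture(census_date: str | pd.Timestamp = "2009-09-07") -> Cohort:
    """Deterministic 11,352-patient cohort realizing the published flow.

    Classified with the first-logon restriction, the streams yield
    exactly 2,634 never-logged-on registrants; 469 with a first logon
    within 3 months of census (insufficient follow-up for the lapse
    analysis); and among the remaining 8,249 completers — 822 early
    lapsers, 1,404 late lapsers and 6,023 persistent users. Every late
    lapser has >= 2 results strictly after the last logon and a last
    logon >= 6 months before census; every persistent user logged on
    within 6 months of census.
    """
    census = pd.Timestamp(census_date)
    rng = np.random.default_rng(20090907)  # fixture-internal, fixed
    centers = _fixture_centers(census)
    center_ids = list(centers["center_id"])

    patient_rows, logon_rows, result_rows = [], [], []
    counter = 0

    def reg_spread(i, min_days_before, span_days):
        return (census - pd.Timedelta(days=int(min_days_before + (i * 37) % span_days))).normalize()

    def add_results(pid, days):
        for d in days:
            result_rows.append((pid, d.normalize()))

    # never logged on: 2,634
    for i in range(2634):
        pid = f"F{counter:06d}"; counter += 1
        reg = reg_spread(i, 420, 800)
        patient_rows.append(_fixture_patient(pid, reg, rng, center_ids))
        add_results(pid, [reg + pd.Timedelta(days=60 + 120 * k) for k in range(3)])

    # first logon within 3 months of census: 469
    for i in range(469):
        pid = f"F{counter:06d}"; counter += 1
        reg = (census - pd.Timedelta(days=50 + (i % 30))).normalize()
        patient_rows.append(_fixture_patient(pid, reg, rng, center_ids))
        logon_rows.append((pid, reg + pd.Timedelta(days=4, hours=10)))
        logon_rows.append((pid, reg + pd.Timedelta(days=9, hours=19, minutes=30)))
        add_results(pid, [reg + pd.Timedelta(days=14)])

    # early lapsers: 822 (all logons within 30 days of registration)
    for i in range(822):
        pid = f"F{counter:06d}"; counter += 1
        reg = reg_spread(i, 420, 700)
        patient_rows.append(_fixture_patient(pid, reg, rng, center_ids))
        logon_rows.append((pid, reg + pd.Timedelta(days=1, hours=9)))
        logon_rows.append((pid, reg + pd.Timedelta(days=20, hours=17, minutes=15)))
        add_results(pid, [reg + pd.Timedelta(days=30 + 100 * k) for k in range(3)])

    # late lapsers: 1,404 (silence >= 6 months, >= 2 results after last logon)
    for i in range(1404):
        pid = f"F{counter:06d}"; counter += 1
        reg = reg_spread(i, 500, 700)
        patient_rows.append(_fixture_patient(pid, reg, rng, center_ids))
        last = census - pd.Timedelta(days=220 + (i % 40))
        logon_rows.append((pid, reg + pd.Timedelta(days=2, hours=11)))
        logon_rows.append((pid, reg + pd.Timedelta(days=45, hours=20, minutes=5)))
        logon_rows.append((pid, last + pd.Timedelta(hours=12)))
        add_results(
            pid,
            [reg + pd.Timedelta(days=30),
             census - pd.Timedelta(days=150),
             census - pd.Timedelta(days=90),
             census - pd.Timedelta(days=30)],
        )

    # persistent users: 6,023 (a logon within 6 months of census)
    for i in range(6023):
        pid = f"F{counter:06d}"; counter += 1
        reg = reg_spread(i, 250, 1000)
        patient_rows.append(_fixture_patient(pid, reg, rng, center_ids))
        logon_rows.append((pid, reg + pd.Timedelta(days=3, hours=8, minutes=45)))
        logon_rows.append((pid, reg + pd.Timedelta(days=60, hours=13)))
        logon_rows.append((pid, census - pd.Timedelta(days=60 - (i % 30)) + pd.Timedelta(hours=18)))
        add_results(
            pid,
            [reg + pd.Timedelta(days=25),
             census - pd.Timedelta(days=200),
             census - pd.Timedelta(days=100)],
        )

    patients = pd.DataFrame(
        patient_rows,
        columns=["patient_id", "registration_date", "age_years", "gender",
                 "treatment", "deprivation_decile", "center_id"],
    )
    logons = pd.DataFrame(logon_rows, columns=["patient_id", "timestamp"])
    logons = logons.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)
    results = pd.DataFrame(result_rows, columns=["patient_id", "sample_date"])
    results = results.sort_values(["patient_id", "sample_date"], kind="stable").reset_index(drop=True)
    return Cohort(patients, centers, logons, results)


def make_activity_fixture(census_date: str | pd.Timestamp = "2009-09-07") -> Cohort:
    """Deterministic 5,808-user cohort for the activity analyses.

    Every user has at least three logons spanning at least 3 months
    after first logon; 5,085 satisfy the persistent-user rules at census
    and 723 the late-lapse rules.
    """
    census = pd.Timestamp(census_date)
    rng = np.random.default_rng(58085085)  # fixture-internal, fixed
    centers = _fixture_centers(census)
    center_ids = list(centers["center_id"])

    patient_rows, logon_rows, result_rows = [], [], []
    counter = 0

    # persistent: 5,085
    for i in range(5085):
        pid = f"A{counter:06d}"; counter += 1
        reg = (census - pd.Timedelta(days=600 + (i * 13) % 500)).normalize()
        patient_rows.append(_fixture_patient(pid, reg, rng, center_ids))
        logon_rows.append((pid, reg + pd.Timedelta(days=2, hours=9)))
        logon_rows.append((pid, reg + pd.Timedelta(days=50, hours=12, minutes=30)))
        logon_rows.append((pid, census - pd.Timedelta(days=60 - (i % 30)) + pd.Timedelta(hours=15)))
        result_rows.append((pid, (reg + pd.Timedelta(days=20)).normalize()))
        result_rows.append((pid, (census - pd.Timedelta(days=120)).normalize()))

    # late lapsers: 723
    for i in range(723):
        pid = f"A{counter:06d}"; counter += 1
        reg = (census - pd.Timedelta(days=750 + (i * 17) % 400)).normalize()
        patient_rows.append(_fixture_patient(pid, reg, rng, center_ids))
        logon_rows.append((pid, reg + pd.Timedelta(days=2, hours=10)))
        logon_rows.append((pid, reg + pd.Timedelta(days=50, hours=11)))
        logon_rows.append((pid, reg + pd.Timedelta(days=150 + (i % 20), hours=16)))
        result_rows.append((pid, (reg + pd.Timedelta(days=30)).normalize()))
        result_rows.append((pid, (census - pd.Timedelta(days=120)).normalize()))
        result_rows.append((pid, (census - pd.Timedelta(days=50)).normalize()))

    patients = pd.DataFrame(
        patient_rows,
        columns=["patient_id", "registration_date", "age_years", "gender",
                 "treatment", "deprivation_decile", "center_id"],
    )
    logons = pd.DataFrame(logon_rows, columns=["patient_id", "timestamp"])
    logons = logons.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)
    results = pd.DataFrame(result_rows, columns=["patient_id", "sample_date"])
    results = results.sort_values(["patient_id", "sample_date"], kind="stable").reset_index(drop=True)
    return Cohort(patients, centers, logons, results)
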