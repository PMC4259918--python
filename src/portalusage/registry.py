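"""Domain model for a patient-portal registry extract.

The unit of analysis is a registrant of an online renal patient portal:
a patient record with registration date and covariates, a link to the
treating renal center, and two per-patient event streams extracted from
the server audit log — portal logons (date-time, minute resolution) and
blood-test result uploads (date only). A fixed census date closes every
observation window.

Four CSV tables carry a dataset::

    patients.csv  patient_id,registration_date,age_years,gender,treatment,
                  deprivation_decile,center_id
    centers.csv   center_id,rpv_start_date,assisted_start,rrt_population
    logons.csv    patient_id,timestamp
    results.csv   patient_id,sample_date

Dates are ISO-8601; logon timestamps carry time-of-day ("YYYY-MM-DD HH:MM");
booleans are written ``true``/``false``. Missing covariates are retained
(empty field) and dropped per-analysis, complete-case.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Length of an analysis month in days (365.25 / 12). All interval
#: arithmetic ("6 months before census", "logons per month") uses this.
MONTH_DAYS: float = 30.4375

#: The "first month post registration" gate is 30 exact days, boundary
#: inclusive (a logon on day 30 still counts as first-month).
FIRST_MONTH_DAYS: float = 30.0

DAY = np.timedelta64(1, "D")


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Treatment(str, enum.Enum):
    """Treatment modality at registration.

    ``HOSPITAL_HD`` is in-center hemodialysis (monthly blood monitoring);
    ``HOME_HD_PD`` pools home hemodialysis with peritoneal dialysis;
    ``NOT_RRT`` covers chronic kidney disease managed without renal
    replacement therapy.
    """

    HOSPITAL_HD = "hospital_hd"
    HOME_HD_PD = "home_hd_pd"
    TRANSPLANT = "transplant"
    NOT_RRT = "not_rrt"


class AgeBand(str, enum.Enum):
    LT18 = "lt18"
    A18_34 = "a18_34"
    A35_54 = "a35_54"
    A55_74 = "a55_74"
    GT75 = "gt75"


class DeprivationGroup(str, enum.Enum):
    HIGH = "high"      # deciles 1-2, most deprived
    MIDDLE = "middle"  # deciles 3-8
    LOW = "low"        # deciles 9-10, least deprived


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    registration_date: pd.Timestamp
    age_years_at_registration: float | None
    gender: Gender | None
    treatment: Treatment | None
    deprivation_decile: int | None
    center_id: str


@dataclass(frozen=True)
class CenterRecord:
    center_id: str
    rpv_start_date: pd.Timestamp
    assisted_start: bool
    rrt_population: int


@dataclass(frozen=True)
class CensusSpec:
    """The fixed extraction date of the analyzed log snapshot."""

    census_date: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "census_date", pd.Timestamp(self.census_date))


@dataclass
class Cohort:
    """A full four-table dataset with per-patient streams sorted ascending.

    ``patients`` and ``centers`` are one row per entity; ``logons`` and
    ``results`` are long event tables sorted by (patient_id, time).
    """

    patients: pd.DataFrame
    centers: pd.DataFrame
    logons: pd.DataFrame
    results: pd.DataFrame

    def logons_by_patient(self) -> Mapping[str, np.ndarray]:
        """datetime64 logon timestamps per patient, sorted ascending."""
        return {
            pid: grp["timestamp"].to_numpy()
            for pid, grp in self.logons.groupby("patient_id", sort=False)
        }

    def results_by_patient(self) -> Mapping[str, np.ndarray]:
        """datetime64[D]-normalized result sample dates per patient, sorted."""
        return {
            pid: grp["sample_date"].to_numpy()
            for pid, grp in self.results.groupby("patient_id", sort=False)
        }


_SCHEMAS = {
    "patients": [
        "patient_id", "registration_date", "age_years", "gender",
        "treatment", "deprivation_decile", "center_id",
    ],
    "centers": ["center_id", "rpv_start_date", "assisted_start", "rrt_population"],
    "logons": ["patient_id", "timestamp"],
    "results": ["patient_id", "sample_date"],
}


def age_band(age_years: float) -> AgeBand:
    """Assign an age to its analysis band.

    Bands are contiguous half-open intervals [0,18), [18,35), [35,55),
    [55,75), [75,inf) — lower edge inclusive, so 35.0 falls in 35-54 and
    75.0 in 75-and-over.
    """
    if age_years is None or not np.isfinite(age_years) or age_years < 0:
        raise ValidationError(f"age must be a non-negative number, got {age_years!r}")
    if age_years < 18:
        return AgeBand.LT18
    if age_years < 35:
        return AgeBand.A18_34
    if age_years < 55:
        return AgeBand.A35_54
    if age_years < 75:
        return AgeBand.A55_74
    return AgeBand.GT75


def deprivation_group(decile: int) -> DeprivationGroup:
    """Consolidate a rank-deprivation decile (1 = most deprived) into the
    three-level grouping: deciles 1-2 high, 3-8 middle, 9-10 low."""
    if decile not in range(1, 11):
        raise ValidationError(f"deprivation decile must be in 1..10, got {decile!r}")
    if decile <= 2:
        return DeprivationGroup.HIGH
    if decile <= 8:
        return DeprivationGroup.MIDDLE
    return DeprivationGroup.LOW


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}.csv is missing column(s): {', '.join(missing)}")


def _parse_enum(series: pd.Series, enum_cls: type[enum.Enum], name: str) -> pd.Series:
    valid = {e.value for e in enum_cls}
    bad = series.dropna().loc[lambda s: ~s.isin(valid)]
    if len(bad):
        raise ValidationError(
            f"invalid {name} value(s): {sorted(bad.unique())}; expected {sorted(valid)}"
        )
    return series


def validate_cohort(cohort: Cohort, census: CensusSpec | None = None) -> None:
    """Check referential integrity and event-stream invariants.

    Raises :class:`ValidationError` naming the offending patients when a
    logon predates its owner's registration, an event references an unknown
    patient, a patient references an unknown center, or (when ``census`` is
    given) a registration postdates the census date.
    """
    patients, centers = cohort.patients, cohort.centers
    known = set(patients["patient_id"])
    orphan_centers = set(patients["center_id"]) - set(centers["center_id"])
    if orphan_centers:
        raise ValidationError(f"patients reference unknown center(s): {sorted(orphan_centers)}")
    for name, events in (("logons", cohort.logons), ("results", cohort.results)):
        orphans = set(events["patient_id"]) - known
        if orphans:
            raise ValidationError(
                f"{name} reference unknown patient(s): {sorted(orphans)[:10]}"
            )
    reg = patients.set_index("patient_id")["registration_date"]
    if len(cohort.logons):
        lg = cohort.logons
        early = lg["timestamp"].to_numpy() < reg.loc[lg["patient_id"]].to_numpy()
        if early.any():
            bad = sorted(lg.loc[early, "patient_id"].unique())
            raise ValidationError(f"logon before registration for patient(s): {bad[:10]}")
    if census is not None:
        late = patients.loc[patients["registration_date"] > census.census_date, "patient_id"]
        if len(late):
            raise ValidationError(
                f"registration after census date for patient(s): {sorted(late)[:10]}"
            )


def read_tables(
    patients_path: str | Path,
    centers_path: str | Path,
    logons_path: str | Path,
    results_path: str | Path,
    validate: bool = True,
) -> Cohort:
    """Read the four CSV tables into a typed, sorted :class:`Cohort`.

    Event tables come back sorted by (patient_id, time). With
    ``validate=True`` (default) referential integrity and the
    logon-after-registration invariant are enforced.
    """
    patients = pd.read_csv(patients_path, dtype={"patient_id": str, "center_id": str})
    _require_columns(patients, "patients")
    patients["registration_date"] = pd.to_datetime(patients["registration_date"])
    patients["age_years"] = pd.to_numeric(patients["age_years"], errors="raise")
    patients["gender"] = _parse_enum(patients["gender"], Gender, "gender")
    patients["treatment"] = _parse_enum(patients["treatment"], Treatment, "treatment")
    patients["deprivation_decile"] = patients["deprivation_decile"].astype("Int64")
    bad_dec = patients["deprivation_decile"].dropna()
    bad_dec = bad_dec[(bad_dec < 1) | (bad_dec > 10)]
    if len(bad_dec):
        raise ValidationError(f"deprivation_decile out of 1..10 for {len(bad_dec)} patient(s)")

    centers = pd.read_csv(centers_path, dtype={"center_id": str})
    _require_columns(centers, "centers")
    centers["rpv_start_date"] = pd.to_datetime(centers["rpv_start_date"])
    centers["assisted_start"] = centers["assisted_start"].map(
        {True: True, False: False, "true": True, "false": False}
    )
    if centers["assisted_start"].isna().any():
        raise ValidationError("assisted_start must be true/false")
    centers["rrt_population"] = centers["rrt_population"].astype(int)

    logons = pd.read_csv(logons_path, dtype={"patient_id": str})
    _require_columns(logons, "logons")
    logons["timestamp"] = pd.to_datetime(logons["timestamp"])
    logons = logons.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)

    results = pd.read_csv(results_path, dtype={"patient_id": str})
    _require_columns(results, "results")
    results["sample_date"] = pd.to_datetime(results["sample_date"]).dt.normalize()
    results = results.sort_values(["patient_id", "sample_date"], kind="stable").reset_index(drop=True)

    cohort = Cohort(patients=patients, centers=centers, logons=logons, results=results)
    if validate:
        validate_cohort(cohort)
    return cohort


def write_tables(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort back to the four canonical CSVs under ``out_dir``.

    Output is byte-stable for a given cohort: event rows sorted by
    (patient_id, time), dates as ISO days, timestamps to the minute,
    booleans as true/false.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in _SCHEMAS}

    p = cohort.patients.copy()
    p["registration_date"] = p["registration_date"].dt.strftime("%Y-%m-%d")
    p[_SCHEMAS["patients"]].to_csv(paths["patients"], index=False)

    c = cohort.centers.copy()
    c["rpv_start_date"] = c["rpv_start_date"].dt.strftime("%Y-%m-%d")
    c["assisted_start"] = c["assisted_start"].map({True: "true", False: "false"})
    c[_SCHEMAS["centers"]].to_csv(paths["centers"], index=False)

    lg = cohort.logons.sort_values(["patient_id", "timestamp"], kind="stable").copy()
    lg["timestamp"] = lg["timestamp"].dt.strftime("%Y-%m-%d %H:%M")
    lg[_SCHEMAS["logons"]].to_csv(paths["logons"], index=False)

    rs = cohort.results.sort_values(["patient_id", "sample_date"], kind="stable").copy()
    rs["sample_date"] = rs["sample_date"].dt.strftime("%Y-%m-%d")
    rs[_SCHEMAS["results"]].to_csv(paths["results"], index=False)
    return paths


def read_cohort_dir(directory: str | Path, validate: bool = True) -> Cohort:
    """Convenience: read ``patients/centers/logons/results.csv`` from one dir."""
    d = Path(directory)
    return read_tables(
        d / "patients.csv", d / "centers.csv", d / "logons.csv", d / "results.csv",
        validate=validate,
    )
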