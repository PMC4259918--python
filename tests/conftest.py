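import numpy as np
import pandas as pd
import pytest

from portalusage import CensusSpec, Cohort

CENSUS = CensusSpec("2009-09-07")


@pytest.fixture(scope="session")
def census():
    return CENSUS


def build_cohort(patients, logons, results, centers=None):
    """Assemble a Cohort from lightweight row tuples.

    patients: (pid, registration_date, age, gender, treatment, decile, center)
    logons:   (pid, timestamp);  results: (pid, sample_date)
    """
    p = pd.DataFrame(
        patients,
        columns=["patient_id", "registration_date", "age_years", "gender",
                 "treatment", "deprivation_decile", "center_id"],
    )
    p["registration_date"] = pd.to_datetime(p["registration_date"])
    lg = pd.DataFrame(logons, columns=["patient_id", "timestamp"])
    lg["timestamp"] = pd.to_datetime(lg["timestamp"])
    lg = lg.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)
    rs = pd.DataFrame(results, columns=["patient_id", "sample_date"])
    rs["sample_date"] = pd.to_datetime(rs["sample_date"]).dt.normalize()
    rs = rs.sort_values(["patient_id", "sample_date"], kind="stable").reset_index(drop=True)
    if centers is None:
        centers = pd.DataFrame(
            {
                "center_id": sorted(p["center_id"].unique()),
                "rpv_start_date": pd.Timestamp("2005-06-01"),
                "assisted_start": False,
                "rrt_population": 1000,
            }
        )
    return Cohort(patients=p, centers=centers, logons=lg, results=rs)


@pytest.fixture(scope="session")
def printed_fixture():
    from portalusage import make_printed_cohort_fixture

    return make_printed_cohort_fixture(CENSUS.census_date)


@pytest.fixture(scope="session")
def activity_fixture():
    from portalusage import make_activity_fixture

    return make_activity_fixture(CENSUS.census_date)
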