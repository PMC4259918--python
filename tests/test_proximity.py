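import numpy as np
import pandas as pd
import pytest

from portalusage import (
    CensusSpec,
    GeneratorConfig,
    generate_cohort,
    headline_fractions,
    nearest_result_interval,
    pooled_intervals,
    proximity_histogram,
    shuffle_null,
)
from portalusage.errors import ValidationError

from conftest import CENSUS


def _dates(days, origin="2008-01-01"):
    o = pd.Timestamp(origin)
    return pd.to_datetime([o + pd.Timedelta(days=int(d)) for d in days])


def test_nearest_interval_examples():
    assert nearest_result_interval("2008-05-10", _dates([0], "2008-05-10")) == 0
    assert nearest_result_interval("2008-05-08", _dates([0], "2008-05-10")) == -2
    # day 6 against results on days 0 and 10: |6-10| < |6-0| -> -4
    assert nearest_result_interval(
        pd.Timestamp("2008-01-01") + pd.Timedelta(days=6), _dates([0, 10])
    ) == -4
    assert nearest_result_interval("2008-05-10", _dates([])) is None


def test_nearest_interval_equidistant_tie_goes_positive():
    # logon on day 5, results on days 0 and 10: tie -> +5 (after the result)
    assert nearest_result_interval(
        pd.Timestamp("2008-01-01") + pd.Timedelta(days=5), _dates([0, 10])
    ) == 5


def test_nearest_interval_matches_linear_scan():
    """Binary-search nearest interval == brute-force scan, including the
    positive tie-break, over randomized instances."""
    rng = np.random.default_rng(123)
    origin = pd.Timestamp("2008-01-01")
    for _ in range(300):
        res_days = np.unique(rng.integers(0, 400, size=rng.integers(1, 12)))
        logon_day = int(rng.integers(-20, 420))
        got = nearest_result_interval(
            origin + pd.Timedelta(days=logon_day), _dates(res_days)
        )
        diffs = logon_day - res_days  # positive = logon after result
        best = None
        for d in diffs:
            if best is None or abs(d) < abs(best) or (abs(d) == abs(best) and d > best):
                best = int(d)
        assert got == best


def _frames(pairs, results):
    """pairs: (pid, logon day); results: (pid, result day); day 0 = origin."""
    o = pd.Timestamp("2008-01-01")
    lg = pd.DataFrame(
        {"patient_id": [p for p, _ in pairs],
         "timestamp": [o + pd.Timedelta(days=d, hours=9) for _, d in pairs]}
    )
    rs = pd.DataFrame(
        {"patient_id": [p for p, _ in results],
         "sample_date": [o + pd.Timedelta(days=d) for _, d in results]}
    )
    return lg, rs


def test_pooled_intervals_respect_patient_boundaries():
    lg, rs = _frames([("a", 10), ("b", 10)], [("a", 9), ("b", 300)])
    iv = pooled_intervals(lg, rs, CENSUS)
    assert sorted(iv.tolist()) == [-290, 1]


def test_histogram_single_bin():
    lg, rs = _frames([("a", 11), ("b", 21)], [("a", 10), ("b", 20)])
    h = proximity_histogram(lg, rs, CENSUS)
    assert h.n_in_window == 2 and h.n_logons_total == 2
    assert h.proportions[np.where(h.bin_edges == 1)[0][0]] == 1.0
    assert h.proportions.sum() == pytest.approx(h.n_in_window / h.n_logons_total)


def test_histogram_counts_no_result_logons_in_denominator():
    lg, rs = _frames([("a", 11), ("c", 50)], [("a", 10)])
    h = proximity_histogram(lg, rs, CENSUS)
    assert h.n_logons_total == 2 and h.n_in_window == 1
    assert h.proportions.sum() == pytest.approx(0.5)


def test_histogram_requires_some_results():
    lg, rs = _frames([("a", 11)], [])
    with pytest.raises(ValidationError):
        proximity_histogram(lg, rs, CENSUS)


def test_headline_fractions_conventions():
    assert headline_fractions(np.array([0, 0, 5]))["frac_after_0_1"] == pytest.approx(2 / 3)
    assert headline_fractions(np.array([-1, -2, -3]))["frac_pre_3"] == 1.0
    out = headline_fractions(np.array([20, 25, 30]))
    assert out["frac_within_14"] == 0.0
    mixed = headline_fractions(np.array([0, 1, 2, 3, -1, -4, 13, 14]))
    assert mixed["frac_after_0_3"] == pytest.approx(3 / 8)
    assert mixed["frac_pre_3"] == pytest.approx(1 / 8)
    assert mixed["frac_within_14"] == pytest.approx(5 / 8)  # 0,1,2,3,13


def test_headline_fractions_empty_rejected():
    with pytest.raises(ValidationError):
        headline_fractions(np.array([np.nan]))


@pytest.fixture(scope="module")
def null_cohort():
    cfg = GeneratorConfig(
        n_patients=150, seed=77,
        class_mixture={"never": 0, "early_lapser": 0, "late_lapser": 0, "persistent": 1.0},
        registration_window_months=(12, 30),
        initial_burst_rate=0.0, post_result_excess_rate=0.0, pre_result_bump_rate=0.0,
        baseline_rate=0.1,
    )
    cohort, _ = generate_cohort(cfg)
    return cohort, CensusSpec(cfg.census_date)


def test_shuffle_preserves_counts_and_sanity(null_cohort):
    cohort, census = null_cohort
    null = shuffle_null(cohort.logons, cohort.results, census,
                        n_permutations=100, seed=5)
    # every null histogram is built from the same number of logons
    assert null.observed.n_logons_total == len(cohort.logons)
    assert null.null_histograms.shape == (100, 57)
    # result-decoupled logons: observed proportions sit inside the null
    # envelope almost everywhere and no bin is extreme
    assert null.p_values.min() >= 1 / 101
    frac_outside = np.mean(
        (null.observed.proportions > null.null_hi)
        | (null.observed.proportions < null.null_lo)
    )
    assert frac_outside <= 0.15


def test_shuffle_results_mode_runs(null_cohort):
    cohort, census = null_cohort
    null = shuffle_null(cohort.logons, cohort.results, census,
                        n_permutations=100, seed=6, mode="shuffle_results")
    assert null.mode == "shuffle_results"
    assert null.observed.n_logons_total == len(cohort.logons)


def test_shuffle_rejects_few_permutations(null_cohort):
    cohort, census = null_cohort
    with pytest.raises(ValidationError):
        shuffle_null(cohort.logons, cohort.results, census, n_permutations=10)


def test_excess_cohort_mode_in_post_result_bins():
    cfg = GeneratorConfig(
        n_patients=200, seed=78,
        class_mixture={"never": 0, "early_lapser": 0, "late_lapser": 0, "persistent": 1.0},
        registration_window_months=(12, 30),
        initial_burst_rate=0.0, pre_result_bump_rate=0.0,
        post_result_excess_rate=0.8,
    )
    cohort, _ = generate_cohort(cfg)
    h = proximity_histogram(cohort.logons, cohort.results, CensusSpec(cfg.census_date))
    mode_bin = h.bin_edges[np.argmax(h.proportions)]
    assert 0 <= mode_bin < 3
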