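"""Factor association at the three engagement hurdles.

Portal disengagement is modelled as three binary "hurdles" derived from
the lifecycle classes:

* ``not_complete_first_logon`` — never logged on, among all registrants;
* ``early_lapse`` — early lapser, among first-logon completers with
  enough follow-up (early + late + persistent);
* ``late_lapse`` — late lapser, among late lapsers and persistent users
  (early lapsers are out: they never cleared the previous hurdle).

Each hurdle gets a maximum-likelihood logistic regression of the outcome
on patient factors (age band, gender, treatment, three-level deprivation
group) and, when center data are supplied, center factors (assisted
start, portal offered < 2 years at census, center registration-rate
quartile). Reference levels default to age 35-54, hospital hemodialysis
and middle deprivation. Covariates are complete-case: rows missing any
modelled factor are dropped.

Model reduction is backward elimination by analysis of deviance: the
factor (all levels at once) whose removal gives the largest
likelihood-ratio p-value is dropped while that p exceeds ``alpha``
(default 0.05), and the removal trail is retained on the result.

:class:`HurdleLogit` wraps the whole stage statsmodels-style:
``HurdleLogit(classes, patients, hurdle=...).fit()`` returns a
:class:`FactorModelResult` with per-level odds ratios, 95% CIs and a
``summary()`` table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .classification import UsageClass
from .errors import SeparationError, ValidationError
from .registry import age_band, deprivation_group

HURDLES = ("not_complete_first_logon", "early_lapse", "late_lapse")

DEFAULT_REFERENCES: dict[str, str] = {
    "age_band": "a35_54",
    "treatment": "hospital_hd",
    "deprivation_group": "middle",
}

_PARAM_RE = re.compile(r"C\((?P<col>\w+).*?\)\[T\.(?P<level>[^\]]+)\]")


@dataclass
class FactorModelResult:
    """Fitted (and possibly reduced) hurdle logistic model.

    ``table`` holds one row per non-reference level of every retained
    factor: factor, level, odds_ratio, ci_low, ci_high. ``removed`` maps
    eliminated factors to the deviance-test p-value at their removal
    step. Reference levels carry OR 1 implicitly and are not listed.
    """

    hurdle: str
    table: pd.DataFrame
    retained: list[str]
    removed: dict[str, float]
    references: dict[str, str]
    n_complete_case: int
    n_events: int
    deviance: float
    llf: float

    def odds_ratio(self, factor: str, level: str) -> float:
        row = self.table[(self.table["factor"] == factor) & (self.table["level"] == level)]
        if row.empty:
            raise KeyError(f"{factor}={level} not in retained model")
        return float(row["odds_ratio"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Hurdle logistic model: {self.hurdle}",
            f"n = {self.n_complete_case} (events = {self.n_events}), "
            f"deviance = {self.deviance:.2f}, loglik = {self.llf:.2f}",
            "",
            "factor               level        OR     95% CI",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['factor']:<20} {r['level']:<10} {r['odds_ratio']:6.2f}  "
                f"({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            )
        for factor, ref in self.references.items():
            if factor in self.retained:
                lines.append(f"{factor:<20} {ref:<10}   1.00  (reference)")
        if self.removed:
            lines.append("")
            lines.append(
                "removed: "
                + ", ".join(f"{f} (p={p:.3f})" for f, p in self.removed.items())
            )
        return "\n".join(lines)


def derive_covariates(
    patients: pd.DataFrame,
    centers: pd.DataFrame | None = None,
    census=None,
) -> pd.DataFrame:
    """Patient-level model covariates from the raw registry tables.

    Produces ``age_band``, ``gender``, ``treatment`` and
    ``deprivation_group`` per patient (missing stays missing); with
    ``centers`` and ``census`` also ``assisted_start``,
    ``center_recent`` (portal offered < 2 years at census) and
    ``center_rate_quartile`` (quartile of registered-RRT-count /
    RRT-population across centers).
    """
    out = patients[["patient_id", "gender", "treatment"]].copy()
    out["age_band"] = patients["age_years"].map(
        lambda a: age_band(float(a)).value if pd.notna(a) else None
    )
    out["deprivation_group"] = patients["deprivation_decile"].map(
        lambda d: deprivation_group(int(d)).value if pd.notna(d) else None
    )
    if centers is not None:
        c = centers.set_index("center_id")
        out["assisted_start"] = patients["center_id"].map(c["assisted_start"]).astype(bool)
        if census is not None:
            census = pd.Timestamp(census.census_date if hasattr(census, "census_date") else census)
            age_days = (census - c["rpv_start_date"]).dt.days
            out["center_recent"] = patients["center_id"].map(age_days < 730).astype(bool)
        rrt = patients[patients["treatment"].isin(["hospital_hd", "home_hd_pd", "transplant"])]
        registered = rrt.groupby("center_id").size().reindex(c.index, fill_value=0)
        rate = registered / c["rrt_population"]
        quart = pd.qcut(rate.rank(method="first"), 4, labels=["Q1", "Q2", "Q3", "Q4"])
        out["center_rate_quartile"] = patients["center_id"].map(
            pd.Series(quart.astype(str), index=c.index)
        )
    return out


def build_hurdle_cohort(
    classes: pd.DataFrame,
    patients: pd.DataFrame,
    hurdle: str,
    centers: pd.DataFrame | None = None,
    census=None,
    factors: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome vector and complete-case covariate table for one hurdle."""
    if hurdle not in HURDLES:
        raise ValidationError(f"unknown hurdle {hurdle!r}; expected one of {HURDLES}")
    merged = classes.merge(patients, on="patient_id", how="left")
    cls = merged["usage_class"]
    if hurdle == "not_complete_first_logon":
        eligible = pd.Series(True, index=merged.index)
        positive = cls == UsageClass.NEVER_LOGGED_ON.value
    elif hurdle == "early_lapse":
        eligible = cls.isin(
            [UsageClass.EARLY_LAPSER.value, UsageClass.LATE_LAPSER.value,
             UsageClass.PERSISTENT_USER.value]
        )
        positive = cls == UsageClass.EARLY_LAPSER.value
    else:
        eligible = cls.isin([UsageClass.LATE_LAPSER.value, UsageClass.PERSISTENT_USER.value])
        positive = cls == UsageClass.LATE_LAPSER.value
    sub = merged[eligible].reset_index(drop=True)
    if sub.empty:
        raise ValidationError(f"hurdle cohort for {hurdle!r} is empty")
    pos = positive[eligible].reset_index(drop=True)
    cov = derive_covariates(sub, centers, census)
    if factors is None:
        factors = [c for c in cov.columns if c != "patient_id"]
    cov = cov[["patient_id", *factors]]
    keep = cov[list(factors)].notna().all(axis=1).to_numpy()
    cov = cov[keep].reset_index(drop=True)
    y = pos[keep].reset_index(drop=True).astype(int)
    y.name = "outcome"
    return y, cov


def _term(col: str, series: pd.Series, references: Mapping[str, str]) -> str:
    if pd.api.types.is_bool_dtype(series) or series.dropna().isin([True, False]).all():
        return f"C({col})"
    ref = references.get(col)
    if ref is not None:
        return f'C({col}, Treatment(reference="{ref}"))'
    return f"C({col})"


def _check_degeneracy(y: pd.Series, X: pd.DataFrame, factors: Sequence[str]) -> None:
    for col in factors:
        tab = pd.crosstab(X[col], y)
        if tab.shape[1] < 2:
            raise SeparationError(
                f"outcome is constant within the cohort; cannot fit (factor {col})"
            )
        degenerate = tab.index[(tab == 0).any(axis=1)]
        if len(degenerate):
            raise SeparationError(
                f"perfect separation in factor {col!r}: level(s) "
                f"{list(map(str, degenerate))} have a constant outcome"
            )
        if len(tab) < 2:
            raise SeparationError(f"factor {col!r} has a single level (aliased)")


def fit_factor_model(
    outcome: pd.Series,
    covariates: pd.DataFrame,
    references: Mapping[str, str] | None = None,
    factors: Sequence[str] | None = None,
    hurdle: str = "custom",
    check_separation: bool = True,
) -> FactorModelResult:
    """Maximum-likelihood logistic fit of a binary outcome on factors.

    Per-level odds ratios are exp(coefficient) against the reference
    level, with Wald 95% CIs exp(coef +/- 1.96 SE). Perfect separation
    raises :class:`SeparationError` naming the factor; a singular design
    raises it listing the aliased columns.
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}
    if factors is None:
        factors = [c for c in covariates.columns if c != "patient_id"]
    if outcome.nunique() < 2:
        raise SeparationError("outcome has a single class; nothing to fit")
    data = covariates.copy()
    data["outcome"] = np.asarray(outcome, dtype=int)
    if check_separation:
        _check_degeneracy(data["outcome"], data, factors)

    terms = [_term(c, data[c], references) for c in factors]
    formula = "outcome ~ " + (" + ".join(terms) if terms else "1")
    model = smf.glm(formula, data=data, family=sm.families.Binomial())
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        aliased = [
            model.exog_names[j]
            for j in range(r.shape[1])
            if abs(r[j, j]) < 1e-8
        ]
        raise SeparationError(f"singular design; aliased column(s): {aliased}")
    fit = model.fit()

    rows = []
    ci = fit.conf_int()
    for name, coef in fit.params.items():
        if name == "Intercept":
            continue
        m = _PARAM_RE.match(name)
        factor_name = m.group("col") if m else name
        level = m.group("level") if m else name
        rows.append(
            {
                "factor": factor_name,
                "level": level,
                "odds_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(ci.loc[name, 0])),
                "ci_high": float(np.exp(ci.loc[name, 1])),
            }
        )
    table = pd.DataFrame(rows, columns=["factor", "level", "odds_ratio", "ci_low", "ci_high"])
    result = FactorModelResult(
        hurdle=hurdle,
        table=table,
        retained=list(factors),
        removed={},
        references={k: v for k, v in references.items() if k in factors},
        n_complete_case=len(data),
        n_events=int(data["outcome"].sum()),
        deviance=float(fit.deviance),
        llf=float(fit.llf),
    )
    result._fit = fit  # keep the statsmodels results for diagnostics
    return result


def eliminate_factors(
    outcome: pd.Series,
    covariates: pd.DataFrame,
    references: Mapping[str, str] | None = None,
    factors: Sequence[str] | None = None,
    alpha: float = 0.05,
    hurdle: str = "custom",
) -> FactorModelResult:
    """Backward elimination by analysis of deviance.

    Starting from the full model, repeatedly refit without each
    remaining factor, compute the likelihood-ratio (deviance difference
    vs chi-square) p-value of the removal, and drop the factor with the
    largest p while it exceeds ``alpha``. Factors are removed whole (all
    levels at once). Deterministic given the data and alpha.
    """
    if factors is None:
        factors = [c for c in covariates.columns if c != "patient_id"]
    remaining = list(factors)
    removed: dict[str, float] = {}
    current = fit_factor_model(
        outcome, covariates, references, remaining, hurdle, check_separation=True
    )
    while remaining:
        candidates: list[tuple[str, float]] = []
        for f in remaining:
            reduced_factors = [x for x in remaining if x != f]
            reduced = fit_factor_model(
                outcome, covariates, references, reduced_factors, hurdle,
                check_separation=False,
            )
            dev_diff = reduced.deviance - current.deviance
            df_diff = len(current.table) - len(reduced.table)
            p = float(stats.chi2.sf(max(dev_diff, 0.0), max(df_diff, 1)))
            candidates.append((f, p))
        worst, worst_p = max(candidates, key=lambda t: (t[1], t[0]))
        if worst_p <= alpha:
            break
        remaining.remove(worst)
        removed[worst] = worst_p
        current = fit_factor_model(
            outcome, covariates, references, remaining, hurdle, check_separation=False
        )
    current.removed = removed
    current.retained = remaining
    return current


class HurdleLogit:
    """statsmodels-style front end for one hurdle model.

    >>> model = HurdleLogit(classes, patients, hurdle="early_lapse")
    >>> res = model.fit()            # with backward elimination
    >>> print(res.summary())
    """

    def __init__(
        self,
        classes: pd.DataFrame,
        patients: pd.DataFrame,
        hurdle: str,
        centers: pd.DataFrame | None = None,
        census=None,
        references: Mapping[str, str] | None = None,
        factors: Sequence[str] | None = None,
    ):
        self.hurdle = hurdle
        self.references = references
        self.outcome, self.covariates = build_hurdle_cohort(
            classes, patients, hurdle, centers, census, factors
        )
        # constant factors carry no information and would alias the design
        self.factors = [
            c for c in self.covariates.columns
            if c != "patient_id" and self.covariates[c].nunique() > 1
        ]

    def fit(self, eliminate: bool = True, alpha: float = 0.05) -> FactorModelResult:
        if eliminate:
            return eliminate_factors(
                self.outcome, self.covariates, self.references, self.factors,
                alpha, self.hurdle,
            )
        return fit_factor_model(
            self.outcome, self.covariates, self.references, self.factors, self.hurdle
        )


def compare_to_reference(
    registered_counts: Sequence[int] | pd.Series,
    population_counts: Sequence[int] | pd.Series,
) -> dict:
    """Per-stratum registration proportions and a Pearson chi-square
    test of the registered / not-registered x stratum table.

    With a single stratum the test is undefined (df = 0) and
    ``chi_square`` / ``p`` come back as None.
    """
    reg = np.asarray(registered_counts, dtype=float)
    pop = np.asarray(population_counts, dtype=float)
    if reg.shape != pop.shape:
        raise ValidationError("strata of registered and population counts must align")
    if np.any(reg > pop):
        raise ValidationError("registered count exceeds population in some stratum")
    props = reg / pop
    if reg.size < 2:
        return {"proportions": props, "chi_square": None, "df": 0, "p": None}
    table = np.vstack([reg, pop - reg])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"proportions": props, "chi_square": float(chi2), "df": int(dof), "p": float(p)}
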