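# Methods

This note documents the models, rule boundaries, numerical choices and
known limitations behind `portalusage`.

## Time arithmetic

All month-valued intervals use an analysis month of 365.25/12 =
30.4375 days; the "first month post registration" gate is 30 exact
days, boundary inclusive. Both are overridable
(`ClassificationParams.month_days`, `early_window_days`). Rule
boundaries are evaluated on calendar dates: a logon's time-of-day never
moves it across a window edge, because registration, census and result
events are date-valued. Dates are ISO-8601 throughout; logon timestamps
carry minute resolution (needed for the hour-of-day histogram).

## Lifecycle classification

Labels are assigned in a fixed priority order: insufficient follow-up,
never logged on, early lapser, late lapser, persistent user. The order
matters — a patient whose only logon is in week 1, with nothing since
and several later results, satisfies both the early and the late rule
and is an early lapser. Boundary conventions: a logon on day 30 is
still first-month; a last-logon-to-census gap of exactly 6 analysis
months counts as lapsed; a result dated the same day as the last logon
does not count toward the ≥ 2-results requirement ("strictly after").

Two observation-window restrictions exist because lapse behaviour
cannot be judged on freshly registered patients. The registration rule
excludes anyone enrolled within 6 months of census. The first-logon
rule excludes anyone whose first logon falls within 3 months of census
while still counting zero-logon registrants as never-logged-on; it is
the restriction used for the lapse analyses, the hurdle models and the
benchmark percentages. The two rules are deliberately not merged: they
select different cohorts and both are first-class parameters.

## Survival of use

Use duration is last logon minus first logon, in analysis months. A
duration is censored (read as "possibly still in use") when the last
logon is within 6 months of census, or when fewer than 2 results
postdate it — the latter also censors patients who used the portal
until death, since their result stream stops too; no separate death
flag exists in audit-log data. Time origin is first logon.

Estimation is the Kaplan–Meier product-limit with Greenwood-based,
log-transformed 95% pointwise intervals, as implemented by lifelines;
events precede censorings at tied times. `attrition_rate` is simple
secant arithmetic on the fitted step function,
(S(t0) − S(t1)) / ((t1 − t0)/12), and `curve_from_points` wraps an
externally reported survival series so the same arithmetic applies to
published checkpoint probabilities.

## Activity intensity

Two denominators for logons/month are first-class and reports name
which was used: registration→census (any user with ≥ 1 logon) and
first→last logon (restricted to ≥ 3 logons spanning ≥ 3 months, since
a rate over a day-long span is meaningless). The natural logarithm is
used for the quartiled quantity; the choice of log base cannot change
quartile membership. Quartiling is implemented rank-based — stable
order by (log rate, patient id), split into four parts differing in
size by at most one — which realizes the 25/50/75 empirical percentile
cuts, sends a value sitting exactly on a cut to the lower quartile, and
keeps the assignment order-invariant under ties. The top-5% flag takes
the ⌈0.05·n⌉ largest raw rates with the same tie-breaking. The hour
histogram refuses input whose timestamps are all exactly midnight, the
signature of date-only data (a genuine all-midnight stream is
indistinguishable and also refused).

## Result proximity

For each logon the signed whole-day interval to the closest result of
the same patient is computed on calendar dates; positive means the
logon follows the result. An exact equidistant tie is assigned the
positive interval — post-result viewing is the object of study — and
this is a documented convention, not a claim about the data. The
histogram uses 1-day bins over ±28 days by default; proportions are
shares of all supplied logons, so the histogram sums to
n_in_window/n_total, and headline fractions are reported with the
defined-interval denominator alongside the all-logons count so either
normalization can be formed.

Internally the whole cohort is embedded on one integer-day axis with a
10⁷-day gap between patients, so a single sorted array and one
`searchsorted` resolve every nearest-result query; a cross-patient
"nearest" candidate is ≥ 5·10⁶ days away and is reported as undefined.

The permutation null redraws each patient's logon times (or result
dates) uniformly within that patient's own window — first logon to
census — preserving per-patient counts. Per-patient (rather than
pooled) shuffling is deliberate: pooling would destroy per-patient rate
heterogeneity and overstate significance. Envelopes are pointwise
2.5–97.5 null percentiles; p-values are the add-one estimator
(1 + #{null ≥ observed}) / (1 + B). The null's window starts at the
observed first logon, so the observed minimum is slightly more
concentrated at the window edge than a null draw; with cohort-sized
inputs the effect on per-bin proportions is negligible (the calibration
test bounds it).

## Hurdle models

Outcomes: never-logged-on among all registrants; early lapse among
early + late + persistent (the completers with adequate follow-up);
late lapse among late + persistent only, because early lapsers never
cleared the previous hurdle. Covariates are complete-case per model.
Age is banded at registration ([0,18), [18,35), [35,55), [55,75),
[75,∞), lower edge inclusive); deprivation deciles collapse to
high (1–2) / middle (3–8) / low (9–10). Center covariates are joined
from the centers table: assisted start, portal offered < 2 years at
census, and the quartile of the center's registration rate
(registered-RRT-count / RRT population, ranked then `qcut`).

Fits are maximum-likelihood logistic (statsmodels GLM, binomial);
odds ratios are exp(coef) with Wald 95% intervals exp(coef ± 1.96 SE).
Backward elimination drops whole factors: at each step the factor
whose removal yields the largest likelihood-ratio p (deviance
difference vs chi-square on the dummy-count difference) is removed
while that p exceeds α = 0.05, so α = 0 strips the model to the
intercept and α = 1 retains everything. Perfect separation (a factor
level with a constant outcome) and singular designs are detected and
raised as explicit errors naming the factor or aliased columns; the
`HurdleLogit` front end additionally drops constant factors before
fitting, since they carry no information. The population comparison
uses Pearson's chi-square without continuity correction; a single
stratum has df 0 and the statistic is reported as not applicable.

## Synthetic cohorts

The generator emulates the structure the analyses assume, not any
particular registry's empirical distributions. Defaults: census
2009-09-07; registrations uniform 1–42 months pre-census; covariate
marginals shaped like a renal registry (≈ 60% male, middle-aged and
older adults dominant, treatment split hospital HD / home dialysis /
transplant / non-RRT CKD ≈ 19/7/33/41%, deciles uniform); lifecycle
mixture never/early/late/persistent = 0.23/0.08/0.13/0.56, optionally
covariate-dependent via a callable. Result schedules are uniform
25–35 d intervals for hospital HD (monthly monitoring) and 90–365 d
otherwise. Logons superpose homogeneous Poisson components — baseline
0.066/day (≈ 2/month) scaled by a per-patient log-normal multiplier
(σ = 0.6, producing the heavy-tailed rate spread real logs show), a
14-day registration burst at 0.4/day, a 3-day post-result excess at
0.6/day and a 3-day pre-result bump at 0.12/day — truncated by class:
never (no logons), early (within day 25), late (until a stop date
drawn from a 0.06/month geometric hazard, clipped ≥ 7 months before
census with ≥ 2 results guaranteed afterwards), persistent (to
census). Classes infeasible for a registration date (late lapse too
close to census) are downgraded to persistent and the emitted ground
truth is the class actually realized. Margins (day 25 vs the 30-day
rule, 7 vs 6 months) keep generated cases strictly inside rule
boundaries so label recovery is a fair test of the classifier, not of
boundary conventions.

What the generator does not emulate: calendar structure (weekday or
holiday effects on results), shared family logons, center-level
recruitment dynamics, or any fitted correspondence to a real
registry's covariate joint distribution. Passing recovery tests
therefore demonstrates rule correctness and statistical calibration,
not real-world classification accuracy.

The two deterministic fixtures construct event streams whose
classification realizes a published cohort flow exactly (11,352
registrants → 2,634 never / 469 too-recent / 822 early / 1,404 late /
6,023 persistent; 5,808 span-eligible users → 5,085 persistent / 723
late). Internal covariate draws use fixed seeds so the fixtures are
byte-stable. The late-lapse remainder is 1,404 by arithmetic
(8,249 − 822 − 6,023); sources that quote 1,401 for the late-lapse
model cohort are not silently reconciled.

## Problem sizes in tests

The default suite uses cohorts of 150–5,000 synthetic patients, 100–999
permutations, and 200 logistic replicates of n = 5,000 — sizes chosen
so each statistical check has comfortable power (3-SE margins, ≥ 99%
recovery) while the whole suite runs in well under a minute of compute
per heavy test. All randomness is seeded; reruns are exact.

## Known limitations

Deprivation deciles are taken as input (no postcode lookup); result
values, letters and session content are out of scope; death is only
proxied by the result stream; no mixed-effects or smooth-age models;
no multiple-testing correction across the three hurdle models, which
are reported as three separate analyses.
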