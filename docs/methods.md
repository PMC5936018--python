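# Methods

## Cohort and outcome

The analysis operates on a retrospective decedent design: membership and the
outcome are defined backward from the date of death. A patient enters the
**any-nursing cohort** if they are 19 or older at death (whole years between
birth and death dates), died inside the study period when one is given, and
have at least one nursing visit dated on or after their cancer diagnosis, on
or before death, and within the outcome window (default 182 days before
death; both window ends closed, so visits on the index date and on the death
date qualify). The **EOL sub-cohort** additionally requires an in-window
visit with *effective* end-of-life intent.

**Intent reclassification.** Recorded visit intent is `standard` or `eol`.
From a patient's first `eol`-intent visit onward, every visit — including
standard-intent visits on the same calendar day — is treated as end-of-life.
The rule is monotone (never reverts) and idempotent; both properties are
tested. The diagnosis-date constraint is applied to *every* counted visit,
including the qualifying EOL visit (the stricter of the two readings of the
inclusion rule).

**Outcome.** For each EOL sub-cohort member,
`days_to_first_eol = first in-window effective-EOL visit − (death − 182 d)`,
an integer in [0, 182]; 182 means initiation on the death date itself. All
date arithmetic is in whole days; any computed value outside [0, 182] aborts
the run rather than being clipped, since it can only arise from inconsistent
inputs.

**Weekly tabulation.** Service use is tabulated in 26 death-anchored 7-day
bins (week 26 = days 0–6 before death, week 1 the earliest bin). Because the
window holds 183 distinct days, the single extra day (a visit exactly 182
days before death) is folded into week 1. Within one week a patient counts in
exactly one category — EOL wins when both intents occur — but may move from
standard to EOL across weeks.

## Regional comparison

Region summaries are the unadjusted mean and SD of the outcome plus
(age-band × sex) stratum means, with age bands {19–59, 60–69, 70–79, 80+} —
four bands keep every cell populated at realistic region sizes. Regions with
no EOL members are carried with a null mean and excluded from ranking,
testing and plotting with a warning.

A chi-square statistic cannot be applied to means directly, so regions are
compared by dichotomizing each patient at the pooled median
(≤ median = early initiation) and applying Pearson's chi-square test of
homogeneity, without continuity correction, to the region × {early, late}
table (df = #regions − 1). The cut at the pooled median maximizes power
against location shifts while keeping the test distribution-free; under a
shared timing distribution the test rejects at the nominal 5% rate (verified
by simulation in the suite).

## Pared-mean benchmark

Regions are ranked ascending by mean days (lower = better); ties are broken
in favour of the larger region (this stabilizes the contributing prefix and
is seed-independent), then lexicographically. Walking down the ranking,
caseloads are accumulated until the selected regions cover at least
`threshold_fraction` (default 0.10) of the total EOL caseload — the EOL
sub-cohort n is the "eligible population" for the coverage rule, since it is
the outcome's denominator. The benchmark is the caseload-weighted mean over
that shortest qualifying prefix. With `threshold_fraction = 1` the benchmark
equals the overall weighted mean exactly.

The five method criteria are verified programmatically on every result:
benchmark ≤ overall weighted mean (excellence); benchmark ≥ best observed
region mean (achievability — some region has actually attained it); the
contributing set is exactly the ranking's qualifying prefix (pre-defined
selection); every contributing region has positive weight (full
contribution); and no region below a small-n floor (default n < 30) carries
more than its caseload share of weight. Under the plain n-weighted mean the
fifth criterion holds by construction; the check is retained as a safeguard
should an alternative weighting ever be configured. No Bayesian shrinkage is
applied — the benchmark is a plain weighted average of observed means.

## Funnel plot

The funnel displays (nᵣ, t̄ᵣ) per region against control limits
μ ± z·σ/√n, with μ the caseload-weighted pooled mean of the plotted values
and σ the pooled *within-region* patient-level SD,
σ² = Σ(nᵣ−1)sᵣ² / Σ(nᵣ−1) — a common-variance model with no overdispersion
inflation. Levels default to 95% and 99.8% with two-sided normal quantiles
z = 1.95996 and 3.09023 (the exact quantiles, not 2 and 3). Limit curves are
symmetric about μ, nest across levels, and narrow as 1/√n; under a null
cohort in which every region shares one timing distribution, ~5% / ~0.2% of
region means fall outside the respective limits (checked by a 2500-region
simulation).

**Age/sex adjustment.** Indirect standardization: with wᵣₛ the region's own
stratum weights and μ̄ₛ the pooled stratum means,
`expectedᵣ = Σₛ wᵣₛ μ̄ₛ` and `adjustedᵣ = observedᵣ − expectedᵣ + μ`.
A region whose case mix matches the pooled mix is unchanged; strata empty in
a region drop out of its expectation with the remaining weights renormalizing
automatically. Adjustment can be switched off (`adjustment: none`) to plot
crude means.

## Synthetic data generator

The generator emulates the linkage output of provincial cancer-registry /
homecare / health-insurance databases. Its default configuration fixes each
of the 28 regions' any-nursing size and EOL count to the published table
(totals 85,339 and 61,903), so cohort bookkeeping is reproduced exactly;
when a proportion is given instead of a count, the EOL sub-cohort size is
binomially sampled.

Per patient: death dates are uniform over the study window (2004-04-01 to
2009-03-31); diagnosis precedes the 182-day window by 1–913 additional days,
so every in-window visit is post-diagnosis; ages at death follow a
log-normal matched to each region's published median and IQR, floored at 19
and capped at 105; sex, comorbidity and top-income-quintile flags are
Bernoulli draws at the published region rates.

**Timing model.** The day of the first EOL visit is drawn from a normal
distribution with region-specific mean, truncated to [0, 182] and rounded to
whole days — the simplest two-parameter family consistent with the
normal-approximation control limits. `timing_sd = 0` is accepted as a
degenerate point mass. The published source gives no per-region outcome
means or SDs, so the default means are package choices echoing the reported
structure (BC regions earliest, then NS, ON latest; extremes 55 and 97 days,
with the two sub-benchmark regions sized n = 372 and n = 3663), and
`timing_sd` defaults to 35 days — a spread wide enough that initiation spans
the whole half-year, as the weekly tabulations of real cohorts show. These
defaults were set once from the narrative and are not fitted to anything.

Around the first EOL visit, Poisson numbers of standard visits
(`visit_rate_std`, default 1.5) fall uniformly before initiation and of EOL
visits (`visit_rate_eol`, default 3.0) after it; standard-only patients get
1 + Poisson(1.5) visits in-window. About 15% of patients also receive one
pre-window visit to exercise the window filter; it never affects the
outcome. Identical config + seed yields byte-identical CSVs.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: visit-intensity differences in how provinces
record nursing (hours vs visits vs monthly authorizations), cause-of-death
misclassification and registry lag, within-region correlation between
timing and demographics (timing is drawn independently of age and sex, which
is exactly what makes the adjustment-identity test informative), and any
dependence of EOL uptake on case mix. The published headline values —
overall mean 76 days, benchmark 57 days, extremes 97/55 — derive from
confidential data and are *not* reproduction targets; the suite checks their
structure (benchmark below the mean, BC/NS best, near two-fold contrast),
not their values.

## Numerical and reporting conventions

Percentages are rounded half-up to integers and means to one decimal at the
presentation layer only; CSVs keep full precision. Ranking ties prefer the
larger region; same-day standard+EOL visits resolve to EOL. The pipeline
records seed, an analysis-settings hash (output paths excluded) and the
package version in `report.json`; reruns with the same settings are
byte-identical.

## Problem sizes in the test suite

The suite exercises the full calibrated 28-region cohort (85k patients,
~400k visits, shared across tests via a session fixture), a 2500-region ×
200-patient null cohort for funnel coverage, 1000 random 28-region instances
against the brute-force pared-mean oracle, and 800 replicates for the
chi-square null rejection rate. The whole run completes in well under a
minute on one CPU.
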