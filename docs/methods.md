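# Methods

## Data model and deduplication

FAERS quarters are "$"-delimited tables keyed by PRIMARYID (one row per case
*version*) and CASEID (one logical case). The parser normalizes the common
column-name dialects through a single alias map; the legacy pre-2012 ISR
format is out of scope. Quarters are concatenated before cleaning because
follow-up versions of a case routinely arrive in later quarters.

Deduplication keeps, per CASEID, the version with the most recent FDA receipt
date (FDA_DT), breaking ties by the numerically larger PRIMARYID (numeric
comparison when both ids parse as integers, lexicographic otherwise, so the
ordering is total). A version with no FDA_DT sorts earliest, so any dated
version of the case wins over an undated one — dated records are strictly
more informative. The rule is idempotent, order-independent, and conserves
counts (kept + removed = input); these are tested as properties.

Partial dates (YYYY or YYYYMM) are imputed to the interval midpoint — July 1
or the 15th — and flagged imprecise. Midpoint imputation is unbiased for
interval statistics, and the flag lets the onset analysis exclude imputed
dates rather than silently use them.

## Disproportionality statistics

The counting unit is the report: a report mentioning a PT twice contributes
one to `a`, and at SOC level a report counts once per distinct mapped SOC.
The comparator (`c`, `d`) is all other deduplicated reports in the window,
not a comparator-drug subset.

* ROR = (a·d)/(b·c), 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). Any
  zero cell leaves the ROR undefined with an explicit reason code; a Haldane
  +0.5 correction is available but off by default, because inventing half a
  case changes weak signals more than it stabilizes strong ones and the IC
  already covers the sparse regime.
* IC = log₂((a+0.5)/(E+0.5)) with E = (a+b)(a+c)/N — the closed-form
  shrinkage version of the BCPNN information component, defined at a = 0 —
  and IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2.
* Default flags: ROR CI lower bound > 1 with ≥3 cases; IC025 > 0. Both
  thresholds are configuration, not code. No multiple-testing correction is
  applied anywhere: disproportionality screening is hypothesis generation,
  and the false-positive behaviour of the raw thresholds is characterized by
  the null-calibration test instead.
* "Unexpected" signals are flagged by case-insensitive PT membership against
  an editable per-product label-term list; the shipped lists for the two
  CAR-T products are best-effort seeds, not MedDRA extracts.

A small consistency checker (`wald_width_feasible`) verifies that a printed
(n, CI) row can have come from the Wald construction: the implied standard
error ln(CI_hi/CI_lo)/(2·1.96) can never fall below √(1/a).

## Subgroup and subset analyses

Subgroups are total predicates over reports: sex F/M, ages 18–64 and ≥65
(under-18s omitted — spontaneous reporting for these products is essentially
adult), and their products. Reports with unknown sex or age fall outside the
corresponding strata but stay in the overall analysis, so stratum `a` counts
for an exhaustive partition (F + M + unknown) sum to the overall `a` — a
tested invariant.

Sex differences within the cohort use the F-vs-M reporting odds ratio (rows
sex, columns event, Wald CI), the standard sex-disproportionality
construction; it is antisymmetric under swapping the sexes. The death-outcome
analysis restricts *both* cohort and comparator to reports whose outcome
codes include DE, so it asks "which events distinguish fatal target-drug
reports from other fatal reports", not "which events are fatal".

Secondary malignancies are screened per HLGT-style group with the IC (the
statistic remains informative at very small counts), aggregating a report
once per group over an editable group→PT table, and paired with the group's
onset mean/median.

## Time-to-onset and the Weibull model

TTO = event date − earliest therapy-start date of a query-matching drug
entry, in whole days; negative, missing and imprecise-date intervals are
encoded in a validity flag rather than dropped silently. Onset summaries and
the Weibull fit use one onset per report (a report's onset is shared by its
reaction PTs; per-(report, PT) records exist for event-restricted summaries
such as the malignancy screen).

The two-parameter Weibull is fitted by maximum likelihood: the profile score
in the shape is monotone, so the shape MLE comes from deterministic
root-finding (tolerance 10⁻¹²) and the scale in closed form. 95% CIs are
Wald on (log α, log β) from the numerically evaluated observed information —
log-parameterization guarantees positive bounds. Likelihood-ratio CIs were
considered and not implemented; at the sample sizes involved (hundreds of
onsets) the Wald and profile intervals are indistinguishable at the second
decimal. Day-0 onsets (common for infusion-reaction-type events) lie outside
the Weibull support; the default shifts them to 0.5 day, with drop and
+1-day offset as alternatives. No censoring model is used — only observed
onsets are fitted.

Failure-type classification is a total function of the shape CI: early if
the CI lies below 1, wear-out if above, random if it straddles 1,
indeterminate for failed fits. Note that fitting day-*floored* data raises
the estimated shape slightly relative to the continuous-time parameter (the
pipeline's synthetic fits read ≈0.48 where the generator draws at 0.43);
classification is unaffected.

## Synthetic data: what it emulates and what it does not

The generator is the package's ground-truth instrument. Per report: one
suspect drug (target products by configured share, default 5% each for the
two CAR-T-like products, else a uniform background drug); max(1, Poisson(1.7))
distinct background PTs drawn uniformly, so any given PT appears with
probability p₀ = (λ + e^−λ)/n_PT; demographics from categorical tables whose
defaults follow the marginals typical of a published CAR-T case series
(52% male, 47% aged ≥65, 78% US, 10.5% fatal outcome); therapy-start dates
uniform over 2019–2023 with Weibull onsets (background shape 0.43, scale
12.67 days — the early-failure regime characteristic of CAR-T toxicity) and
a 1–90-day receipt lag; 10% of cases re-emitted as duplicate versions with
perturbed FDA_DT and higher PRIMARYID.

An implanted (drug, PT, rate r) association adds the PT to eligible
target-drug reports with probability r·p₀ (optionally restricted to a
demographic or outcome stratum), while all other reports carry it at p₀.
This makes the expected 2×2 table — and hence the expected ROR,
r(1−p₀)/(1−r·p₀) ≈ r for small p₀ — available in closed form
(`expected_contingency`), which is what the calibration and recovery tests
check against. Default implants: CRS, neurotoxicity-type events (rates
25–50, early onset) and one late secondary malignancy per product (rate 8,
Weibull shape 2, scale 400 days — wear-out).

Not emulated: drug-name noise (misspellings, combination products),
indication/therapy complexity beyond one suspect drug per report, reporting
heterogeneity over time, and correlated event co-reporting. Passing tests
therefore demonstrate the *statistical machinery* — counting, deduplication,
estimator calibration, recovery power — under a clean generative model, not
robustness to the string-level messiness of real FAERS extracts; the
pattern-list cohort matching and alias-map parsing address that messiness
but are exercised only on synthetic name sets.

## Null calibration: why the geometric mean

Under the null the log-ROR estimate is approximately normal around 0 with
standard error √(Σ1/cell) ≈ 0.5 at expected a ≈ 4.7, so the *arithmetic*
mean of ROR estimates sits near exp(σ²/2) ≈ 1.15 even for a perfectly
calibrated implementation. Calibration is therefore asserted on the
geometric mean (within exp(±0.1) of 1 over 100 simulated null datasets of
5,000 reports) together with the flagged fraction (≤5% of PTs with ≥3
cases). At smaller datasets the ≥3-case floor itself selects upward
fluctuations and the geometric mean rises — a selection effect, not an
estimator defect; the calibration condition is pinned at 5,000 reports for
this reason.

## Problem sizes

Simulation-backed tests use 100 null datasets of 5,000 reports, 100
recovery replicates of 3,000 reports (expected implanted case counts ≥10),
and 200 Weibull fits of 676 onsets (matching a published case-series size);
the acceptance script scales the replicate counts to 30/50/100. These sizes
give Monte-Carlo error comfortably below every asserted margin while keeping
the default suite around a minute of runtime.

## Known limitations

* ROR is undefined (not approximated) for zero-cell tables unless the
  continuity correction is enabled.
* The Weibull fit ignores interval censoring from day resolution and
  truncation from the reporting window; both matter only for shape values
  far from the ones relevant here.
* PRR, EBGM/MGPS and the full-Bayes gamma-posterior BCPNN are not
  implemented; the closed-form shrinkage IC is the single Bayesian statistic.
* MedDRA is licensed: SOC/HLGT analyses require a user-supplied PT→SOC
  table, and the shipped malignancy groups and label-term lists are
  editable seeds, not dictionary extracts.
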