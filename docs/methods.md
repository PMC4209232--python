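# Methods

`riskprofiler` implements a complete workflow for comparing hospitals on
risk-adjusted short-term outcomes when only routinely collected data are
available: hospital discharge abstracts, a small set of admission-level
clinical variables, outpatient drug-dispensing records and a death registry.
Two applications are built in: 30-day mortality after admission for acute
myocardial infarction (AMI), and surgery within 48 hours of admission for
hip fracture. This note records the models, the conventions, the defaults
and the design decisions, and what the synthetic-data experiments do and do
not establish.

## Cohort construction

An index admission enters the AMI cohort when the principal diagnosis is an
AMI code (ICD-9-CM 410.xx), or when AMI appears as a secondary diagnosis and
the principal diagnosis is a recognised complication of myocardial
infarction (423.0, 427.0–427.4, 427.6, 427.8, 427.9, 429.5, 429.6, 518.4,
780.2, 799.1, 998.2). Re-admissions within 28 days of the first admission of
an episode are folded into that episode; the window anchors at the episode's
*first* admission, so admissions at days 0, 20 and 40 yield episodes at days
0 and 40. Patients must be 18–100 years old, resident in the study region,
and admitted during the study period (January–November of the study year by
default).

The hip-fracture cohort takes admissions with a hip-fracture diagnosis
(820.xx, principal or secondary) and applies seven exclusions in a fixed,
logged order: prior hip fracture within two years; age outside 65–100;
non-residence; cancer (ICD-9 140–208) on the index admission or in the
previous two years; multiple-trauma DRG (484–487); direct ICU admission; and
death within the first 48 hours without surgery. Every filter writes one row
of an attrition table, and the table always balances: excluded plus retained
equals input.

Window conventions, all configurable:

* **comorbidity lookback** — two years, half-open `[index − 730 d, index)`;
  a diagnosis on the index date itself is not "prior". Conditions are
  defined by string-prefix match on dot-stripped codes against a per-condition
  prefix map. The packaged map is a deliberately small, documented default
  (one canonical prefix family per condition); regional programmes keep
  their own curated lists, and the map is fully overridable.
* **index-admission flags** — a configurable subset of conditions (e.g.
  blood disorders, other ischaemic heart disease) may additionally be
  ascertained from the *index* admission's secondary diagnoses, reflecting
  conditions recorded as present on admission. Index secondary diagnoses
  never set the lookback flags.
* **drug exposure** — at least one dispensing of the class in the 90 days
  before admission, again half-open, with ATC-prefix classes (e.g. ACE
  inhibitors C09A+C09B; "other lipid-modifying agents" is C10 minus C10AA).
* **outcomes** — 30-day mortality counts deaths with
  `death_date − admission_date ≤ 30` (day 30 inclusive) from the death
  registry, or an in-hospital death disposition with discharge within the
  window; 48-hour surgery means the earliest qualifying procedure falls on
  calendar day 0 or 1.

Clinical variables are categorised, never imputed: systolic blood pressure
≤ 100 / > 100 mmHg / missing (100 inclusive in the low category), INR in
range 0.9–1.2 (both bounds inclusive) / out of range / missing. Missingness
is an explicit model category; only records missing *administrative* fields
(age, gender, hospital) are dropped.

## Risk-adjustment models

For each outcome two nested logistic models are built. Model A uses
discharge data only: age and gender (forced a priori) plus comorbidity
flags. Model B adds the clinical categories and drug-exposure flags.
Candidate predictors are screened by **bootstrap stepwise selection**:

1. draw a resample of size n with replacement;
2. run bidirectional stepwise selection starting from the forced-only
   model — entry by Rao score test (p ≤ 0.05), removal by Wald test
   (p > 0.05), ties broken by candidate name so the procedure is
   deterministic given the data;
3. record which candidates ended in the final model with p ≤ 0.05;
4. repeat (default 1000 replicates; replicates with separation or
   non-convergence are dropped and the denominator is the usable count);
5. retain candidates selected in ≥ 30% of usable replicates (an
   absolute-count variant is available via `min_count`).

Categorical clinical variables enter as indicator blocks (reference levels:
SBP > 100, INR in range) and are selected or dropped as a block, with
block-level score and Wald chi-square tests. Discrimination is summarised
by the apparent (in-sample) c-statistic, computed by the midrank
(Mann–Whitney) identity; ties count one half. No optimism correction is
applied, matching standard practice for descriptive model comparison.

**Operating characteristics of the retention rule.** Because every
bootstrap replicate is drawn from the same sample, a candidate's selection
frequency concentrates around its *original-sample* z-statistic rather than
its population effect (across resamples, z* ≈ N(z, 1)). At α = 0.05 the
frequency exceeds the 30% retention threshold whenever |z| ≳ 1.44, so a
predictor with no population effect is retained with probability
≈ 2Φ(−1.44) ≈ 15%, not 5%. The rule should therefore be read as a
*stability* filter on sample associations — substantially stricter than a
single p ≤ 0.05 test (which retains "noise" predictors that happen to reach
|z| > 1.96 in-sample with the same logic), but not a 5%-level family-wise
guarantee. The test suite measures this rate empirically (~17% over 150
noise-predictor experiments, consistent with the closed form).

The in-house Newton–Raphson/IRLS solver exists because the bootstrap loop
needs tens of thousands of small fits; it reproduces `statsmodels.Logit`
coefficients, standard errors and p-values to ~1e-8 (asserted in the test
suite), flags separation instead of raising, and uses step-halving for
robustness.

## Hospital profiling by direct standardisation

Hospitals are compared with a logistic model containing **one indicator per
hospital, no global intercept, and all adjustment covariates centred at
their cohort means** (continuous covariates and category indicators alike).
Each hospital coefficient is then the log-odds of the outcome for that
hospital at the cohort-average case mix. Back-transformation gives

    adjusted_j = expit(estimate_j) × K,
    K = observed events / Σ_j expit(estimate_j) · n_j.

K corrects for the non-linearity of the logistic link: the rate at the mean
case mix is not the mean rate. K is computed in a single pass from the
uncorrected inverse-logit proportions (the circular reading of the formula,
with the corrected proportions on both sides, is not used), which enforces
the conservation identity Σ_j adjusted_j · n_j = observed events exactly;
the suite checks it to 1e-8 relative. With no adjustment covariates the
model is saturated, every adjusted proportion equals the observed hospital
rate and K = 1.

Numerical conventions: hospitals with fewer than `min_volume` episodes
(default 10) are excluded from the indicator model and listed separately;
hospitals with zero or all events have unbounded ML indicators and receive
a small ridge penalty (1e-4) on their indicator coefficient only, flagged
in the output. Adjusted proportions above 1 (possible with large K) are
reported with a warning, never clipped.

**Funnel plots** place each hospital at (volume n_j, adjusted proportion)
around the overall rate, with 95% and 99.8% control limits. The default
limits use the normal approximation `target ± z·√(target(1−target)/n)`
(z = 1.96 and 3.09), clipped to [0, 1]; exact binomial limits are available.
The precision axis is the raw volume n_j. Limits are closed: a point exactly
on a limit is classified inside. No overdispersion inflation is applied —
the between-hospital variance is instead reported by the sensitivity model.

**Sensitivity analysis.** A random-intercept logistic model (Gaussian
hospital effect on the log-odds scale) is fitted by Gauss–Hermite-quadrature
maximum likelihood (25 nodes, BFGS over (β, log σ)); shrunken per-hospital
effects are posterior modes at the ML estimates. An in-house fit is used
because the available approximate-Bayes alternative failed to converge and
materially underestimated σ on a 50×300 benchmark; the quadrature fit
recovers σ = 0.5 within sampling error there and collapses cleanly to ~0
under homogeneity. With ~10 hospitals the ML variance estimate can collapse
to zero even when σ > 0 — a known small-m property, not a defect.

Profiles from the two adjustment models are compared by Spearman rank
correlation of the adjusted proportions and by concordance of the funnel
outlier flags.

## Synthetic registry generator

The generator emulates the four registry streams with fully known ground
truth. Outcomes follow

    logit P(Y=1) = c + log(1.08)·(age − 70.1) + log(0.96)·female
                   + Σ_k log(OR_k)·x_k + u_h,

with the default prevalences and odds ratios taken from the published
case-mix and full-model estimates of the two cohorts (e.g. diabetes 10.89%
/ OR 1.34; SBP ≤ 100 10.05% / OR 4.60; diuretics 20.71% / OR 1.69; hip
cohort: INR out of range 13.47% / OR 0.56, antiplatelet 13.41% / OR 0.79).
The intercept c is calibrated by bracketed root finding so the marginal
event rate matches the published crude rate (10.8% and 19.8%); hospital
effects u_h are mean-centred Gaussian with default σ = 0.2 — a typical
between-hospital spread in the profiling literature, chosen once since the
source data report none.

Comorbidity evidence is emitted as *real prior discharge rows* and drug
exposure as real dispensing rows, so the cohort builder's window logic is
exercised end to end; out-of-window and wrong-class decoy records are added
deliberately. `lookback_fraction` places a configurable share of evidence
outside the window (such evidence does not enter the outcome model, so the
builder must reproduce the effective flags exactly — asserted in the
suite). Its default is 1.0, making configured prevalences exactly the
prevalences of the effective flags.

Simplifications to keep in mind when reading test results: covariates are
mutually independent by default (only marginal prevalences are published; a
pairwise latent-Gaussian correlation hook exists but is off), clinical
missingness is completely at random, there are no inter-hospital transfer
chains and no longitudinal disease progression, and coding is perfectly
accurate. Passing tests therefore validate the *estimators and rules*, not
robustness to miscoding, informative missingness or correlated case mix.
One master seed drives everything through per-stream substreams: identical
configs give byte-identical outputs, and adding one record type never
perturbs another.

## Problem sizes used in the checks

The acceptance script runs both cohorts at the published cohort scale
(7613 patients / 62 hospitals and 6348 / 83) with 200 bootstrap replicates
per candidate set — a desk-scale choice for the selection step, also used
by the selection operating-characteristics tests. Coefficient recovery uses
50 simulations of n = 20000; funnel coverage uses 1000 hospitals of 200
patients; random-intercept recovery uses 50 hospitals × 300 patients at
σ ∈ {0, 0.5} (estimate within 25% relative at 0.5).

## Known limitations

* Apparent c only; no optimism correction or calibration statistics.
* No indirect standardisation or empirical-Bayes public-reporting variants
  beyond the stated random-intercept sensitivity model.
* Identifiers are assumed clean (no record linkage), and no ICD-9→ICD-10
  mapping is provided.
* The packaged comorbidity map is a toy default; substantive use requires a
  curated regional code list.
* The noise-retention rate of the bootstrap stepwise rule is ~15% at its
  default settings, as derived above; users wanting a stricter screen
  should raise `retain_fraction` or lower `alpha`.
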