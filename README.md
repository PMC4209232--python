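# riskprofiler

Risk-adjusted comparison of hospital outcome rates from routinely collected
data: hospital discharge abstracts, a few admission-level clinical variables
(systolic blood pressure, INR, creatinine) and outpatient drug-dispensing
records, linked to a death registry.

The package is written for health-services and outcomes researchers who ask
two questions about a regional hospital system:

1. **Does adding clinical variables and drug-prescription information to a
   discharge-data risk model improve outcome prediction?** Two nested
   logistic models are built per outcome — discharge data only vs.
   discharge + clinical + drugs — with predictors screened by a bootstrap
   stepwise procedure, and compared by their c-statistic (area under the
   ROC curve).
2. **Does the richer adjustment change which hospitals look divergent?**
   Hospitals are profiled by direct standardisation: a logistic model with
   no intercept, one indicator per hospital and covariates centred at the
   cohort mean, back-transformed as

       adjusted_j = expit(estimate_j) · K,   K = events / Σ_j p_j n_j,

   where the single-pass correction K makes adjusted expected events sum
   exactly to observed events. Profiles are drawn on funnel plots with
   95%/99.8% control limits and compared across models by Spearman rank
   correlation and outlier-flag concordance; a Gauss–Hermite random-intercept
   model provides the multilevel sensitivity analysis.

Two applications ship ready-made: 30-day mortality after acute myocardial
infarction (AMI) and surgery within 48 hours of a hip fracture. Because the
regional registries such analyses run on are not publicly available, the
package includes a first-class synthetic registry generator with known
ground truth (published case-mix margins and model odds ratios as
defaults), so every stage — episode deduplication, two-year comorbidity
lookback, 90-day drug windows, model selection, standardisation — is
testable end to end. See `docs/methods.md` for the full model description.

## Worked example

`examples/` contains one narrative script per capability. From
`examples/02_model_pair.py` (5000 synthetic AMI patients, 50 bootstrap
replicates):

```
retained in the full model: ['ace_inhibitors', 'angiotensin_ii_antagonists',
'blood_disorders', 'calcium_channel_blockers', 'cancer', 'diabetes',
'diuretics', 'heart_failure', 'lipid_disorders', 'other_ischemic',
'other_ischemic_index', 'previous_ami', 'previous_cabg', 'previous_pci', 'sbp']

c-statistic: 0.758 (discharge only) -> 0.801 (+clinical+drugs), delta +0.043
```

The selection keeps the predictors that are stably significant across
bootstrap replicates; adding blood pressure and drug exposures lifts the
discrimination of the mortality model by about 0.04 — low blood pressure at
admission (true odds ratio 4.6 in the generator) carries severity
information that comorbidity history cannot. From
`examples/03_hospital_profiling.py` (25 hospitals, between-hospital sd 0.3):

```
discharge: K = 1.3312, conservation error 0.0e+00 (adjusted expected events == observed events)
     full: K = 1.5030, conservation error 1.4e-16 (adjusted expected events == observed events)

per-hospital profile (full model):
hospital_id   n  value classification direction
       H009 321  0.164    outside_998      high

rank agreement between adjustment models: Spearman rho = 0.947, outlier-flag concordance = 0.84
random-intercept sensitivity: between-hospital sd = 0.219 (generator truth 0.3)
```

Each hospital's `value` is its outcome proportion had it treated the
cohort-average case mix; H009 is flagged beyond the 99.8% limits (a genuine
high outlier under the generator's hospital effects), and the two
adjustment models rank hospitals almost identically — the central
observation the profiling comparison is designed to make.

A thin CLI wraps the same pipeline for shell use:

```bash
riskprofiler all --cohort ami --seed 7 --outdir run_ami
```

writing the cohort, attrition, model, per-hospital profile and comparison
CSVs plus funnel plots, with a manifest (seed, config hash, versions) that
makes the run reproducible.

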