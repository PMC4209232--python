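"""Configuration objects for the generator, cohort rules, model selection,
profiling and the end-to-end pipeline.

The default generator configurations encode the published case-mix of two
Italian regional study cohorts: marginal prevalences of chronic
conditions, clinical categories and 3-month drug exposures, together with the
adjusted odds ratios of the full risk-adjustment model, which serve as the
simulation ground truth. Quantities are dimensionless probabilities and odds
ratios except where noted (age in years, blood pressure in mmHg, creatinine
in mg/dl).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import yaml

from . import codes

Cohort = Literal["ami", "hip"]


def _check_prob(name: str, v: float) -> None:
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be a probability in [0,1], got {v}")


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for the synthetic registry generator.

    ``covariate_prevalences`` holds the marginal probability of each binary
    covariate; clinical-category keys (``sbp_le100``, ``inr_out_of_range``)
    are conditional on the value being observed, with the missingness rate in
    ``missing_prob`` — the marginal category probability is then
    ``(1 - missing) * conditional``. ``covariate_or`` gives the per-covariate
    odds ratio of the outcome-generating logistic model; ``age_or`` is the
    odds ratio per year of age (age enters centred at ``age_mean``).
    """

    cohort: Cohort = "ami"
    n_patients: int = 7613
    n_hospitals: int = 62
    hospital_effect_sd: float = 0.2
    covariate_prevalences: dict[str, float] = field(default_factory=dict)
    covariate_or: dict[str, float] = field(default_factory=dict)
    age_mean: float = 70.1
    age_sd: float = 13.5
    age_range: tuple[float, float] = (18.0, 100.0)
    age_or: float = 1.08
    gender_female_prob: float = 0.353
    gender_female_or: float = 0.96
    target_event_rate: float = 0.108
    missing_prob: dict[str, float] = field(default_factory=dict)
    #: probability that a comorbid patient's qualifying prior admission falls
    #: inside (vs outside) the two-year lookback window. 1.0 means configured
    #: prevalences are exactly the prevalences of the effective flags.
    lookback_fraction: float = 1.0
    #: fraction of patients given a second index-condition admission shortly
    #: after the first, to exercise episode deduplication downstream.
    readmit_fraction: float = 0.03
    #: rate of out-of-window / irrelevant dispensings added as decoys.
    decoy_dispensing_rate: float = 0.15
    #: optional pairwise latent-Gaussian correlations between binary
    #: covariates: (name_a, name_b, rho). Off (empty) by default.
    covariate_corr: list[tuple[str, str, float]] = field(default_factory=list)
    #: optional per-hospital prevalence overrides: covariate -> one prevalence
    #: per hospital (length n_hospitals), for studying hospital-heterogeneous
    #: confounders.
    hospital_prevalences: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_hospitals < 2:
            raise ValueError("n_hospitals must be >= 2")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.hospital_effect_sd < 0:
            raise ValueError("hospital_effect_sd must be >= 0")
        _check_prob("target_event_rate", self.target_event_rate)
        _check_prob("lookback_fraction", self.lookback_fraction)
        _check_prob("gender_female_prob", self.gender_female_prob)
        for k, v in self.covariate_prevalences.items():
            _check_prob(f"prevalence[{k}]", v)
        for k, v in self.missing_prob.items():
            _check_prob(f"missing_prob[{k}]", v)
        for k, v in self.covariate_or.items():
            if not v > 0:
                raise ValueError(f"odds ratio for {k} must be > 0, got {v}")
        if not self.age_or > 0 or not self.gender_female_or > 0:
            raise ValueError("age/gender odds ratios must be > 0")
        for k, pv in self.hospital_prevalences.items():
            if len(pv) != self.n_hospitals:
                raise ValueError(
                    f"hospital_prevalences[{k}] must have one entry per hospital")
            for v in pv:
                _check_prob(f"hospital_prevalences[{k}]", v)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


# -- published AMI case mix ------------------------------------------------
# Marginal prevalences of the reported chronic conditions and drug exposures
# in the AMI cohort (n = 7613), and the adjusted odds ratios of the full
# (discharge + clinical + drug) 30-day mortality model. Conditions without a
# row in the final model carry OR 1.0.

AMI_PREVALENCES: dict[str, float] = {
    "cancer": 0.0574,
    "diabetes": 0.1089,
    "nutritional_deficiencies": 0.0028,
    "lipid_disorders": 0.0452,
    "obesity": 0.0097,
    "blood_disorders": 0.0444,
    "blood_disorders_index": 0.0516,       # 393 / 7613
    "rheumatic_heart": 0.0088,
    "hypertension": 0.1815,
    "previous_ami": 0.1493,
    "other_ischemic": 0.1311,
    "other_ischemic_index": 0.0230,        # 175 / 7613
    "endocarditis_myocarditis": 0.0003,
    "cardiomyopathy": 0.0125,
    "conduction_arrhythmias": 0.0778,
    "heart_failure": 0.0728,
    "ill_defined_heart": 0.0181,
    "other_heart": 0.0135,
    "cerebrovascular": 0.0673,
    "vascular_disease": 0.0399,
    "copd": 0.0556,
    "chronic_liver_pancreas_intestine": 0.0112,
    "chronic_renal": 0.0550,
    "previous_cabg": 0.0407,
    "previous_pci": 0.1122,
    "cerebral_revascularisation": 0.0055,
    "other_cardiac_operations": 0.0062,
    "other_vascular_operations": 0.0239,
    # clinical category, conditional on SBP being observed (marginal 10.05%
    # with 3.36% missing)
    "sbp_le100": 0.1005 / (1.0 - 0.0336),
    # 3-month drug exposures
    "anticoagulants": 0.0648,
    "antiplatelet": 0.3214,
    "cardiac_therapy": 0.2215,
    "antihypertensives": 0.0472,
    "diuretics": 0.2071,
    "beta_blockers": 0.2041,
    "calcium_channel_blockers": 0.2062,
    "ace_inhibitors": 0.2597,
    "angiotensin_ii_antagonists": 0.2395,
    "statins": 0.2476,
    "other_lipid_agents": 0.0732,
    "antidiabetics": 0.2120,
}

AMI_ODDS_RATIOS: dict[str, float] = {
    "cancer": 1.42,
    "diabetes": 1.34,
    "lipid_disorders": 0.46,
    "blood_disorders_index": 0.69,
    "blood_disorders": 1.28,
    "previous_ami": 0.71,
    "heart_failure": 1.51,
    "other_ischemic_index": 0.47,
    "other_ischemic": 1.26,
    "chronic_renal": 1.48,
    "chronic_liver_pancreas_intestine": 1.92,
    "previous_cabg": 0.52,
    "previous_pci": 0.62,
    "sbp_le100": 4.60,
    "sbp_missing": 1.33,
    "diuretics": 1.69,
    "ace_inhibitors": 0.77,
    "angiotensin_ii_antagonists": 0.82,
}

# -- published hip-fracture case mix ---------------------------------------
# Same structure for the hip-fracture cohort (n = 6348); outcome is surgery
# within 48 hours, crude rate 19.8%.

HIP_PREVALENCES: dict[str, float] = {
    "diabetes": 0.064,
    "obesity": 0.0036,
    "obesity_index": 0.0065,               # 41 / 6348
    "blood_disorders": 0.0507,
    "dementia": 0.0302,
    "parkinsons": 0.0088,
    "hemiplegia": 0.0035,
    "rheumatic_heart": 0.0047,
    "hypertension": 0.1382,
    "previous_ami": 0.0257,
    "other_ischemic": 0.0882,
    "cardiomyopathy": 0.0079,
    "conduction_arrhythmias": 0.0755,
    "heart_failure": 0.0561,
    "ill_defined_heart": 0.0184,
    "other_heart": 0.0129,
    "cerebrovascular": 0.0884,
    "vascular_disease": 0.0243,
    "copd": 0.0577,
    "chronic_liver_pancreas_intestine": 0.0112,
    "chronic_renal": 0.0365,
    "rheumatoid_arthritis": 0.0039,
    "osteoporosis": 0.0090,
    # INR out-of-range, conditional on observed (marginal 13.47%, 10.38% missing)
    "inr_out_of_range": 0.1347 / (1.0 - 0.1038),
    "antiplatelet": 0.1341,
    "anticoagulants": 0.0375,
}

HIP_ODDS_RATIOS: dict[str, float] = {
    "diabetes": 0.68,
    "obesity_index": 2.33,
    "obesity": 1.04,
    "osteoporosis": 1.97,
    "inr_out_of_range": 0.56,
    "inr_missing": 0.78,
    "antiplatelet": 0.79,
}


def ami_generator_config(**overrides) -> GeneratorConfig:
    """Generator config matching the published AMI cohort margins."""
    base = dict(
        cohort="ami",
        n_patients=7613,
        n_hospitals=62,
        covariate_prevalences=dict(AMI_PREVALENCES),
        covariate_or=dict(AMI_ODDS_RATIOS),
        age_mean=70.1,
        age_sd=13.5,
        age_range=(18.0, 100.0),
        age_or=1.08,
        gender_female_prob=0.353,
        gender_female_or=0.96,
        target_event_rate=0.108,
        missing_prob={"sbp": 0.0336},
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def hip_generator_config(**overrides) -> GeneratorConfig:
    """Generator config matching the published hip-fracture cohort margins."""
    base = dict(
        cohort="hip",
        n_patients=6348,
        n_hospitals=83,
        covariate_prevalences=dict(HIP_PREVALENCES),
        covariate_or=dict(HIP_ODDS_RATIOS),
        age_mean=83.0,
        age_sd=7.1,
        age_range=(65.0, 100.0),
        age_or=1.00,
        gender_female_prob=0.7758,
        gender_female_or=1.37,
        target_event_rate=0.198,
        missing_prob={"inr": 0.1038, "creatinine": 0.0},
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class CohortSpec:
    """Rules that turn raw registry rows into an analysis-ready cohort."""

    cohort: Cohort = "ami"
    index_dx_prefixes: tuple[str, ...] = (codes.AMI_INDEX_PREFIX,)
    complication_dx_codes: tuple[str, ...] = codes.AMI_COMPLICATION_CODES
    age_range: tuple[float, float] = (18.0, 100.0)
    episode_window_days: int = 28
    lookback_days: int = 730
    drug_window_days: int = 90
    comorbidity_map: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(codes.DEFAULT_COMORBIDITY_MAP))
    index_flag_map: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(codes.DEFAULT_INDEX_FLAG_MAP))
    drug_class_map: Mapping[str, tuple[Sequence[str], Sequence[str]]] = field(
        default_factory=lambda: dict(codes.DEFAULT_DRUG_CLASS_MAP))
    surgery_prefixes: tuple[str, ...] = codes.HIP_SURGERY_PREFIXES
    cancer_prefixes: tuple[str, ...] = codes.CANCER_PREFIXES
    trauma_drgs: tuple[str, ...] = codes.MULTIPLE_TRAUMA_DRGS
    mortality_window_days: int = 30
    surgery_window_days: int = 1   # calendar-day difference 0 or 1 = "48 h"
    #: index admissions must fall inside this window (None disables); prior
    #: admissions outside it still count for lookback ascertainment.
    study_period: tuple[str, str] | None = ("2010-01-01", "2010-11-30")

    def __post_init__(self) -> None:
        if self.episode_window_days <= 0 or self.lookback_days <= 0 \
                or self.drug_window_days <= 0:
            raise ValueError("window lengths must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")


def ami_cohort_spec(**overrides) -> CohortSpec:
    base = dict(cohort="ami", age_range=(18.0, 100.0))
    base.update(overrides)
    return CohortSpec(**base)


def hip_cohort_spec(**overrides) -> CohortSpec:
    base = dict(
        cohort="hip",
        index_dx_prefixes=(codes.HIP_FRACTURE_PREFIX,),
        age_range=(65.0, 100.0),
    )
    base.update(overrides)
    return CohortSpec(**base)


@dataclass
class SelectionConfig:
    """Bootstrap stepwise selection settings."""

    n_bootstrap: int = 1000
    alpha: float = 0.05
    alpha_entry: float = 0.05
    alpha_stay: float = 0.05
    retain_fraction: float = 0.30
    #: optional absolute-count retention rule (candidate kept if selected with
    #: p <= alpha in at least this many usable replicates); None disables it.
    min_count: int | None = None
    forced: tuple[str, ...] = ("age", "gender_female")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if not (0 < self.retain_fraction <= 1) and self.retain_fraction != 0:
            raise ValueError("retain_fraction must be in [0,1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class ProfilingConfig:
    """Direct-standardisation and funnel-plot settings."""

    min_volume: int = 10
    funnel_levels: tuple[float, ...] = (0.95, 0.998)
    limit_method: Literal["normal", "binomial"] = "normal"
    ridge: float = 1e-4

    def __post_init__(self) -> None:
        for lv in self.funnel_levels:
            if not (0 < lv < 1):
                raise ValueError("funnel levels must lie in (0,1)")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: exactly one data source (a
    generator config or a directory of registry CSVs)."""

    cohort: Cohort = "ami"
    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    cohort_spec: CohortSpec | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    outdir: str = "riskprofiler_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of generator config and input_dir must be given")
        if self.cohort_spec is None:
            self.cohort_spec = (ami_cohort_spec() if self.cohort == "ami"
                                else hip_cohort_spec())


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return run_config_from_dict(raw)


def run_config_from_dict(raw: dict) -> RunConfig:
    cohort = raw.get("cohort", "ami")
    gen = None
    if "generator" in raw and raw["generator"] is not None:
        gdict = dict(raw["generator"])
        factory = ami_generator_config if cohort == "ami" else hip_generator_config
        if "covariate_corr" in gdict:
            gdict["covariate_corr"] = [tuple(t) for t in gdict["covariate_corr"]]
        gen = factory(**gdict)
    sel = SelectionConfig(**raw.get("selection", {}))
    prof_raw = dict(raw.get("profiling", {}))
    if "funnel_levels" in prof_raw:
        prof_raw["funnel_levels"] = tuple(prof_raw["funnel_levels"])
    prof = ProfilingConfig(**prof_raw)
    return RunConfig(
        cohort=cohort,
        generator=gen,
        input_dir=raw.get("input_dir"),
        selection=sel,
        profiling=prof,
        outdir=raw.get("outdir", "riskprofiler_run"),
        seed=int(raw.get("seed", 0)),
    )
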