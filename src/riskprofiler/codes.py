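"""Diagnosis, procedure and drug code maps.

ICD-9-CM codes are matched by string prefix on dot-stripped codes
("250.01" -> "25001" matches prefix "250"); DRG codes are matched exactly.
ATC classes are matched by hierarchical prefix, optionally minus an excluded
sub-prefix (e.g. "other lipid-modifying agents" = C10 excluding C10AA).

The comorbidity map shipped here is a small documented default — one
representative prefix list per condition — and is fully overridable: regional
programmes maintain their own (unpublished) lists, so any production run
should supply its own map through :class:`~riskprofiler.config.CohortSpec`.
The ATC class map, by contrast, is the standard one (the class definitions
are printed ATC prefixes).
"""

from __future__ import annotations

import re
from typing import Iterable

# Principal-diagnosis codes that admit a secondary AMI diagnosis as an index
# event (complications of myocardial infarction). Dot-stripped.
AMI_COMPLICATION_CODES: tuple[str, ...] = (
    "4230", "4270", "4271", "4272", "4273", "4274", "4276", "4278", "4279",
    "4295", "4296", "5184", "7802", "7991", "9982",
)

AMI_INDEX_PREFIX = "410"
HIP_FRACTURE_PREFIX = "820"

#: Cancer exclusion range for the hip-fracture cohort: ICD-9 140-208.
CANCER_PREFIXES: tuple[str, ...] = tuple(str(c) for c in range(140, 209))

#: Multiple-trauma DRG exclusion codes (exact match).
MULTIPLE_TRAUMA_DRGS: tuple[str, ...] = ("484", "485", "486", "487")

#: Hip-fracture surgery procedure prefixes (reduction/fixation/arthroplasty).
HIP_SURGERY_PREFIXES: tuple[str, ...] = ("7915", "7925", "7935", "8151", "8152")

# Default toy comorbidity map: condition -> ICD-9-CM dot-stripped prefixes.
# One canonical prefix family per condition reported in the descriptive table.
DEFAULT_COMORBIDITY_MAP: dict[str, tuple[str, ...]] = {
    "cancer": CANCER_PREFIXES,
    "diabetes": ("250",),
    "nutritional_deficiencies": ("260", "261", "262", "263"),
    "lipid_disorders": ("272",),
    "obesity": ("2780",),
    "blood_disorders": ("280", "281", "282", "283", "284", "285", "286",
                        "287", "288", "289"),
    "dementia": ("290", "3310"),
    "parkinsons": ("332",),
    "hemiplegia": ("342", "344"),
    "rheumatic_heart": ("393", "394", "395", "396", "397", "398"),
    "hypertension": ("401", "402", "403", "404", "405"),
    "previous_ami": ("412",),
    "other_ischemic": ("411", "413", "414"),
    "endocarditis_myocarditis": ("421", "422"),
    "cardiomyopathy": ("425",),
    "conduction_arrhythmias": ("426", "427"),
    "heart_failure": ("428",),
    "ill_defined_heart": ("429",),
    "other_heart": ("420", "423", "424"),
    "cerebrovascular": ("430", "431", "432", "433", "434", "435", "436",
                        "437", "438"),
    "vascular_disease": ("440", "441", "442", "443", "444", "447"),
    "copd": ("490", "491", "492", "494", "496"),
    "chronic_liver_pancreas_intestine": ("555", "556", "571", "577"),
    "chronic_renal": ("585", "586"),
    "rheumatoid_arthritis": ("714",),
    "osteoporosis": ("7330",),
    "previous_cabg": ("V4581",),
    "previous_pci": ("V4582",),
    "cerebral_revascularisation": ("V4588",),
    "other_cardiac_operations": ("V422", "V433"),
    "other_vascular_operations": ("V434",),
}

# Conditions whose flag may also be set from the *index* admission's secondary
# diagnoses (reported as "(index admission)" rows in the model tables). They
# are distinct covariates from their two-year-lookback counterparts.
DEFAULT_INDEX_FLAG_MAP: dict[str, tuple[str, ...]] = {
    "blood_disorders_index": DEFAULT_COMORBIDITY_MAP["blood_disorders"],
    "other_ischemic_index": DEFAULT_COMORBIDITY_MAP["other_ischemic"],
    "obesity_index": DEFAULT_COMORBIDITY_MAP["obesity"],
}

#: ATC drug classes: name -> (include prefixes, exclude prefixes).
DEFAULT_DRUG_CLASS_MAP: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "anticoagulants": (("B01AA", "B01AB"), ()),
    "antiplatelet": (("B01AC",), ()),
    "cardiac_therapy": (("C01",), ()),
    "antihypertensives": (("C02",), ()),
    "diuretics": (("C03",), ()),
    "beta_blockers": (("C07",), ()),
    "calcium_channel_blockers": (("C08",), ()),
    "ace_inhibitors": (("C09A", "C09B"), ()),
    "angiotensin_ii_antagonists": (("C09C", "C09D"), ()),
    "statins": (("C10AA",), ()),
    "other_lipid_agents": (("C10",), ("C10AA",)),
    "antidiabetics": (("A10",), ()),
}


def strip_dots(code: str) -> str:
    """Normalise an ICD-9-CM code: remove dots, strip spaces, upper-case."""
    return str(code).replace(".", "").strip().upper()


def dx_matches(code: str, prefixes: Iterable[str]) -> bool:
    """True if the dot-stripped code starts with any of the prefixes."""
    c = strip_dots(code)
    return any(c.startswith(p) for p in prefixes)


def atc_matches(code: str, include: Iterable[str], exclude: Iterable[str] = ()) -> bool:
    """True if an ATC code belongs to a class (include minus exclude prefixes)."""
    c = str(code).strip().upper()
    if any(c.startswith(p) for p in exclude):
        return False
    return any(c.startswith(p) for p in include)


_ATC_OK = re.compile(r"^[A-Z]\d\d([A-Z]([A-Z](\d\d)?)?)?$")


def is_valid_atc(code: str) -> bool:
    """Check the hierarchical ATC pattern (letter, 2 digits, optional levels)."""
    return bool(_ATC_OK.match(str(code).strip().upper()))
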