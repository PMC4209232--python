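"""Cohort construction from registry-shaped tables.

Turns raw discharge abstracts, dispensings, clinical values and death records
into one analysis-ready row per index episode: outcome flag, demographics,
two-year-lookback comorbidity flags, index-admission condition flags,
3-month drug-exposure flags and categorised clinical variables.

Window conventions (configurable via :class:`~riskprofiler.config.CohortSpec`):

* episode, lookback and drug windows are half-open ``[index - w, index)`` —
  an event on the index date itself is not prior exposure;
* episode deduplication anchors at the first admission of an episode, so an
  admission chain at days 0, 20, 40 yields index episodes at days 0 and 40;
* 30-day mortality includes day 30; "surgery within 48 hours" means a
  calendar-day difference of 0 or 1.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import codes
from .config import CohortSpec

logger = logging.getLogger(__name__)

SBP_CATEGORIES = ("gt100", "le100", "missing")
INR_CATEGORIES = ("in_range", "out_of_range", "missing")


# --------------------------------------------------------------------------
# small categorisation helpers


def categorize_sbp(sbp: float | None) -> str:
    """Categorise systolic blood pressure (mmHg): ``le100`` iff value <= 100."""
    if sbp is None or (isinstance(sbp, float) and np.isnan(sbp)):
        return "missing"
    if sbp <= 0:
        raise ValueError(f"systolic blood pressure must be positive, got {sbp}")
    return "le100" if sbp <= 100 else "gt100"


def categorize_inr(inr: float | None) -> str:
    """Categorise INR: ``in_range`` iff 0.9 <= value <= 1.2 (bounds inclusive)."""
    if inr is None or (isinstance(inr, float) and np.isnan(inr)):
        return "missing"
    if inr <= 0:
        raise ValueError(f"INR must be positive, got {inr}")
    return "in_range" if 0.9 <= inr <= 1.2 else "out_of_range"


# --------------------------------------------------------------------------
# code handling


def _dx_lists(df: pd.DataFrame) -> pd.Series:
    """All diagnoses (principal first) per row, dot-stripped."""
    sec = df["secondary_dx"].fillna("").astype(str)
    out = []
    for p, s in zip(df["principal_dx"].astype(str), sec):
        lst = [codes.strip_dots(p)]
        if s:
            lst.extend(codes.strip_dots(c) for c in s.split("|") if c)
        out.append(lst)
    return pd.Series(out, index=df.index)


def _prefix_regex(prefixes: Iterable[str]) -> re.Pattern:
    return re.compile("^(?:" + "|".join(re.escape(p) for p in prefixes) + ")")


def _parse_procedures(cell: str) -> list[tuple[str, np.datetime64]]:
    """Parse the ``code@date|code@date`` procedure encoding."""
    if not isinstance(cell, str) or not cell:
        return []
    out = []
    for item in cell.split("|"):
        if "@" not in item:
            continue
        code, date = item.split("@", 1)
        out.append((codes.strip_dots(code), np.datetime64(date, "D")))
    return out


# --------------------------------------------------------------------------
# episode handling


def _period_filter(adm: pd.DataFrame, spec: CohortSpec) -> tuple[pd.DataFrame, int]:
    """Keep only admissions whose admission date lies in the study period."""
    if spec.study_period is None:
        return adm, 0
    start, end = (pd.Timestamp(d) for d in spec.study_period)
    keep = adm["admission_date"].between(start, end)
    return adm[keep], int((~keep).sum())


def dedupe_episodes(admissions: pd.DataFrame, window_days: int) -> pd.DataFrame:
    """Collapse re-admissions into episodes anchored at the first admission.

    Per patient, an admission is dropped iff it begins within ``window_days``
    of the retained episode's *first* admission; a later admission then opens
    a new episode. Exact duplicate (patient, date, hospital) rows trigger a
    warning and one copy is kept.
    """
    adm = admissions.sort_values(
        ["patient_id", "admission_date", "hospital_id", "admission_id"])
    dup = adm.duplicated(["patient_id", "admission_date", "hospital_id"])
    if dup.any():
        logger.warning("dropping %d duplicate (patient, date, hospital) rows",
                       int(dup.sum()))
        adm = adm[~dup]

    multi = adm["patient_id"].duplicated(keep=False)
    singles = adm[~multi]
    kept_idx: list = list(singles.index)
    for _, grp in adm[multi].groupby("patient_id", sort=False):
        dates = grp["admission_date"].to_numpy()
        anchor = None
        for i, d in zip(grp.index, dates):
            if anchor is None or (d - anchor) / np.timedelta64(1, "D") > window_days:
                kept_idx.append(i)
                anchor = d
    return adm.loc[sorted(kept_idx)].sort_values(
        ["patient_id", "admission_date"]).reset_index(drop=True)


def select_ami_index(records: pd.DataFrame,
                     spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select AMI index admissions and report per-rule attrition.

    An admission qualifies if the principal diagnosis is an AMI code, or if a
    secondary diagnosis is an AMI code and the principal diagnosis belongs to
    the printed list of myocardial-infarction complications. Age/residence
    filters and episode deduplication are then applied in order.
    """
    rec = records.copy()
    dxs = _dx_lists(rec)
    principal = rec["principal_dx"].astype(str).map(codes.strip_dots)
    is_ami_principal = principal.str.startswith(tuple(spec.index_dx_prefixes))
    has_ami_secondary = dxs.map(
        lambda lst: any(c.startswith(tuple(spec.index_dx_prefixes)) for c in lst[1:]))
    compl_re = _prefix_regex(spec.complication_dx_codes)
    is_compl = principal.str.match(compl_re)
    candidate = is_ami_principal | (has_ami_secondary & is_compl)

    steps: list[tuple[str, int]] = []
    cur = rec[candidate]
    steps.append(("not an index AMI admission", len(rec) - len(cur)))

    cur, n_out = _period_filter(cur, spec)
    steps.append(("outside study period", n_out))

    lo, hi = spec.age_range
    keep = (cur["age"] >= lo) & (cur["age"] <= hi)
    steps.append(("age outside range", int((~keep).sum())))
    cur = cur[keep]

    keep = cur["resident"].astype(bool)
    steps.append(("non-resident", int((~keep).sum())))
    cur = cur[keep]

    before = len(cur)
    cur = dedupe_episodes(cur, spec.episode_window_days)
    steps.append(("re-admission within episode window", before - len(cur)))

    attrition = pd.DataFrame(steps, columns=["rule", "n_excluded"])
    return cur.reset_index(drop=True), attrition


def select_hf_index(records: pd.DataFrame, deaths: pd.DataFrame,
                    spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select hip-fracture index admissions, applying the seven exclusion
    rules in their stated order, and report per-rule attrition."""
    rec = records.copy()
    dxs = _dx_lists(rec)
    hip_re = _prefix_regex(spec.index_dx_prefixes)
    is_hip = dxs.map(lambda lst: any(hip_re.match(c) for c in lst))
    cur = rec[is_hip].copy()
    steps: list[tuple[str, int]] = [
        ("no hip-fracture diagnosis", len(rec) - len(cur))]
    cur, n_out = _period_filter(cur, spec)
    steps.append(("outside study period", n_out))

    # history lookups reuse the full record table
    hist = rec[["patient_id", "admission_date"]].copy()
    hist["dx"] = dxs
    cancer_re = _prefix_regex(spec.cancer_prefixes)

    def _prior_with(cur_df: pd.DataFrame, pattern: re.Pattern,
                    days: int) -> pd.Series:
        """Episodes with a matching diagnosis in [index - days, index)."""
        flags = np.zeros(len(cur_df), dtype=bool)
        by_pat = {p: g for p, g in hist.groupby("patient_id", sort=False)}
        for k, (idx, row) in enumerate(cur_df.iterrows()):
            g = by_pat.get(row["patient_id"])
            if g is None:
                continue
            delta = (row["admission_date"] - g["admission_date"]).dt.days
            in_win = (delta > 0) & (delta <= days)
            if any(pattern.match(c)
                   for lst in g.loc[in_win, "dx"] for c in lst):
                flags[k] = True
        return pd.Series(flags, index=cur_df.index)

    # 1. hip fracture in the previous two years
    drop = _prior_with(cur, hip_re, spec.lookback_days)
    steps.append(("hip fracture in previous two years", int(drop.sum())))
    cur = cur[~drop]

    # 2. age outside 65-100
    lo, hi = spec.age_range
    drop = (cur["age"] < lo) | (cur["age"] > hi)
    steps.append(("age outside range", int(drop.sum())))
    cur = cur[~drop]

    # 3. non-resident
    drop = ~cur["resident"].astype(bool)
    steps.append(("non-resident", int(drop.sum())))
    cur = cur[~drop]

    # 4. cancer on index admission or in previous two years
    on_index = dxs.loc[cur.index].map(
        lambda lst: any(cancer_re.match(c) for c in lst))
    drop = on_index | _prior_with(cur, cancer_re, spec.lookback_days)
    steps.append(("cancer diagnosis", int(drop.sum())))
    cur = cur[~drop]

    # 5. multiple trauma (DRG)
    drop = cur["drg"].astype(str).isin(spec.trauma_drgs)
    steps.append(("multiple trauma DRG", int(drop.sum())))
    cur = cur[~drop]

    # 6. direct ICU admission
    drop = cur["icu_direct"].astype(bool)
    steps.append(("direct ICU admission", int(drop.sum())))
    cur = cur[~drop]

    # 7. no surgery and death within the first 48 hours
    surgery = cur["procedures"].map(
        lambda c: any(code.startswith(tuple(spec.surgery_prefixes))
                      for code, _ in _parse_procedures(c)))
    dmap = deaths.set_index("patient_id")["death_date"] if len(deaths) else pd.Series(dtype="datetime64[ns]")
    ddate = cur["patient_id"].map(dmap)
    early_death = (ddate - cur["admission_date"]).dt.days <= spec.surgery_window_days
    drop = ~surgery & early_death.fillna(False)
    steps.append(("death within 48 h without surgery", int(drop.sum())))
    cur = cur[~drop]

    attrition = pd.DataFrame(steps, columns=["rule", "n_excluded"])
    return cur.reset_index(drop=True), attrition


# --------------------------------------------------------------------------
# covariate ascertainment


def lookback_comorbidities(index_adm: pd.DataFrame, history: pd.DataFrame,
                           comorbidity_map: dict[str, Sequence[str]],
                           lookback_days: int,
                           index_flag_map: dict[str, Sequence[str]] | None = None,
                           ) -> pd.DataFrame:
    """Comorbidity flags from prior admissions in ``[index - lookback, index)``.

    A condition flag is 1 iff any prior admission of the patient inside the
    half-open lookback window carries a mapped code as principal or secondary
    diagnosis. Conditions in ``index_flag_map`` are instead ascertained from
    the *index* admission's secondary diagnoses (pre-existing conditions
    recorded at admission). Returns one row per index admission.
    """
    for name, prefixes in (comorbidity_map | (index_flag_map or {})).items():
        if not prefixes:
            raise ValueError(f"comorbidity map entry {name!r} has no code prefixes")

    out = pd.DataFrame(index=index_adm.index)
    hist = history[["patient_id", "admission_date"]].copy()
    hist["dx"] = _dx_lists(history)
    long = hist.explode("dx").rename(columns={"dx": "code"}).dropna(subset=["code"])

    merged = long.merge(
        index_adm[["admission_id", "patient_id", "admission_date"]]
        .rename(columns={"admission_date": "index_date",
                         "admission_id": "episode_id"}),
        on="patient_id", how="inner")
    delta = (merged["index_date"] - merged["admission_date"]).dt.days
    merged = merged[(delta > 0) & (delta <= lookback_days)]

    eid = index_adm["admission_id"]
    for name, prefixes in comorbidity_map.items():
        rex = _prefix_regex(prefixes)
        hit = merged.loc[merged["code"].str.match(rex), "episode_id"].unique()
        out[name] = eid.isin(hit).astype(np.int8).to_numpy()

    if index_flag_map:
        sec_lists = index_adm["secondary_dx"].fillna("").astype(str).map(
            lambda s: [codes.strip_dots(c) for c in s.split("|") if c])
        for name, prefixes in index_flag_map.items():
            rex = _prefix_regex(prefixes)
            out[name] = sec_lists.map(
                lambda lst: int(any(rex.match(c) for c in lst))).astype(np.int8).to_numpy()
    return out


def drug_exposure_flags(index_adm: pd.DataFrame, dispensings: pd.DataFrame,
                        class_map: dict[str, tuple[Sequence[str], Sequence[str]]],
                        window_days: int) -> pd.DataFrame:
    """Drug-class exposure flags: at least one dispensing with a mapped ATC
    code in the half-open ``[index - window, index)`` interval.

    Malformed ATC strings are skipped with a warning.
    """
    disp = dispensings.copy()
    disp["atc"] = disp["atc"].astype(str).str.strip().str.upper()
    bad = ~disp["atc"].map(codes.is_valid_atc)
    if bad.any():
        logger.warning("skipping %d dispensings with malformed ATC codes",
                       int(bad.sum()))
        disp = disp[~bad]

    merged = disp.merge(
        index_adm[["admission_id", "patient_id", "admission_date"]]
        .rename(columns={"admission_date": "index_date",
                         "admission_id": "episode_id"}),
        on="patient_id", how="inner")
    delta = (merged["index_date"] - merged["dispensing_date"]).dt.days
    merged = merged[(delta > 0) & (delta <= window_days)]

    out = pd.DataFrame(index=index_adm.index)
    eid = index_adm["admission_id"]
    for name, (include, exclude) in class_map.items():
        sel = merged["atc"].str.startswith(tuple(include))
        if exclude:
            sel &= ~merged["atc"].str.startswith(tuple(exclude))
        hit = merged.loc[sel, "episode_id"].unique()
        out[name] = eid.isin(hit).astype(np.int8).to_numpy()
    return out


# --------------------------------------------------------------------------
# outcomes


def outcome_30d_mortality(index_adm: pd.DataFrame, deaths: pd.DataFrame,
                          window_days: int = 30) -> pd.Series:
    """Death within ``window_days`` of admission (day ``window_days``
    inclusive), from the death registry or an in-hospital death disposition."""
    dmap = (deaths.set_index("patient_id")["death_date"]
            if len(deaths) else pd.Series(dtype="datetime64[ns]"))
    ddate = index_adm["patient_id"].map(dmap)
    delta = (ddate - index_adm["admission_date"]).dt.days
    if (delta < 0).any():
        bad = index_adm.loc[delta < 0, "patient_id"].tolist()
        raise ValueError(f"death before admission for patients {bad[:5]}")
    from_registry = delta <= window_days
    disch_delta = (index_adm["discharge_date"] - index_adm["admission_date"]).dt.days
    from_disposition = (index_adm["disposition"].eq("died")
                        & (disch_delta <= window_days))
    return (from_registry.fillna(False) | from_disposition).astype(np.int8)


def outcome_surgery_48h(index_adm: pd.DataFrame,
                        surgery_prefixes: Sequence[str],
                        window_days: int = 1) -> pd.Series:
    """Earliest qualifying surgical procedure on calendar day 0 or 1."""
    out = np.zeros(len(index_adm), dtype=np.int8)
    prefixes = tuple(surgery_prefixes)
    for k, (_, row) in enumerate(index_adm.iterrows()):
        procs = [d for c, d in _parse_procedures(row["procedures"])
                 if c.startswith(prefixes)]
        if not procs:
            continue
        first = min(procs)
        delta = int((first - np.datetime64(row["admission_date"], "D"))
                    / np.timedelta64(1, "D"))
        if delta < 0:
            raise ValueError(
                f"procedure before admission for patient {row['patient_id']}")
        out[k] = int(delta <= window_days)
    return pd.Series(out, index=index_adm.index)


def complete_case_filter(rows: pd.DataFrame,
                         required: Sequence[str] = ("age", "gender", "hospital_id"),
                         ) -> tuple[pd.DataFrame, int]:
    """Drop rows with missing *administrative* fields.

    Clinical-variable missingness is never dropped here — it is an explicit
    category of the risk models.
    """
    if len(rows) == 0:
        return rows, 0
    present = [c for c in required if c in rows.columns]
    keep = rows[present].notna().all(axis=1)
    for c in present:
        if rows[c].dtype == object:
            keep &= rows[c].astype(str).str.len() > 0
    return rows[keep].reset_index(drop=True), int((~keep).sum())


# --------------------------------------------------------------------------
# end-to-end cohort assembly


def _assemble(index_adm: pd.DataFrame, registry, spec: CohortSpec,
              outcome: pd.Series, attrition: pd.DataFrame,
              clinical_kind: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    com = lookback_comorbidities(index_adm, registry.discharges,
                                 dict(spec.comorbidity_map), spec.lookback_days,
                                 dict(spec.index_flag_map))
    drugs = drug_exposure_flags(index_adm, registry.dispensings,
                                dict(spec.drug_class_map), spec.drug_window_days)
    cohort = pd.DataFrame({
        "episode_id": index_adm["admission_id"].to_numpy(),
        "patient_id": index_adm["patient_id"].to_numpy(),
        "hospital_id": index_adm["hospital_id"].to_numpy(),
        "outcome": outcome.to_numpy(),
        "age": index_adm["age"].to_numpy(),
        "gender": index_adm["gender"].to_numpy(),
    })
    cohort["gender_female"] = (cohort["gender"] == "F").astype(np.int8)
    cohort = pd.concat([cohort,
                        com.reset_index(drop=True),
                        drugs.reset_index(drop=True)], axis=1)

    clin = registry.clinical.set_index("admission_id") if len(registry.clinical) else pd.DataFrame()
    if clinical_kind == "sbp":
        vals = (clin["sbp"].reindex(cohort["episode_id"]).to_numpy()
                if "sbp" in clin.columns else np.full(len(cohort), np.nan))
        cats = [categorize_sbp(v) for v in vals]
        cohort["sbp_cat"] = cats
        cohort["sbp_le100"] = (cohort["sbp_cat"] == "le100").astype(np.int8)
        cohort["sbp_missing"] = (cohort["sbp_cat"] == "missing").astype(np.int8)
    else:
        vals = (clin["inr"].reindex(cohort["episode_id"]).to_numpy()
                if "inr" in clin.columns else np.full(len(cohort), np.nan))
        cats = [categorize_inr(v) for v in vals]
        cohort["inr_cat"] = cats
        cohort["inr_out_of_range"] = (cohort["inr_cat"] == "out_of_range").astype(np.int8)
        cohort["inr_missing"] = (cohort["inr_cat"] == "missing").astype(np.int8)

    cohort, n_removed = complete_case_filter(cohort)
    attrition = pd.concat([attrition, pd.DataFrame(
        [("incomplete administrative data", n_removed)],
        columns=["rule", "n_excluded"])], ignore_index=True)
    return cohort, attrition


def build_ami_cohort(registry, spec: CohortSpec | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AMI cohort: index selection, covariates and 30-day mortality outcome.

    ``registry`` is any object with ``discharges``, ``dispensings``,
    ``clinical`` and ``deaths`` DataFrames in the documented schemas (e.g.
    :class:`~riskprofiler.synthetic.SyntheticData`).
    """
    from .config import ami_cohort_spec
    spec = spec or ami_cohort_spec()
    index_adm, attrition = select_ami_index(registry.discharges, spec)
    outcome = outcome_30d_mortality(index_adm, registry.deaths,
                                    spec.mortality_window_days)
    return _assemble(index_adm, registry, spec, outcome, attrition, "sbp")


def build_hip_cohort(registry, spec: CohortSpec | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hip-fracture cohort: exclusion rules, covariates and the
    surgery-within-48-hours outcome."""
    from .config import hip_cohort_spec
    spec = spec or hip_cohort_spec()
    index_adm, attrition = select_hf_index(registry.discharges, registry.deaths,
                                           spec)
    outcome = outcome_surgery_48h(index_adm, spec.surgery_prefixes,
                                  spec.surgery_window_days)
    return _assemble(index_adm, registry, spec, outcome, attrition, "inr")
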