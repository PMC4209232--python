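"""Synthetic registry generator.

Emulates the four record streams a regional health-information system
provides — hospital discharge abstracts, outpatient drug dispensings,
admission-level clinical variables and a death registry — with fully known
ground truth, so that every downstream stage (cohort construction, risk
modelling, hospital profiling) can be tested without access to real data.

Outcomes are drawn from a logistic model

    logit P(Y=1) = intercept + log(OR_age)*(age - age_mean)
                   + log(OR_female)*female + sum_k log(OR_k) x_k + u_h

with ``u_h`` a mean-centred Gaussian hospital effect on the log-odds scale
and the intercept calibrated by root finding so the marginal event rate
matches the configured crude rate. Comorbidity evidence is emitted as real
prior discharge records (not pre-computed flags) and drug exposure as real
dispensing rows, so the cohort builder's window logic is exercised
end-to-end. Binary covariates are generated mutually independently by
default; an optional pairwise latent-Gaussian correlation hook and a
per-hospital prevalence override are available.

One master seed drives everything; independent substreams are derived per
record type so that, e.g., adding dispensings does not perturb the discharge
draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .config import GeneratorConfig

STUDY_START = np.datetime64("2010-01-01")
#: index admissions fall in Jan–Nov of the study year
INDEX_SPAN_DAYS = 334

#: one representative full ATC code per drug class (include-prefix compatible,
#: disjoint from every other class's prefixes).
CLASS_ATC_CODE = {
    "anticoagulants": "B01AA03",
    "antiplatelet": "B01AC06",
    "cardiac_therapy": "C01DA14",
    "antihypertensives": "C02AC01",
    "diuretics": "C03CA01",
    "beta_blockers": "C07AB07",
    "calcium_channel_blockers": "C08CA01",
    "ace_inhibitors": "C09AA05",
    "angiotensin_ii_antagonists": "C09CA06",
    "statins": "C10AA05",
    "other_lipid_agents": "C10AB05",
    "antidiabetics": "A10BA02",
}
_DECOY_ATC = "N02BE01"   # analgesic, matches no modelled class

#: representative ICD-9-CM code per condition (dot-stripped), derived from the
#: default comorbidity map's first prefix.
CONDITION_CODE = {
    "cancer": "1629", "diabetes": "25000", "nutritional_deficiencies": "2609",
    "lipid_disorders": "2724", "obesity": "27800", "blood_disorders": "2859",
    "dementia": "2900", "parkinsons": "3320", "hemiplegia": "3429",
    "rheumatic_heart": "3949", "hypertension": "4019", "previous_ami": "412",
    "other_ischemic": "4149", "endocarditis_myocarditis": "4219",
    "cardiomyopathy": "4254", "conduction_arrhythmias": "42731",
    "heart_failure": "4280", "ill_defined_heart": "4299",
    "other_heart": "4240", "cerebrovascular": "4340",
    "vascular_disease": "4439", "copd": "496",
    "chronic_liver_pancreas_intestine": "5712", "chronic_renal": "5859",
    "rheumatoid_arthritis": "7140", "osteoporosis": "73300",
    "previous_cabg": "V4581", "previous_pci": "V4582",
    "cerebral_revascularisation": "V4588", "other_cardiac_operations": "V422",
    "other_vascular_operations": "V434",
    # index-admission flags reuse the same code families
    "blood_disorders_index": "2859", "other_ischemic_index": "4149",
    "obesity_index": "27800",
}

DRUG_CLASSES = tuple(CLASS_ATC_CODE)

#: clinical-category covariate names handled outside the plain-binary path
CLINICAL_KEYS = ("sbp_le100", "inr_out_of_range")


@dataclass
class SyntheticData:
    """The four registry tables plus the ground-truth table."""

    discharges: pd.DataFrame
    dispensings: pd.DataFrame
    clinical: pd.DataFrame
    deaths: pd.DataFrame
    truth: pd.DataFrame

    def write_csvs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("discharges", "dispensings", "clinical", "deaths", "truth"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def read_registry(indir: str | Path) -> SyntheticData:
    """Read the four registry CSVs (+ truth table, if present) back in."""
    indir = Path(indir)
    date_cols = {
        "discharges": ["admission_date", "discharge_date"],
        "dispensings": ["dispensing_date"],
        "clinical": [],
        "deaths": ["death_date"],
        "truth": [],
    }
    frames = {}
    for name, cols in date_cols.items():
        p = indir / f"{name}.csv"
        if not p.exists():
            if name == "truth":
                frames[name] = pd.DataFrame()
                continue
            raise FileNotFoundError(p)
        frames[name] = pd.read_csv(p, parse_dates=cols)
    return SyntheticData(**frames)


def calibrate_intercept(target_rate: float, linear_predictor: np.ndarray,
                        tol: float = 1e-10) -> float:
    """Solve for the intercept that makes the mean simulated event
    probability equal ``target_rate``.

    ``mean(expit(c + lp))`` is strictly increasing in ``c``, so the root is
    found by bracketed root finding to well below the 1e-6 contract.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if lp.size == 0:
        raise ValueError("linear predictor sample must be non-empty")
    if not (0.0 < target_rate < 1.0):
        raise ValueError(
            f"target event rate must lie strictly in (0,1), got {target_rate}")

    def f(c: float) -> float:
        return float(np.mean(expit(c + lp))) - target_rate

    lo, hi = -40.0, 40.0
    return float(brentq(f, lo, hi, xtol=tol))


def sample_hospital_effects(n_hospitals: int, sd: float,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw mean-centred Gaussian log-odds shifts, one per hospital.

    ``sd = 0`` returns exact zeros; otherwise the draws are explicitly
    re-centred so the arithmetic mean is 0.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_hospitals < 1:
        raise ValueError("n_hospitals must be >= 1")
    if sd == 0:
        return np.zeros(n_hospitals)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    u = rng.normal(0.0, sd, n_hospitals)
    return u - u.mean()


def _correlated_bernoulli(rng: np.random.Generator, n: int, pa: np.ndarray,
                          pb: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two binary draws with latent-Gaussian correlation ``rho``."""
    from scipy.stats import norm
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    a = (z[:, 0] < norm.ppf(pa)).astype(np.int8)
    b = (z[:, 1] < norm.ppf(pb)).astype(np.int8)
    return a, b


def simulate_covariates(config: GeneratorConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw patient-level covariates, hospital membership and outcome.

    Returns the ground-truth table: one row per patient with every effective
    covariate, the clinical category, the hospital effect, the full linear
    predictor (intercept included), the event probability and the outcome.
    """
    cfg = config
    n = cfg.n_patients
    m = cfg.n_hospitals

    hosp_idx = rng.integers(0, m, n)
    u = sample_hospital_effects(m, cfg.hospital_effect_sd, rng)

    a, b = cfg.age_range
    age = truncnorm.rvs((a - cfg.age_mean) / cfg.age_sd,
                        (b - cfg.age_mean) / cfg.age_sd,
                        loc=cfg.age_mean, scale=cfg.age_sd,
                        size=n, random_state=rng)
    female = rng.binomial(1, cfg.gender_female_prob, n).astype(np.int8)

    out: dict[str, np.ndarray | list] = {
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "hospital_id": [f"H{j:03d}" for j in hosp_idx],
        "hospital_effect": u[hosp_idx],
        "age": np.round(age, 1),
        "gender_female": female,
    }

    corr_names = {nm for pair in cfg.covariate_corr for nm in pair[:2]}
    binary_names = [k for k in cfg.covariate_prevalences if k not in CLINICAL_KEYS]
    for name in binary_names:
        if name in corr_names:
            continue
        if name in cfg.hospital_prevalences:
            p = np.asarray(cfg.hospital_prevalences[name])[hosp_idx]
        else:
            p = cfg.covariate_prevalences[name]
        out[name] = rng.binomial(1, p, n).astype(np.int8)
    for na, nb, rho in cfg.covariate_corr:
        va, vb = _correlated_bernoulli(
            rng, n, cfg.covariate_prevalences[na], cfg.covariate_prevalences[nb], rho)
        out[na], out[nb] = va, vb

    # clinical categories
    if cfg.cohort == "ami":
        miss = rng.binomial(1, cfg.missing_prob.get("sbp", 0.0), n).astype(bool)
        le100 = rng.binomial(1, cfg.covariate_prevalences.get("sbp_le100", 0.0),
                             n).astype(bool) & ~miss
        out["sbp_le100"] = le100.astype(np.int8)
        out["sbp_missing"] = miss.astype(np.int8)
        sbp = np.where(le100, rng.uniform(72, 100, n), rng.uniform(101, 178, n))
        out["sbp_value"] = np.where(miss, np.nan, np.round(sbp))
    else:
        miss = rng.binomial(1, cfg.missing_prob.get("inr", 0.0), n).astype(bool)
        oor = rng.binomial(1, cfg.covariate_prevalences.get("inr_out_of_range", 0.0),
                           n).astype(bool) & ~miss
        out["inr_out_of_range"] = oor.astype(np.int8)
        out["inr_missing"] = miss.astype(np.int8)
        low = rng.uniform(0.5, 0.89, n)
        high = rng.uniform(1.21, 4.0, n)
        inr = np.where(oor, np.where(rng.random(n) < 0.3, low, high),
                       rng.uniform(0.9, 1.2, n))
        out["inr_value"] = np.where(miss, np.nan, np.round(inr, 2))
        cmiss = rng.binomial(1, cfg.missing_prob.get("creatinine", 0.0), n).astype(bool)
        out["creatinine_value"] = np.where(
            cmiss, np.nan, np.round(np.exp(rng.normal(0.0, 0.3, n)), 2))

    # lookback placement: comorbidity/drug evidence falls inside the window
    # with probability lookback_fraction; only in-window evidence counts
    for name in binary_names:
        if cfg.lookback_fraction < 1.0:
            inside = rng.binomial(1, cfg.lookback_fraction, n).astype(bool)
            raw = np.asarray(out[name]).astype(bool)
            out[name + "__raw"] = out[name]
            out[name] = (raw & inside).astype(np.int8)
            out[name + "__outside"] = (raw & ~inside).astype(np.int8)

    # linear predictor and outcome
    lp = (np.log(cfg.age_or) * (np.asarray(out["age"]) - cfg.age_mean)
          + np.log(cfg.gender_female_or) * np.asarray(out["gender_female"], float))
    for name, orr in cfg.covariate_or.items():
        if name in out:
            lp = lp + np.log(orr) * np.asarray(out[name], float)
    lp = lp + np.asarray(out["hospital_effect"])
    intercept = calibrate_intercept(cfg.target_event_rate, lp)
    out["linear_predictor"] = intercept + lp
    out["p_event"] = expit(intercept + lp)
    out["outcome"] = rng.binomial(1, out["p_event"]).astype(np.int8)
    frame = pd.DataFrame(out)
    frame.attrs["intercept"] = intercept
    return frame


def _pack_codes(codes_per_patient: pd.Series) -> list[list[str]]:
    """Split each patient's code list into chunks of <= 6 (1 principal + 5
    secondary), the discharge-abstract limit."""
    chunks = []
    for lst in codes_per_patient:
        for i in range(0, len(lst), 6):
            chunks.append(lst[i:i + 6])
    return chunks


def generate_population(config: GeneratorConfig) -> SyntheticData:
    """Generate a full synthetic registry from one master seed.

    Substreams are spawned per record type: identical configs and seeds give
    byte-identical outputs, and draws for one stream never perturb another.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_cov, s_adm, s_prior, s_disp, s_death = [
        np.random.default_rng(c) for c in ss.spawn(5)]

    truth = simulate_covariates(cfg, s_cov)
    n = cfg.n_patients
    pid = truth["patient_id"].to_numpy()

    # ---- index admissions -------------------------------------------------
    adm_offset = s_adm.integers(0, INDEX_SPAN_DAYS, n)
    adm_date = STUDY_START + adm_offset.astype("timedelta64[D]")
    los = s_adm.integers(3, 16, n)
    hh = s_adm.integers(0, 24, n)
    mm = s_adm.integers(0, 60, n)
    adm_time = [f"{h:02d}:{m:02d}" for h, m in zip(hh, mm)]

    if cfg.cohort == "ami":
        sub = s_adm.choice(["41001", "41011", "41041", "41071", "41091"], n)
        principal = sub.astype(object)
        secondary = [[] for _ in range(n)]
        # a fraction present as a complication principal + secondary AMI code
        compl = s_adm.random(n) < 0.08
        compl_code = s_adm.choice(["4230", "4271", "4274", "5184"], n)
        for i in np.where(compl)[0]:
            secondary[i].append(principal[i])
            principal[i] = compl_code[i]
        drg = np.where(s_adm.random(n) < 0.5, "121", "122").astype(object)
    else:
        sub = s_adm.choice(["82000", "82021", "82022", "8208"], n)
        principal = sub.astype(object)
        secondary = [[] for _ in range(n)]
        drg = np.where(s_adm.random(n) < 0.7, "209", "211").astype(object)

    # index-admission flags live on the index record's secondary diagnoses
    for name in cfg.covariate_prevalences:
        if not name.endswith("_index"):
            continue
        flagged = truth[name].to_numpy().astype(bool)
        code = CONDITION_CODE[name]
        for i in np.where(flagged)[0]:
            if len(secondary[i]) < 5:
                secondary[i].append(code)

    # ---- procedures and deaths -------------------------------------------
    outcome = truth["outcome"].to_numpy().astype(bool)
    procedures: list[list[str]] = [[] for _ in range(n)]
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    if cfg.cohort == "ami":
        pci = s_adm.random(n) < 0.3
        for i in np.where(pci)[0]:
            procedures[i].append(f"0066@{adm_date[i]}")
        dd = s_death.integers(0, 31, n)
        late = (~outcome) & (s_death.random(n) < 0.06)
        dd_late = s_death.integers(31, 366, n)
        death_date[outcome] = adm_date[outcome] + dd[outcome].astype("timedelta64[D]")
        death_date[late] = adm_date[late] + dd_late[late].astype("timedelta64[D]")
    else:
        surg_day = np.where(s_adm.random(n) < 0.5, 0, 1)
        late_day = s_adm.integers(2, 11, n)
        late_surg = (~outcome) & (s_adm.random(n) < 0.7)
        surg_code = s_adm.choice(["7935", "8151", "8152"], n)
        for i in range(n):
            if outcome[i]:
                d = adm_date[i] + np.timedelta64(int(surg_day[i]), "D")
                procedures[i].append(f"{surg_code[i]}@{d}")
            elif late_surg[i]:
                d = adm_date[i] + np.timedelta64(int(late_day[i]), "D")
                procedures[i].append(f"{surg_code[i]}@{d}")
        die = s_death.random(n) < 0.05
        dd_any = s_death.integers(5, 366, n)
        death_date[die] = adm_date[die] + dd_any[die].astype("timedelta64[D]")

    disch_date = adm_date + los.astype("timedelta64[D]")
    died_in_hosp = ~np.isnat(death_date) & (death_date <= disch_date)
    disch_date = np.where(died_in_hosp, death_date, disch_date)
    disposition = np.where(died_in_hosp, "died", "discharged").astype(object)

    index_df = pd.DataFrame({
        "admission_id": [f"A{i:07d}" for i in range(n)],
        "patient_id": pid,
        "hospital_id": truth["hospital_id"].to_numpy(),
        "admission_date": adm_date,
        "admission_time": adm_time,
        "discharge_date": disch_date,
        "principal_dx": principal,
        "secondary_dx": ["|".join(s) for s in secondary],
        "procedures": ["|".join(p) for p in procedures],
        "drg": drg,
        "disposition": disposition,
        "age": truth["age"].to_numpy(),
        "gender": np.where(truth["gender_female"].to_numpy() == 1, "F", "M"),
        "resident": True,
        "icu_direct": False,
    })

    # ---- early re-admissions (same episode) -------------------------------
    readmit = s_adm.random(n) < cfg.readmit_fraction
    ridx = np.where(readmit)[0]
    if len(ridx):
        gap = s_adm.integers(3, 27, len(ridx))
        r_adm = adm_date[ridx] + gap.astype("timedelta64[D]")
        # readmission must start before the episode window would re-open and
        # (for usable ground truth) not outlive the death date
        keep = np.ones(len(ridx), dtype=bool)
        keep &= np.isnat(death_date[ridx]) | (r_adm <= death_date[ridx])
        ridx, r_adm = ridx[keep], r_adm[keep]
    if len(ridx):
        r_los = s_adm.integers(2, 8, len(ridx))
        readmit_df = pd.DataFrame({
            "admission_id": [f"R{i:07d}" for i in range(len(ridx))],
            "patient_id": pid[ridx],
            "hospital_id": truth["hospital_id"].to_numpy()[ridx],
            "admission_date": r_adm,
            "admission_time": "12:00",
            "discharge_date": r_adm + r_los.astype("timedelta64[D]"),
            "principal_dx": principal[ridx],
            "secondary_dx": "",
            "procedures": "",
            "drg": drg[ridx],
            "disposition": "discharged",
            "age": truth["age"].to_numpy()[ridx],
            "gender": np.where(truth["gender_female"].to_numpy()[ridx] == 1, "F", "M"),
            "resident": True,
            "icu_direct": False,
        })
    else:
        readmit_df = pd.DataFrame(columns=index_df.columns)

    # ---- prior admissions carrying comorbidity evidence -------------------
    prior_rows = []
    cond_names = [nm for nm in cfg.covariate_prevalences
                  if nm not in CLINICAL_KEYS and not nm.endswith("_index")
                  and nm not in DRUG_CLASSES]
    pairs_in, pairs_out = [], []
    for name in cond_names:
        flags_in = truth[name].to_numpy().astype(bool)
        for i in np.where(flags_in)[0]:
            pairs_in.append((i, CONDITION_CODE[name]))
        outside_col = name + "__outside"
        if outside_col in truth.columns:
            for i in np.where(truth[outside_col].to_numpy().astype(bool))[0]:
                pairs_out.append((i, CONDITION_CODE[name]))

    def _emit_prior(pairs: list[tuple[int, str]], inside: bool, tag: str):
        if not pairs:
            return
        dfp = pd.DataFrame(pairs, columns=["i", "code"]).sort_values(["i", "code"])
        grouped = dfp.groupby("i")["code"].apply(list)
        for i, code_list in grouped.items():
            for c0 in range(0, len(code_list), 6):
                chunk = code_list[c0:c0 + 6]
                if inside:
                    back = int(s_prior.integers(30, 720))
                else:
                    back = int(s_prior.integers(735, 1100))
                p_adm = adm_date[i] - np.timedelta64(back, "D")
                prior_rows.append({
                    "admission_id": f"{tag}{len(prior_rows):07d}",
                    "patient_id": pid[i],
                    "hospital_id": f"H{int(s_prior.integers(0, cfg.n_hospitals)):03d}",
                    "admission_date": p_adm,
                    "admission_time": "10:00",
                    "discharge_date": p_adm + np.timedelta64(int(s_prior.integers(2, 11)), "D"),
                    "principal_dx": chunk[0],
                    "secondary_dx": "|".join(chunk[1:]),
                    "procedures": "",
                    "drg": "127",
                    "disposition": "discharged",
                    "age": float(truth["age"].iloc[i]),
                    "gender": "F" if truth["gender_female"].iloc[i] == 1 else "M",
                    "resident": True,
                    "icu_direct": False,
                })

    _emit_prior(pairs_in, inside=True, tag="B")
    _emit_prior(pairs_out, inside=False, tag="C")
    prior_df = (pd.DataFrame(prior_rows) if prior_rows
                else pd.DataFrame(columns=index_df.columns))

    discharges = pd.concat([index_df, readmit_df, prior_df], ignore_index=True)
    discharges["admission_date"] = pd.to_datetime(discharges["admission_date"])
    discharges["discharge_date"] = pd.to_datetime(discharges["discharge_date"])

    # ---- dispensings ------------------------------------------------------
    disp_rows = []
    drug_names = [nm for nm in cfg.covariate_prevalences if nm in DRUG_CLASSES]
    for name in drug_names:
        atc = CLASS_ATC_CODE[name]
        flags = truth[name].to_numpy().astype(bool)
        idx = np.where(flags)[0]
        n_rx = s_disp.integers(1, 3, len(idx))
        for i, k in zip(idx, n_rx):
            for _ in range(int(k)):
                back = int(s_disp.integers(1, 90))
                disp_rows.append((pid[i], adm_date[i] - np.timedelta64(back, "D"), atc))
        outside_col = name + "__outside"
        if outside_col in truth.columns:
            for i in np.where(truth[outside_col].to_numpy().astype(bool))[0]:
                back = int(s_disp.integers(95, 300))
                disp_rows.append((pid[i], adm_date[i] - np.timedelta64(back, "D"), atc))
        # out-of-window decoys for unexposed patients
        unexp = np.where(~flags)[0]
        decoy = unexp[s_disp.random(len(unexp)) < cfg.decoy_dispensing_rate * 0.3]
        for i in decoy:
            back = int(s_disp.integers(95, 300))
            disp_rows.append((pid[i], adm_date[i] - np.timedelta64(back, "D"), atc))
    # irrelevant-class decoys inside the window
    decoy = np.where(s_disp.random(n) < cfg.decoy_dispensing_rate)[0]
    for i in decoy:
        back = int(s_disp.integers(1, 90))
        disp_rows.append((pid[i], adm_date[i] - np.timedelta64(back, "D"), _DECOY_ATC))
    dispensings = pd.DataFrame(disp_rows,
                               columns=["patient_id", "dispensing_date", "atc"])
    dispensings["dispensing_date"] = pd.to_datetime(dispensings["dispensing_date"])
    dispensings = dispensings.sort_values(
        ["patient_id", "dispensing_date", "atc"]).reset_index(drop=True)

    # ---- clinical variables ----------------------------------------------
    if cfg.cohort == "ami":
        clinical = pd.DataFrame({
            "admission_id": index_df["admission_id"],
            "sbp": truth["sbp_value"],
            "inr": np.nan,
            "creatinine": np.nan,
        })
    else:
        clinical = pd.DataFrame({
            "admission_id": index_df["admission_id"],
            "sbp": np.nan,
            "inr": truth["inr_value"],
            "creatinine": truth["creatinine_value"],
        })

    # ---- deaths -----------------------------------------------------------
    has_death = ~np.isnat(death_date)
    deaths = pd.DataFrame({
        "patient_id": pid[has_death],
        "death_date": pd.to_datetime(death_date[has_death]),
    })

    truth = truth.copy()
    truth.insert(1, "admission_id", index_df["admission_id"].to_numpy())
    return SyntheticData(discharges, dispensings, clinical, deaths, truth)
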