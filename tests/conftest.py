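"""Shared fixtures: hand-constructed toy registries with hand-worked
expected results, and small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import riskprofiler as rp
from riskprofiler.synthetic import SyntheticData

DISCHARGE_COLUMNS = [
    "admission_id", "patient_id", "hospital_id", "admission_date",
    "admission_time", "discharge_date", "principal_dx", "secondary_dx",
    "procedures", "drg", "disposition", "age", "gender", "resident",
    "icu_direct",
]


def _adm(aid, pid, hosp, adm, disch, pdx, sdx="", procs="", drg="121",
         dispo="discharged", age=70.0, gender="M", resident=True, icu=False):
    return dict(zip(DISCHARGE_COLUMNS,
                    [aid, pid, hosp, adm, "10:00", disch, pdx, sdx, procs,
                     drg, dispo, age, gender, resident, icu]))


def _registry(adm_rows, disp_rows, clin_rows, death_rows) -> SyntheticData:
    discharges = pd.DataFrame(adm_rows, columns=DISCHARGE_COLUMNS)
    discharges["admission_date"] = pd.to_datetime(discharges["admission_date"])
    discharges["discharge_date"] = pd.to_datetime(discharges["discharge_date"])
    dispensings = pd.DataFrame(disp_rows,
                               columns=["patient_id", "dispensing_date", "atc"])
    dispensings["dispensing_date"] = pd.to_datetime(dispensings["dispensing_date"])
    clinical = pd.DataFrame(clin_rows,
                            columns=["admission_id", "sbp", "inr", "creatinine"])
    deaths = pd.DataFrame(death_rows, columns=["patient_id", "death_date"])
    deaths["death_date"] = pd.to_datetime(deaths["death_date"])
    return SyntheticData(discharges, dispensings, clinical, deaths, pd.DataFrame())


@pytest.fixture(scope="session")
def toy_ami_registry() -> SyntheticData:
    """Hand-built AMI registry covering index selection, the 28-day episode
    rule, lookback and drug windows, clinical categories, both mortality
    ascertainment routes and the complete-case rule. Expected results are
    worked by hand in the tests that consume it."""
    adm = [
        # P01: plain AMI; diabetes admission 365 d before; death day 10
        _adm("A01", "P01", "H1", "2010-03-10", "2010-03-17", "41071"),
        _adm("B01", "P01", "H1", "2009-03-10", "2009-03-13", "25000"),
        # P02: AMI only secondary, principal 427.5 NOT a complication -> out
        _adm("A02", "P02", "H1", "2010-02-05", "2010-02-10", "4275", "4109"),
        # P03: complication presentation (427.1 + secondary 410.1) -> in;
        #      death exactly on day 30
        _adm("A03", "P03", "H2", "2010-04-01", "2010-04-09", "4271", "4101",
             age=55.0, gender="F"),
        # P04: readmission 20 d later (same episode); diabetes admission
        #      800 d before (outside window); death day 31
        _adm("A04", "P04", "H2", "2010-02-01", "2010-02-06", "41091"),
        _adm("A05", "P04", "H3", "2010-02-21", "2010-02-25", "41091"),
        _adm("B02", "P04", "H2", "2007-11-24", "2007-11-27", "25000"),
        # P05: admissions at day 0 / +20 / +40 -> episodes at day 0 and +40
        _adm("A06", "P05", "H3", "2010-05-01", "2010-05-06", "41001"),
        _adm("A07", "P05", "H3", "2010-05-21", "2010-05-25", "41001"),
        _adm("A08", "P05", "H3", "2010-06-10", "2010-06-14", "41001"),
        # P06: age above range
        _adm("A09", "P06", "H1", "2010-03-01", "2010-03-06", "41091", age=101.0),
        # P07: non-resident
        _adm("A10", "P07", "H1", "2010-03-02", "2010-03-07", "41091",
             resident=False),
        # P08: index secondary dx set blood-disorders + other-ischemic index
        #      flags; dies in hospital on day 5 (disposition route, no
        #      registry row); no clinical row -> SBP missing
        _adm("A11", "P08", "H2", "2010-06-01", "2010-06-06", "41011",
             "2859|4149", dispo="died"),
        # P09: missing gender -> complete-case removal
        _adm("A12", "P09", "H1", "2010-07-01", "2010-07-08", "4109", gender=""),
        # P10: hypertension admission exactly 730 d before (window boundary,
        #      inside), lipid-disorder admission 731 d before (outside)
        _adm("A13", "P10", "H3", "2010-08-15", "2010-08-20", "41011"),
        _adm("B03", "P10", "H1", "2008-08-15", "2008-08-18", "4019"),
        _adm("B04", "P10", "H1", "2008-08-14", "2008-08-17", "2724"),
    ]
    disp = [
        ("P03", "2010-03-22", "C09AA05"),   # 10 d before index -> ACE flag
        ("P03", "2009-12-22", "C09AA05"),   # 100 d before -> outside window
        ("P08", "2010-06-01", "C07AB07"),   # on the index date -> no flag
        ("P08", "2010-03-03", "C03CA01"),   # exactly 90 d before -> flag
        ("P10", "2010-08-10", "BAD-CODE"),  # malformed ATC -> skipped
    ]
    clin = [
        ("A01", 130.0, np.nan, np.nan),     # gt100
        ("A03", 85.0, np.nan, np.nan),      # le100
        ("A04", 100.0, np.nan, np.nan),     # boundary -> le100
        ("A06", 110.0, np.nan, np.nan),     # gt100
        ("A13", 120.0, np.nan, np.nan),     # gt100
        # A08, A11: no row -> missing
    ]
    deaths = [
        ("P01", "2010-03-20"),              # day 10
        ("P03", "2010-05-01"),              # day 30 (inclusive boundary)
        ("P04", "2010-03-04"),              # day 31 -> not an event
    ]
    return _registry(adm, disp, clin, deaths)


@pytest.fixture(scope="session")
def toy_hip_registry() -> SyntheticData:
    """Hand-built hip-fracture registry exercising each of the seven
    exclusion rules, the 48-hour surgery outcome and INR categories."""
    adm = [
        # Q01: surgery on day 0 -> event
        _adm("H01", "Q01", "H1", "2010-03-01", "2010-03-12", "82021",
             procs="7935@2010-03-01", drg="209", age=80.0, gender="F"),
        # Q02: surgery on day 1 -> event; INR 1.2 boundary -> in range
        _adm("H02", "Q02", "H1", "2010-04-02", "2010-04-15", "8208",
             procs="8151@2010-04-03", drg="209", age=85.0, gender="F"),
        # Q03: hip fracture 1 year earlier -> rule 1 (the earlier admission
        #      itself falls outside the study period)
        _adm("H03", "Q03", "H2", "2010-05-01", "2010-05-12", "82021",
             procs="7935@2010-05-01", drg="209", age=78.0, gender="F"),
        _adm("H04", "Q03", "H2", "2009-05-01", "2009-05-10", "8200",
             procs="7935@2009-05-01", drg="209", age=77.0, gender="F"),
        # Q04: age 64 -> rule 2
        _adm("H05", "Q04", "H1", "2010-03-05", "2010-03-15", "82021",
             procs="7935@2010-03-05", drg="209", age=64.0),
        # Q05: non-resident -> rule 3
        _adm("H06", "Q05", "H1", "2010-03-06", "2010-03-16", "82021",
             drg="209", age=70.0, resident=False),
        # Q06: cancer on the index admission -> rule 4
        _adm("H07", "Q06", "H2", "2010-03-07", "2010-03-17", "82021", "1749",
             drg="209", age=81.0, gender="F"),
        # Q07: cancer admission in the previous two years -> rule 4
        _adm("H08", "Q07", "H2", "2010-03-08", "2010-03-18", "82021",
             drg="209", age=82.0, gender="F"),
        _adm("H09", "Q07", "H3", "2009-06-01", "2009-06-05", "1534"),
        # Q08: multiple-trauma DRG -> rule 5
        _adm("H10", "Q08", "H1", "2010-03-09", "2010-03-19", "82021",
             drg="485", age=75.0),
        # Q09: direct ICU admission -> rule 6
        _adm("H11", "Q09", "H1", "2010-03-10", "2010-03-20", "82021",
             drg="209", age=76.0, icu=True),
        # Q10: no surgery, death day 1 -> rule 7
        _adm("H12", "Q10", "H3", "2010-03-11", "2010-03-12", "82021",
             drg="209", age=88.0, gender="F", dispo="died"),
        # Q11: no surgery, death day 10 -> retained, no event
        _adm("H13", "Q11", "H3", "2010-03-12", "2010-03-22", "82021",
             drg="209", age=89.0, gender="F", dispo="died"),
        # Q12: surgery on day 2 -> no event; INR 1.3 out of range;
        #      antiplatelet 15 d before, anticoagulant 95 d before
        _adm("H14", "Q12", "H2", "2010-03-13", "2010-03-25", "82022",
             procs="8152@2010-03-15", drg="209", age=83.0, gender="F"),
        # Q13: osteoporosis admission 600 d before; surgery day 1 -> event
        _adm("H15", "Q13", "H2", "2010-09-01", "2010-09-10", "82021",
             procs="7935@2010-09-02", drg="209", age=84.0, gender="F"),
        _adm("B11", "Q13", "H1", "2009-01-10", "2009-01-13", "73300"),
        # Q14: hip fracture as secondary diagnosis -> included, no surgery
        _adm("H16", "Q14", "H3", "2010-03-15", "2010-03-28", "7159", "8202",
             drg="209", age=79.0, gender="F"),
    ]
    disp = [
        ("Q12", "2010-02-26", "B01AC06"),   # 15 d before -> antiplatelet flag
        ("Q12", "2009-12-08", "B01AA03"),   # 95 d before -> no flag
    ]
    clin = [
        ("H02", np.nan, 1.2, 0.9),
        ("H14", np.nan, 1.3, 1.1),
        ("H01", np.nan, 1.0, 0.8),
        ("H13", np.nan, 1.05, 1.0),
        ("H15", np.nan, 0.95, 1.2),
        # H16: no row -> INR missing
    ]
    deaths = [
        ("Q10", "2010-03-12"),
        ("Q11", "2010-03-22"),
    ]
    return _registry(adm, disp, clin, deaths)


@pytest.fixture(scope="session")
def small_ami_data() -> SyntheticData:
    """Default-parameter AMI registry, small enough for fast reuse."""
    cfg = rp.ami_generator_config(n_patients=4000, n_hospitals=12, seed=202)
    return rp.generate_population(cfg)


@pytest.fixture(scope="session")
def small_ami_cohort(small_ami_data) -> pd.DataFrame:
    cohort, _ = rp.build_ami_cohort(small_ami_data)
    return cohort
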