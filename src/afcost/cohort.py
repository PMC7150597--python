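"""Cohort construction: cleaning, incident-AF identification, covariates, panel.

The incident cohort is every patient whose hospital episodes carry ICD-10 code
I48 (atrial fibrillation / flutter) in any of the six diagnostic positions,
taking the earliest such admission as the index event with a 5-year lookback:
an admission only counts as incident when no I48-bearing admission precedes it
within the lookback window, and each patient contributes at most one index
event.  Patients are then followed for five years from the index date; the
follow-up panel has one row per patient per year, keeping the year containing
death and dropping years entirely after it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as dz

logger = logging.getLogger(__name__)

DIAG_COLUMNS = tuple(f"diag_{i}" for i in range(1, 7))

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")

#: ICD-10 prefix -> Charlson condition group (Quan et al. coding, collapsed to
#: prefixes).  Only distinct-group membership matters here: the comorbidity
#: covariate is the 3-level count {none, one, more than one}, not the weighted
#: index.
CHARLSON_ICD10_PREFIXES: dict[str, str] = {
    # myocardial infarction
    "I21": "mi", "I22": "mi", "I252": "mi",
    # congestive heart failure
    "I099": "chf", "I110": "chf", "I130": "chf", "I132": "chf", "I255": "chf",
    "I420": "chf", "I425": "chf", "I426": "chf", "I427": "chf", "I428": "chf",
    "I429": "chf", "I43": "chf", "I50": "chf", "P290": "chf",
    # peripheral vascular disease
    "I70": "pvd", "I71": "pvd", "I731": "pvd", "I738": "pvd", "I739": "pvd",
    "I771": "pvd", "I790": "pvd", "I792": "pvd", "K551": "pvd", "K558": "pvd",
    "K559": "pvd", "Z958": "pvd", "Z959": "pvd",
    # cerebrovascular disease
    "G45": "cevd", "G46": "cevd", "H340": "cevd", "I60": "cevd", "I61": "cevd",
    "I62": "cevd", "I63": "cevd", "I64": "cevd", "I65": "cevd", "I66": "cevd",
    "I67": "cevd", "I68": "cevd", "I69": "cevd",
    # dementia
    "F00": "dementia", "F01": "dementia", "F02": "dementia", "F03": "dementia",
    "F051": "dementia", "G30": "dementia", "G311": "dementia",
    # chronic pulmonary disease
    "I278": "cpd", "I279": "cpd", "J40": "cpd", "J41": "cpd", "J42": "cpd",
    "J43": "cpd", "J44": "cpd", "J45": "cpd", "J46": "cpd", "J47": "cpd",
    "J60": "cpd", "J61": "cpd", "J62": "cpd", "J63": "cpd", "J64": "cpd",
    "J65": "cpd", "J66": "cpd", "J67": "cpd", "J684": "cpd", "J701": "cpd",
    "J703": "cpd",
    # rheumatic disease
    "M05": "rheum", "M06": "rheum", "M315": "rheum", "M32": "rheum",
    "M33": "rheum", "M34": "rheum", "M351": "rheum", "M353": "rheum",
    "M360": "rheum",
    # peptic ulcer disease
    "K25": "pud", "K26": "pud", "K27": "pud", "K28": "pud",
    # mild liver disease
    "B18": "liver", "K700": "liver", "K701": "liver", "K702": "liver",
    "K703": "liver", "K709": "liver", "K713": "liver", "K714": "liver",
    "K715": "liver", "K717": "liver", "K73": "liver", "K74": "liver",
    "K760": "liver", "K762": "liver", "K763": "liver", "K764": "liver",
    "K768": "liver", "K769": "liver", "Z944": "liver",
    # diabetes (with and without complications collapsed to one group)
    "E10": "diabetes", "E11": "diabetes", "E12": "diabetes", "E13": "diabetes",
    "E14": "diabetes",
    # hemiplegia / paraplegia
    "G041": "plegia", "G114": "plegia", "G801": "plegia", "G802": "plegia",
    "G81": "plegia", "G82": "plegia", "G830": "plegia", "G831": "plegia",
    "G832": "plegia", "G833": "plegia", "G834": "plegia", "G839": "plegia",
    # renal disease
    "I120": "renal", "I131": "renal", "N032": "renal", "N033": "renal",
    "N034": "renal", "N035": "renal", "N036": "renal", "N037": "renal",
    "N052": "renal", "N053": "renal", "N054": "renal", "N055": "renal",
    "N056": "renal", "N057": "renal", "N18": "renal", "N19": "renal",
    "N250": "renal", "Z490": "renal", "Z491": "renal", "Z492": "renal",
    "Z940": "renal", "Z992": "renal",
    # any malignancy
    "C0": "cancer", "C1": "cancer", "C2": "cancer", "C3": "cancer",
    "C40": "cancer", "C41": "cancer", "C43": "cancer", "C45": "cancer",
    "C46": "cancer", "C47": "cancer", "C48": "cancer", "C49": "cancer",
    "C5": "cancer", "C6": "cancer", "C70": "cancer", "C71": "cancer",
    "C72": "cancer", "C73": "cancer", "C74": "cancer", "C75": "cancer",
    "C76": "cancer", "C81": "cancer", "C82": "cancer", "C83": "cancer",
    "C84": "cancer", "C85": "cancer", "C88": "cancer", "C90": "cancer",
    "C91": "cancer", "C92": "cancer", "C93": "cancer", "C94": "cancer",
    "C95": "cancer", "C96": "cancer", "C97": "cancer",
    # moderate/severe liver disease
    "I850": "sev_liver", "I859": "sev_liver", "I864": "sev_liver",
    "I982": "sev_liver", "K704": "sev_liver", "K711": "sev_liver",
    "K721": "sev_liver", "K729": "sev_liver", "K765": "sev_liver",
    "K766": "sev_liver", "K767": "sev_liver",
    # metastatic solid tumour
    "C77": "mets", "C78": "mets", "C79": "mets", "C80": "mets",
    # AIDS/HIV
    "B20": "hiv", "B21": "hiv", "B22": "hiv", "B24": "hiv",
}


def clean_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact duplicates, drop malformed rows, sort.

    Rows with unparseable dates or discharge before admission are dropped and
    logged with reasons (never fatal).  Idempotent: clean(clean(E)) = clean(E).
    The drop tally is attached as ``result.attrs['cleaning_log']``.
    """
    df = episodes.copy()
    n_in = len(df)
    log: dict[str, int] = {"rows_in": n_in}

    df["admit_date"] = pd.to_datetime(df["admit_date"], errors="coerce")
    df["discharge_date"] = pd.to_datetime(df["discharge_date"], errors="coerce")
    bad_dates = df["admit_date"].isna() | df["discharge_date"].isna()
    log["unparseable_dates"] = int(bad_dates.sum())
    df = df[~bad_dates]

    wrong_order = df["discharge_date"] < df["admit_date"]
    log["date_order"] = int(wrong_order.sum())
    df = df[~wrong_order]

    before = len(df)
    df = df.drop_duplicates()
    log["duplicates_removed"] = before - len(df)

    df = df.sort_values(["patient_id", "admit_date", "discharge_date"]).reset_index(drop=True)
    log["rows_out"] = len(df)
    if log["unparseable_dates"] or log["date_order"]:
        logger.info("clean_episodes dropped rows: %s", log)
    df.attrs["cleaning_log"] = log
    return df


def _has_af(df: pd.DataFrame) -> pd.Series:
    """Row mask: any of the six diagnostic positions starts with I48."""
    mask = pd.Series(False, index=df.index)
    for col in DIAG_COLUMNS:
        if col in df.columns:
            mask |= df[col].fillna("").astype(str).str.startswith("I48")
    return mask


def identify_incident_af(
    episodes: pd.DataFrame,
    lookback_years: int = 5,
    extract_start: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Identify incident AF index events (one per patient).

    For each patient, the earliest admission carrying I48 in any diagnosis
    position such that no I48-bearing admission exists in the preceding
    ``lookback_years``.  With one index per patient this is the first
    I48 admission; the lookback matters at the data boundary: index events
    within ``lookback_years`` of ``extract_start`` (default: earliest
    admission in the data) are retained but flagged ``lookback_incomplete``
    so a sensitivity exclusion is one filter away.

    Returns a DataFrame (patient_id, index_date, lookback_incomplete).
    """
    if episodes.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "lookback_incomplete"])
    af = episodes[_has_af(episodes)]
    if af.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "lookback_incomplete"])
    first = (
        af.groupby("patient_id", sort=True)["admit_date"].min().rename("index_date").reset_index()
    )
    if extract_start is None:
        extract_start = pd.Timestamp(episodes["admit_date"].min())
    boundary = pd.Timestamp(extract_start) + pd.DateOffset(years=lookback_years)
    first["lookback_incomplete"] = first["index_date"] < boundary
    return first


def comorbidity_category(
    diagnoses, condition_map: dict[str, str] | None = None
) -> int:
    """Collapsed Charlson level from a collection of ICD-10 codes.

    Counts distinct Charlson condition groups among the codes (I48 itself is
    ignored): 0 groups -> 1, exactly one -> 2, more than one -> 3.
    """
    cmap = CHARLSON_ICD10_PREFIXES if condition_map is None else condition_map
    prefixes = sorted(cmap, key=len, reverse=True)
    groups: set[str] = set()
    for code in diagnoses:
        code = str(code).strip().upper().replace(".", "")
        if not code or code.startswith("I48"):
            continue
        for p in prefixes:
            if code.startswith(p):
                groups.add(cmap[p])
                break
    return 1 if not groups else (2 if len(groups) == 1 else 3)


def index_stay_comorbidity(
    episodes: pd.DataFrame,
    index_events: pd.DataFrame,
    condition_map: dict[str, str] | None = None,
    transfer_tolerance_days: int = 0,
) -> pd.Series:
    """Comorbidity level per patient from the index continuous stay's diagnoses."""
    from .costing import build_cis

    out = {}
    ep = episodes.sort_values(["patient_id", "admit_date"])
    idx_map = dict(zip(index_events["patient_id"], index_events["index_date"]))
    for pid, grp in ep.groupby("patient_id", sort=False):
        idx_date = idx_map.get(pid)
        if idx_date is None:
            continue
        codes: list[str] = []
        for cis in build_cis(grp, transfer_tolerance_days):
            if cis.start <= pd.Timestamp(idx_date) <= cis.end:
                for col in DIAG_COLUMNS:
                    if col in cis.episodes.columns:
                        codes.extend(
                            c for c in cis.episodes[col].fillna("").astype(str) if c
                        )
                break
        out[pid] = comorbidity_category(codes, condition_map)
    return pd.Series(out, name="comorbidity")


def age_group(age_at_index: int) -> str:
    """Map an integer age at index admission to its model band."""
    if age_at_index < 0:
        raise ValueError(f"age must be non-negative, got {age_at_index}")
    if age_at_index <= 49:
        return "0-49"
    if age_at_index >= 90:
        return "90-max"
    lo = 50 + 5 * ((int(age_at_index) - 50) // 5)
    return f"{lo}-{lo + 4}"


def build_panel(
    index_events: pd.DataFrame,
    covariates: pd.DataFrame,
    deaths: pd.DataFrame,
    followup_years: int = 5,
) -> pd.DataFrame:
    """Assemble the patient-year follow-up panel skeleton.

    One row per patient per follow-up year from the index date; years entirely
    after death are excluded, the year containing death is retained.
    ``died_within_5y`` is death date <= index + 5 years.  Patients whose death
    precedes their index date are excluded and logged.  Cost fields start at
    zero.

    ``covariates`` carries one row per patient with age, sex, simd, geography,
    health_board, comorbidity (admission_year and age_group are derived here
    if absent).
    """
    if followup_years < 1:
        raise ValueError("followup_years must be >= 1")
    death_map = {}
    if deaths is not None and len(deaths):
        death_map = dict(zip(deaths["patient_id"], pd.to_datetime(deaths["death_date"])))

    cov = covariates.set_index("patient_id")
    rows: list[dict] = []
    excluded = 0
    for _, ev in index_events.iterrows():
        pid = ev["patient_id"]
        index_date = pd.Timestamp(ev["index_date"])
        death = death_map.get(pid)
        if death is not None and death < index_date:
            excluded += 1
            logger.info("excluding %s: death %s precedes index %s", pid, death, index_date)
            continue
        horizon = index_date + pd.DateOffset(years=followup_years)
        died_flag = bool(death is not None and death <= horizon)
        n_years = followup_years
        if death is not None and death < horizon:
            y = 1
            while death >= index_date + pd.DateOffset(years=y):
                y += 1
            n_years = min(y, followup_years)
        c = cov.loc[pid]
        ag = c["age_group"] if "age_group" in cov.columns else age_group(int(c["age"]))
        year = (
            int(c["admission_year"])
            if "admission_year" in cov.columns
            else int(index_date.year)
        )
        for y in range(1, n_years + 1):
            rows.append(
                {
                    "patient_id": pid,
                    "year_index": y,
                    "index_date": index_date,
                    "age_group": ag,
                    "sex": c["sex"],
                    "admission_year": year,
                    "simd": int(c["simd"]),
                    "geography": c["geography"],
                    "health_board": c["health_board"],
                    "comorbidity": int(c["comorbidity"]),
                    "died_within_5y": died_flag,
                    "cost_inpatient": 0.0,
                    "cost_outpatient": 0.0,
                    "cost_prescribing": 0.0,
                    "cost_care_home": 0.0,
                    "total": 0.0,
                    "any_use": False,
                }
            )
    panel = pd.DataFrame(rows)
    panel.attrs["excluded_death_before_index"] = excluded
    return panel


def derive_covariates_from_records(
    episodes: pd.DataFrame, index_events: pd.DataFrame, population: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient covariate table for panel construction.

    Socio-demographic fields (age, sex, SIMD, geography, health board) come
    from the registry-style ``population`` table; the comorbidity level is
    derived from the index continuous stay's diagnoses and the admission year
    from the index date.
    """
    cov = population.drop(columns=["comorbidity"], errors="ignore").copy()
    como = index_stay_comorbidity(episodes, index_events)
    cov = cov.merge(como.rename("comorbidity"), left_on="patient_id", right_index=True)
    idx = index_events.set_index("patient_id")["index_date"]
    cov["admission_year"] = cov["patient_id"].map(idx).dt.year.astype(int)
    if "age_group" not in cov.columns:
        cov["age_group"] = cov["age"].astype(int).map(age_group)
    return cov
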