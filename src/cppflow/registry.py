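"""Registry data model: referral/cancer/patient tables, diagnosis grouping,
cohort construction and referral-diagnosis linkage.

The analysis operates on three delimited-text tables (comma-separated, UTF-8,
header row mandatory, ISO-8601 dates):

* ``referrals.csv``  — one row per CPP episode:
  ``patient_id, cpp_id, wfs_date, stop_date, stop_code``
* ``cancer.csv``     — one row per registered tumour:
  ``patient_id, diagnosis_date, icd_code, histology_code``
* ``patients.csv``   — one row per person:
  ``patient_id, sex, birth_year, death_date``

plus a YAML catalogue describing each standardized cancer patient pathway
(CPP): its primarily suspected diagnosis (PSD) code group, whether a filter
function precedes entry, and the recommended lead-time range in days.

All analysis time is measured in whole calendar days since the date of
well-founded suspicion (WFS); day 0 is the WFS date itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Stop codes recorded when a CPP episode ends.
STOP_CODES = (
    "TREATMENT_START",
    "SUSPICION_REJECTED",
    "OTHER_CANCER",
    "CRITERIA_NOT_MET",
    "PATIENT_CHOICE",
    "OTHER_MEDICAL",
)

#: Diagnosis-group identifier for tumours not mapped to any PSD group
#: (including benign tumours) and for cancer of unknown primary.
OTHER_GROUP = "OTHER"
CUP_GROUP = "CUP"


class SchemaError(ValueError):
    """A mandatory column is missing or the file header is malformed."""


class RowError(ValueError):
    """One or more rows violate the schema; message lists line numbers."""


class LinkageError(ValueError):
    """Referrals reference patient ids absent from the patient table."""


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CppDefinition:
    """One standardized cancer patient pathway.

    Parameters
    ----------
    cpp_id
        Short identifier used in the referral table.
    name
        Display name.
    has_psd
        Whether the CPP targets a primarily suspected diagnosis (PSD).
        The CUP and nonspecific-symptoms pathways do not.
    psd_group
        Diagnosis-group identifier of the PSD, or ``None`` when ``has_psd``
        is false.
    has_filter_function
        Whether a specialist-confirmed pre-step (e.g. mammography) is
        required before well-founded suspicion.
    lead_time_min_days, lead_time_max_days
        Recommended time from well-founded suspicion to start of treatment.
        The range reflects treatment-modality-specific lead times; target
        evaluation conservatively uses the maximum.  ``None`` when the CPP
        has no specified lead time (it is then excluded from lead-time
        evaluation).
    """

    cpp_id: str
    name: str
    has_psd: bool
    psd_group: str | None = None
    has_filter_function: bool = False
    lead_time_min_days: int | None = None
    lead_time_max_days: int | None = None

    def __post_init__(self) -> None:
        if self.has_psd != (self.psd_group is not None):
            raise ValueError(
                f"{self.cpp_id}: has_psd={self.has_psd} inconsistent with "
                f"psd_group={self.psd_group!r}"
            )
        lo, hi = self.lead_time_min_days, self.lead_time_max_days
        if (lo is None) != (hi is None):
            raise ValueError(f"{self.cpp_id}: lead-time range must set both ends")
        if lo is not None and not 0 <= lo <= hi:
            raise ValueError(f"{self.cpp_id}: invalid lead-time range [{lo}, {hi}]")


@dataclass(frozen=True)
class Catalogue:
    """CPP catalogue plus the ICD/histology rules defining each PSD group."""

    cpps: dict[str, CppDefinition]
    code_groups: dict[str, dict]  # group -> {"exact": [...], "prefixes": [...]}

    def __getitem__(self, cpp_id: str) -> CppDefinition:
        return self.cpps[cpp_id]

    def __iter__(self):
        return iter(self.cpps.values())

    def __len__(self) -> int:
        return len(self.cpps)

    @property
    def psd_groups(self) -> list[str]:
        """All distinct PSD groups, in catalogue order."""
        seen: list[str] = []
        for cpp in self.cpps.values():
            if cpp.psd_group is not None and cpp.psd_group not in seen:
                seen.append(cpp.psd_group)
        return seen


def load_catalogue(path: str | Path | None = None) -> Catalogue:
    """Load a CPP catalogue from YAML; the bundled default when *path* is None.

    The bundled catalogue covers the 28 pathways analysed in Swedish regional
    data for 2018.  Its ICD-prefix maps for most PSD groups are editable
    defaults: only the pancreatic / hepatobiliary / CUP rules are fixed by
    the registry coding practice, the rest are user-supplied conventions.
    """
    if path is None:
        text = (
            resources.files("cppflow").joinpath("data/cpp_catalogue.yaml").read_text()
        )
        raw = yaml.safe_load(text)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    cpps: dict[str, CppDefinition] = {}
    for entry in raw["cpps"]:
        cpp = CppDefinition(**entry)
        cpps[cpp.cpp_id] = cpp
    code_groups = raw.get("code_groups", {})
    cat = Catalogue(cpps=cpps, code_groups=code_groups)
    for cpp in cat:
        if cpp.psd_group is not None and cpp.psd_group not in code_groups:
            raise ValueError(f"{cpp.cpp_id}: psd_group {cpp.psd_group} has no code rules")
    return cat


# ---------------------------------------------------------------------------
# Diagnosis classification
# ---------------------------------------------------------------------------


def _normalize_code(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


def _behaviour_digit(histology_code: str | None) -> str | None:
    """Behaviour digit of an ICD-O morphology code ('8140/3' -> '3')."""
    if histology_code is None or "/" not in histology_code:
        return None
    return histology_code.rsplit("/", 1)[1][:1]


def classify_diagnosis(
    icd_code: str,
    histology_code: str | None,
    code_groups: Mapping[str, dict],
) -> str:
    """Map an (ICD code, morphology code) pair to a diagnosis group.

    Total and deterministic: exact-code rules win over prefix rules, longer
    prefixes over shorter ones, and anything unmatched — including benign
    tumours (morphology behaviour 0 or 1) — falls into ``OTHER``.
    """
    if not icd_code:
        raise ValueError("icd_code must be non-empty")
    if _behaviour_digit(histology_code) in ("0", "1"):
        return OTHER_GROUP
    code = _normalize_code(icd_code)
    best_group = OTHER_GROUP
    best_len = -1
    for group, rules in code_groups.items():
        for exact in rules.get("exact", ()):
            if code == _normalize_code(exact):
                return group
        for prefix in rules.get("prefixes", ()):
            p = _normalize_code(prefix)
            if code.startswith(p) and len(p) > best_len:
                best_group, best_len = group, len(p)
    return best_group


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

REFERRAL_COLUMNS = ["patient_id", "cpp_id", "wfs_date", "stop_date", "stop_code"]
CANCER_COLUMNS = ["patient_id", "diagnosis_date", "icd_code", "histology_code"]
PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "death_date"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _parse_dates(df: pd.DataFrame, column: str, path, required: bool) -> pd.Series:
    raw = df[column].astype("string")
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    blank = raw.isna() | (raw.str.strip() == "")
    bad = parsed.isna() & ~blank
    if required:
        bad |= blank
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 zero-based
        raise RowError(
            f"{path}: unparseable or missing {column} on line(s) {lines[:20]}"
        )
    return parsed


def read_referrals(path: str | Path) -> pd.DataFrame:
    """Read and validate a referral table.

    Returns a DataFrame with columns ``patient_id, cpp_id, wfs_date,
    stop_date, stop_code`` (dates as datetime64, stop fields nullable).
    Raises :class:`SchemaError` for missing columns and :class:`RowError`
    (with line numbers) for unknown stop codes, unparseable dates, stop dates
    before the WFS date, or a stop date/code present without the other.
    """
    df = pd.read_csv(path, dtype="string")
    _require_columns(df, REFERRAL_COLUMNS, path)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "cpp_id": df["cpp_id"],
            "wfs_date": _parse_dates(df, "wfs_date", path, required=True),
            "stop_date": _parse_dates(df, "stop_date", path, required=False),
        }
    )
    stop_code = df["stop_code"].astype("string")
    stop_code = stop_code.where(~(stop_code.isna() | (stop_code.str.strip() == "")))
    unknown = stop_code.notna() & ~stop_code.isin(STOP_CODES)
    if unknown.any():
        lines = (df.index[unknown] + 2).tolist()
        raise RowError(
            f"{path}: unknown stop_code on line(s) {lines[:20]}; "
            f"allowed codes: {', '.join(STOP_CODES)}"
        )
    out["stop_code"] = stop_code
    mismatch = out["stop_date"].isna() != out["stop_code"].isna()
    if mismatch.any():
        lines = (df.index[mismatch] + 2).tolist()
        raise RowError(
            f"{path}: stop_date and stop_code must be both present or both "
            f"absent; violated on line(s) {lines[:20]}"
        )
    backwards = out["stop_date"].notna() & (out["stop_date"] < out["wfs_date"])
    if backwards.any():
        lines = (df.index[backwards] + 2).tolist()
        raise RowError(f"{path}: stop_date before wfs_date on line(s) {lines[:20]}")
    return out


def read_cancer_register(
    path: str | Path, catalogue: Catalogue | None = None
) -> pd.DataFrame:
    """Read a cancer-register table and attach the derived diagnosis group.

    One row per registered tumour; patients may contribute several rows.
    ``diagnosis_group`` is populated via :func:`classify_diagnosis` using the
    catalogue's code rules (the bundled catalogue when none is given).
    """
    if catalogue is None:
        catalogue = load_catalogue()
    df = pd.read_csv(path, dtype="string")
    _require_columns(df, CANCER_COLUMNS, path)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "diagnosis_date": _parse_dates(df, "diagnosis_date", path, required=True),
            "icd_code": df["icd_code"],
            "histology_code": df["histology_code"],
        }
    )
    empty_icd = out["icd_code"].isna() | (out["icd_code"].str.strip() == "")
    if empty_icd.any():
        lines = (df.index[empty_icd] + 2).tolist()
        raise RowError(f"{path}: empty icd_code on line(s) {lines[:20]}")
    out["diagnosis_group"] = [
        classify_diagnosis(icd, None if pd.isna(hist) else str(hist), catalogue.code_groups)
        for icd, hist in zip(out["icd_code"], out["histology_code"])
    ]
    return out


def attach_diagnosis_groups(
    cancer: pd.DataFrame, catalogue: Catalogue
) -> pd.DataFrame:
    """Populate ``diagnosis_group`` on an in-memory cancer table."""
    out = cancer.copy()
    out["diagnosis_group"] = [
        classify_diagnosis(
            str(icd), None if pd.isna(hist) else str(hist), catalogue.code_groups
        )
        for icd, hist in zip(out["icd_code"], out["histology_code"])
    ]
    return out


def read_patients(path: str | Path) -> pd.DataFrame:
    """Read a patient-attribute table (sex, birth year, optional death date)."""
    df = pd.read_csv(path, dtype="string")
    _require_columns(df, PATIENT_COLUMNS, path)
    sex = df["sex"].str.lower()
    bad_sex = ~sex.isin(["male", "female"])
    if bad_sex.any():
        lines = (df.index[bad_sex] + 2).tolist()
        raise RowError(f"{path}: sex must be male/female; line(s) {lines[:20]}")
    birth_year = pd.to_numeric(df["birth_year"], errors="coerce")
    if birth_year.isna().any():
        lines = (df.index[birth_year.isna()] + 2).tolist()
        raise RowError(f"{path}: unparseable birth_year on line(s) {lines[:20]}")
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "sex": sex,
            "birth_year": birth_year.astype(int),
            "death_date": _parse_dates(df, "death_date", path, required=False),
        }
    )


# ---------------------------------------------------------------------------
# Cohort construction and linkage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study window and linkage parameters.

    ``diagnosis_lookback_days`` bounds how far before WFS a registered
    diagnosis may lie and still link to the episode (the register interval
    extends one month ahead of diagnosis, hence the default 31).  With
    ``prewfs_full_history`` the whole pre-WFS history is accepted instead
    for the diagnosed-before/after split.  ``post_wfs_window_days`` is the
    "within six months of WFS" window (183 days).
    """

    study_year: int
    censor_date: pd.Timestamp
    diagnosis_lookback_days: int = 31
    post_wfs_window_days: int = 183
    prewfs_full_history: bool = False

    def __post_init__(self) -> None:
        if self.diagnosis_lookback_days < 0 or self.post_wfs_window_days < 0:
            raise ValueError("linkage windows must be non-negative")
        censor = pd.Timestamp(self.censor_date)
        object.__setattr__(self, "censor_date", censor)
        if censor < pd.Timestamp(year=self.study_year, month=1, day=1):
            raise ValueError("censor_date must fall after the study year start")


def build_cohort(
    referrals: pd.DataFrame,
    patients: pd.DataFrame,
    config: CohortConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select the analysis cohort: adults with exactly one CPP episode.

    Retains referrals whose WFS date falls in the study year, whose patient
    is ≥ 18 at WFS, and whose patient has exactly one such referral.  Returns
    the retained referrals (joined with patient attributes) and an exclusion
    report whose buckets partition the input rows; patients with several
    episodes ongoing simultaneously are additionally counted in
    ``multi_cpp_overlapping_patients``.
    """
    known = set(patients["patient_id"])
    unknown = sorted(set(referrals["patient_id"]) - known)
    if unknown:
        raise LinkageError(
            f"referrals reference {len(unknown)} unknown patient id(s): "
            f"{unknown[:10]}"
        )
    df = referrals.merge(patients, on="patient_id", how="left", validate="m:1")

    in_year = df["wfs_date"].dt.year == config.study_year
    n_out_of_year = int((~in_year).sum())
    df = df[in_year]

    age_at_wfs = df["wfs_date"].dt.year - df["birth_year"]
    adult = age_at_wfs >= 18
    n_minor = int((~adult).sum())
    df = df[adult]

    counts = df["patient_id"].value_counts()
    multi_ids = set(counts[counts > 1].index)
    is_multi = df["patient_id"].isin(multi_ids)
    n_multi_rows = int(is_multi.sum())

    # overlap among a multi-episode patient's referrals: [wfs, stop or censor]
    n_overlap_patients = 0
    if multi_ids:
        multi = df[is_multi].copy()
        multi["end"] = multi["stop_date"].fillna(config.censor_date)
        for _, grp in multi.groupby("patient_id", sort=False):
            g = grp.sort_values("wfs_date")
            if (g["end"].shift() >= g["wfs_date"]).iloc[1:].any():
                n_overlap_patients += 1

    cohort = df[~is_multi].reset_index(drop=True)
    report = {
        "input_referrals": int(len(referrals)),
        "retained": int(len(cohort)),
        "wfs_outside_study_year": n_out_of_year,
        "minors": n_minor,
        "multi_cpp_referrals": n_multi_rows,
        "multi_cpp_patients": len(multi_ids),
        "multi_cpp_overlapping_patients": n_overlap_patients,
    }
    assert (
        report["retained"]
        + report["wfs_outside_study_year"]
        + report["minors"]
        + report["multi_cpp_referrals"]
        == report["input_referrals"]
    )
    return cohort, report


def link_diagnoses(
    cohort: pd.DataFrame,
    cancer: pd.DataFrame,
    catalogue: Catalogue,
    config: CohortConfig,
) -> pd.DataFrame:
    """Attach PSD and other-cancer register linkages to each cohort episode.

    For a CPP with a PSD group, the PSD linkage is the earliest register
    record in that group with diagnosis date in
    ``[wfs − lookback, wfs + post_wfs_window]`` (lookback unbounded when
    ``prewfs_full_history``); the other-cancer linkage is the earliest
    record in any other malignant group in the same window.  For CPPs
    without a PSD, every malignant group links as "other".  Absence of a
    linkage is a valid outcome.  ``dx_before_wfs`` is true when the PSD
    diagnosis strictly precedes the WFS date (a diagnosis on the WFS date
    counts as on-or-after).
    """
    out = cohort.copy()
    out["psd_dx_date"] = pd.NaT
    out["other_dx_date"] = pd.NaT

    merged = out[["patient_id", "cpp_id", "wfs_date"]].reset_index().merge(
        cancer[["patient_id", "diagnosis_date", "diagnosis_group"]],
        on="patient_id",
        how="inner",
    )
    if len(merged):
        psd_group = merged["cpp_id"].map(
            {c.cpp_id: c.psd_group for c in catalogue}
        )
        delta = (merged["diagnosis_date"] - merged["wfs_date"]).dt.days
        in_window = delta <= config.post_wfs_window_days
        if not config.prewfs_full_history:
            in_window &= delta >= -config.diagnosis_lookback_days
        merged = merged[in_window]
        psd_group = psd_group[in_window]

        is_psd = merged["diagnosis_group"] == psd_group
        is_other = (merged["diagnosis_group"] != OTHER_GROUP) & ~is_psd

        # earliest-date rule; ties broken by record order (warned)
        for mask, col in ((is_psd, "psd_dx_date"), (is_other, "other_dx_date")):
            sub = merged[mask]
            if not len(sub):
                continue
            ordered = sub.sort_values(
                ["index", "diagnosis_date"], kind="stable"
            )
            ties = ordered.duplicated(subset=["index", "diagnosis_date"], keep=False)
            firsts = ordered.drop_duplicates(subset="index", keep="first")
            if (ties & ~ordered.duplicated(subset="index", keep="first")).any():
                logger.warning(
                    "%d episode(s) had tied %s dates; first record kept",
                    int(ties[firsts.index].sum()),
                    "PSD" if col == "psd_dx_date" else "other-cancer",
                )
            out.loc[firsts["index"], col] = firsts["diagnosis_date"].values

    out["dx_before_wfs"] = out["psd_dx_date"].notna() & (
        out["psd_dx_date"] < out["wfs_date"]
    )
    return out
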