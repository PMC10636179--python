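"""Seeded synthetic registry generator.

Real CPP referral and cancer-register extracts are confidential, so every
downstream stage of the pipeline is exercised on synthetic tables with the
same statistical structure: per-CPP inclusion volumes, a fraction of
patients diagnosed before well-founded suspicion, competing time-to-event
outcomes (treatment start, suspicion rejected, other cancer, exclusion
codes, death), rare re-diagnosis after rejection, and administrative
censoring at the end of the study window.

The generative model, per patient:

1. A WFS date is drawn uniformly over the study year.
2. Each stop event has a piecewise-constant daily hazard; event days are
   sampled independently and the earliest wins (ties broken by a fixed
   priority: death > treatment > rejection > the remaining codes).  Stops
   after the administrative censor date (or beyond ``censor_after_days``)
   are unobserved — the episode remains open.
3. Diagnoses are assigned conditionally: with ``p_dx_before_wfs`` the PSD
   is registered 1–31 days before WFS; treated patients without a prior
   diagnosis carry the PSD with probability ``1 − p_treatment_without_dx``
   (diagnosis during the investigation via the ``psd_dx`` hazard when one
   is configured, otherwise on the treatment day); rejected patients are
   re-diagnosed late with the configured probabilities and a log-normal
   delay; an other-cancer stop registers a tumour in another group.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by the scenario, so a fixed seed reproduces the output files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import Catalogue, attach_diagnosis_groups, load_catalogue

#: Stop-event sampling priority on tied days (first wins).
STOP_EVENTS = (
    "treatment",
    "rejection",
    "other_cancer",
    "criteria_not_met",
    "patient_choice",
    "other_medical",
)
_STOP_CODE = {
    "treatment": "TREATMENT_START",
    "rejection": "SUSPICION_REJECTED",
    "other_cancer": "OTHER_CANCER",
    "criteria_not_met": "CRITERIA_NOT_MET",
    "patient_choice": "PATIENT_CHOICE",
    "other_medical": "OTHER_MEDICAL",
}

_FAR = 10**8  # sentinel for "event never happens"

#: Pool of "other cancer" codes spread over common groups; a CPP's own PSD
#: codes are filtered out at generation time.
DEFAULT_OTHER_CODES = (
    "C34.9",
    "C50.9",
    "C61.9",
    "C18.9",
    "C16.9",
    "C64.9",
    "C43.9",
    "C90.0",
)


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


Hazard = float | Sequence[tuple[int, float]]


def _check_hazard(name: str, hz: Hazard) -> None:
    if isinstance(hz, (int, float)):
        if not 0 <= hz <= 1:
            raise ScenarioError(f"hazard {name} must lie in [0, 1], got {hz}")
        return
    for dur, rate in hz:
        if dur <= 0 or not 0 <= rate <= 1:
            raise ScenarioError(f"hazard {name}: bad segment ({dur}, {rate})")


def _sample_days(rng: np.random.Generator, hz: Hazard, n: int) -> np.ndarray:
    """First event day (1-based) under a piecewise-constant daily hazard."""
    if isinstance(hz, (int, float)):
        if hz <= 0:
            return np.full(n, _FAR, dtype=np.int64)
        return rng.geometric(hz, n).astype(np.int64)
    days = np.full(n, _FAR, dtype=np.int64)
    pending = np.arange(n)
    offset = 0
    segments = list(hz)
    for i, (dur, rate) in enumerate(segments):
        if not len(pending):
            break
        last = i == len(segments) - 1
        if rate > 0:
            draw = rng.geometric(rate, len(pending)).astype(np.int64)
            hit = draw <= dur if not last else np.ones(len(pending), bool)
            days[pending[hit]] = offset + draw[hit]
            pending = pending[~hit]
        offset += dur
    return days


@dataclass(frozen=True)
class CppScenario:
    """Generative parameters for one CPP block.

    ``hazards`` maps event names (``psd_dx``, ``death`` and the six stop
    events ``treatment, rejection, other_cancer, criteria_not_met,
    patient_choice, other_medical``) to a constant daily hazard or a list
    of ``(duration_days, rate)`` segments.  Probability fields configure
    the conditional diagnosis assignment described in the module docstring.
    """

    cpp_id: str
    n_patients: int
    p_dx_before_wfs: float = 0.0
    hazards: Mapping[str, Hazard] = field(default_factory=dict)
    p_late_psd_after_rejection: float = 0.0
    p_late_other_after_rejection: float = 0.0
    late_delay_median_days: float = 60.0
    late_delay_sigma: float = 0.5
    p_treatment_without_dx: float = 0.0
    p_dx_if_censored: float = 0.0
    p_late_cancer_after_criteria_not_met: float = 0.0
    censor_after_days: int = 400
    p_female: float = 0.5
    age_mean: float = 66.0
    age_sd: float = 13.0
    other_icd_codes: tuple[str, ...] = ()  # empty = default pool
    background_cancer_rate: float = 0.0  # diagnosed patients never referred

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ScenarioError(f"{self.cpp_id}: n_patients must be >= 0")
        for name in (
            "p_dx_before_wfs",
            "p_late_psd_after_rejection",
            "p_late_other_after_rejection",
            "p_treatment_without_dx",
            "p_dx_if_censored",
            "p_late_cancer_after_criteria_not_met",
            "p_female",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ScenarioError(f"{self.cpp_id}: {name}={v} outside [0, 1]")
        if self.p_late_psd_after_rejection + self.p_late_other_after_rejection > 1:
            raise ScenarioError(
                f"{self.cpp_id}: late re-diagnosis branch probabilities exceed 1"
            )
        for name, hz in self.hazards.items():
            _check_hazard(f"{self.cpp_id}.{name}", hz)
        if self.censor_after_days < 0:
            raise ScenarioError(f"{self.cpp_id}: censor_after_days must be >= 0")
        if self.background_cancer_rate < 0:
            raise ScenarioError(f"{self.cpp_id}: background_cancer_rate must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """A full synthetic study: CPP blocks plus the shared study window."""

    cpps: tuple[CppScenario, ...]
    study_year: int = 2018
    censor_date: str = "2018-12-31"
    seed: int = 0
    multi_cpp_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.multi_cpp_rate <= 1:
            raise ScenarioError("multi_cpp_rate outside [0, 1]")
        object.__setattr__(self, "cpps", tuple(self.cpps))


def representative_code(group: str, code_groups: Mapping[str, dict]) -> str:
    """An ICD code that classifies into *group* under the catalogue rules."""
    rules = code_groups[group]
    if rules.get("exact"):
        return rules["exact"][0]
    prefix = rules["prefixes"][0]
    return f"{prefix}.9" if "." not in prefix else prefix


def stop_hazards_from_shares(
    shares: Mapping[str, float], mean_stop_days: float
) -> dict[str, Hazard]:
    """Proportional truncated hazards hitting given unconditional shares.

    Event *e* gets the constant daily hazard ``(share_e / S) / mean_stop_days``
    (S = sum of shares) over a risk window of D days, zero after, with D
    chosen so the probability of stopping at all equals S.  Under complete
    follow-up the unconditional probability of each stop type then equals
    its share exactly, and the remaining ``1 − S`` of episodes stay under
    investigation.
    """
    if any(v < 0 for v in shares.values()):
        raise ScenarioError("shares must be non-negative")
    S = sum(shares.values())
    if S <= 0:
        return {}
    if S > 0.999:
        raise ScenarioError("stop-type shares must sum below 1")
    H = 1.0 / mean_stop_days
    D = int(np.ceil(np.log(1.0 - S) / np.log(1.0 - H)))
    return {
        e: [(D, (v / S) * H), (1, 0.0)] for e, v in shares.items() if v > 0
    }


def _generate_block(
    rng: np.random.Generator,
    cpp: CppScenario,
    catalogue: Catalogue,
    study_year: int,
    censor_date: pd.Timestamp,
    id_prefix: str,
):
    n = cpp.n_patients
    year_start = pd.Timestamp(year=study_year, month=1, day=1)
    year_days = (pd.Timestamp(year=study_year, month=12, day=31) - year_start).days + 1
    wfs_offsets = rng.integers(0, year_days, n)
    wfs = year_start + pd.to_timedelta(wfs_offsets, unit="D")
    follow_admin = (censor_date - wfs).days.to_numpy()
    follow = np.minimum(follow_admin, cpp.censor_after_days)

    # competing stop events (priority order) and death
    event_days = np.stack(
        [_sample_days(rng, cpp.hazards.get(e, 0.0), n) for e in STOP_EVENTS]
    )
    stop_idx = event_days.argmin(axis=0)
    stop_day = event_days.min(axis=0)
    death_day = _sample_days(rng, cpp.hazards.get("death", 0.0), n)

    died_first = death_day <= stop_day
    stopped = (~died_first) & (stop_day <= follow)
    stop_code = np.array([_STOP_CODE[STOP_EVENTS[i]] for i in stop_idx], dtype=object)

    has_psd = catalogue[cpp.cpp_id].has_psd if cpp.cpp_id in catalogue.cpps else True
    psd_group = (
        catalogue[cpp.cpp_id].psd_group if cpp.cpp_id in catalogue.cpps else None
    )

    # diagnosis assignment (days relative to WFS; None = no record)
    psd_dx_day = np.full(n, _FAR, dtype=np.int64)
    other_dx_day = np.full(n, _FAR, dtype=np.int64)

    u_pre = rng.random(n)
    pre_lag = rng.integers(1, 32, n)
    u_cancer = rng.random(n)
    dx_hazard_day = _sample_days(rng, cpp.hazards.get("psd_dx", 0.0), n)
    u_late = rng.random(n)
    late_delay = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(cpp.late_delay_median_days), cpp.late_delay_sigma, n)
        ).astype(np.int64),
    )
    u_cnm = rng.random(n)
    cnm_delay = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(cpp.late_delay_median_days), cpp.late_delay_sigma, n)
        ).astype(np.int64),
    )

    if has_psd and psd_group is not None:
        pre = u_pre < cpp.p_dx_before_wfs
        psd_dx_day[pre] = -pre_lag[pre]

        treated = stopped & (stop_code == "TREATMENT_START") & ~pre
        carrier = treated & (u_cancer < 1.0 - cpp.p_treatment_without_dx)
        psd_dx_day[carrier] = np.minimum(dx_hazard_day, stop_day)[carrier]

        open_inv = ~stopped & ~died_first & ~pre
        cens_carrier = open_inv & (u_cancer < cpp.p_dx_if_censored)
        cens_dx = cens_carrier & (dx_hazard_day <= follow)
        psd_dx_day[cens_dx] = dx_hazard_day[cens_dx]

        rejected = stopped & (stop_code == "SUSPICION_REJECTED") & ~pre
        late_psd = rejected & (u_late < cpp.p_late_psd_after_rejection)
        late_other = (
            rejected
            & ~late_psd
            & (
                u_late
                < cpp.p_late_psd_after_rejection + cpp.p_late_other_after_rejection
            )
        )
        psd_dx_day[late_psd] = (stop_day + late_delay)[late_psd]
        other_dx_day[late_other] = (stop_day + late_delay)[late_other]
    else:
        rejected = stopped & (stop_code == "SUSPICION_REJECTED")
        late_other = rejected & (
            u_late
            < cpp.p_late_psd_after_rejection + cpp.p_late_other_after_rejection
        )
        other_dx_day[late_other] = (stop_day + late_delay)[late_other]

    other_stop = stopped & (stop_code == "OTHER_CANCER")
    other_dx_day[other_stop] = stop_day[other_stop]

    cnm = stopped & (stop_code == "CRITERIA_NOT_MET")
    cnm_late = cnm & (u_cnm < cpp.p_late_cancer_after_criteria_not_met)
    other_dx_day[cnm_late] = (stop_day + cnm_delay)[cnm_late]

    # assemble tables
    pid = np.array([f"{id_prefix}{i:06d}" for i in range(n)], dtype=object)
    referrals = pd.DataFrame(
        {
            "patient_id": pid,
            "cpp_id": cpp.cpp_id,
            "wfs_date": wfs,
            "stop_date": pd.Series(
                np.where(
                    stopped,
                    wfs + pd.to_timedelta(np.where(stopped, stop_day, 0), unit="D"),
                    pd.NaT,
                )
            ),
            "stop_code": np.where(stopped, stop_code, None),
        }
    )
    referrals.loc[~stopped, "stop_date"] = pd.NaT

    sex = np.where(rng.random(n) < cpp.p_female, "female", "male")
    age = np.clip(np.round(rng.normal(cpp.age_mean, cpp.age_sd, n)), 18, 94).astype(int)
    death_date = pd.Series(pd.NaT, index=range(n))
    death_obs = death_day <= follow_admin
    death_date[death_obs] = (
        wfs + pd.to_timedelta(np.where(death_obs, death_day, 0), unit="D")
    )[death_obs]
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "birth_year": study_year - age,
            "death_date": death_date,
        }
    )

    cancer_rows = []
    code_groups = catalogue.code_groups
    psd_code = (
        representative_code(psd_group, code_groups) if psd_group is not None else None
    )
    from .registry import classify_diagnosis

    pool = cpp.other_icd_codes or DEFAULT_OTHER_CODES
    other_codes = tuple(
        c for c in pool if classify_diagnosis(c, None, code_groups) != psd_group
    ) or pool
    oc_idx = rng.integers(0, len(other_codes), n)
    for i in range(n):
        if psd_dx_day[i] < _FAR:
            date = wfs[i] + pd.Timedelta(days=int(psd_dx_day[i]))
            if date <= censor_date:
                cancer_rows.append((pid[i], date, psd_code, "8140/3"))
        if other_dx_day[i] < _FAR:
            date = wfs[i] + pd.Timedelta(days=int(other_dx_day[i]))
            if date <= censor_date:
                cancer_rows.append((pid[i], date, other_codes[oc_idx[i]], "8140/3"))
    # background: patients diagnosed with the PSD but never referred to the
    # CPP — these dilute the inclusion-target proportion below 100%
    n_bg = int(round(cpp.background_cancer_rate * n))
    if n_bg and psd_code is not None:
        bg_pid = np.array([f"{id_prefix}B{i:06d}" for i in range(n_bg)], dtype=object)
        bg_offsets = rng.integers(0, year_days, n_bg)
        bg_dates = year_start + pd.to_timedelta(bg_offsets, unit="D")
        bg_sex = np.where(rng.random(n_bg) < cpp.p_female, "female", "male")
        bg_age = np.clip(
            np.round(rng.normal(cpp.age_mean, cpp.age_sd, n_bg)), 18, 94
        ).astype(int)
        patients = pd.concat(
            [
                patients,
                pd.DataFrame(
                    {
                        "patient_id": bg_pid,
                        "sex": bg_sex,
                        "birth_year": study_year - bg_age,
                        "death_date": pd.NaT,
                    }
                ),
            ],
            ignore_index=True,
        )
        for i in range(n_bg):
            if bg_dates[i] <= censor_date:
                cancer_rows.append((bg_pid[i], bg_dates[i], psd_code, "8140/3"))

    cancer = pd.DataFrame(
        cancer_rows, columns=["patient_id", "diagnosis_date", "icd_code", "histology_code"]
    )
    return referrals, cancer, patients


def generate(
    scenario: ScenarioConfig, catalogue: Catalogue | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (referrals, cancer register, patients) for a scenario.

    Output is deterministic for a fixed ``scenario.seed``.  With a positive
    ``multi_cpp_rate``, that fraction of patients receives an additional
    open referral in another CPP two weeks after their first, exercising the
    cohort's multi-CPP exclusion logic.
    """
    if catalogue is None:
        catalogue = load_catalogue()
    rng = np.random.default_rng(scenario.seed)
    censor = pd.Timestamp(scenario.censor_date)
    ref_parts, cancer_parts, patient_parts = [], [], []
    for bi, cpp in enumerate(scenario.cpps):
        r, c, p = _generate_block(
            rng, cpp, catalogue, scenario.study_year, censor, f"P{bi:02d}_"
        )
        ref_parts.append(r)
        cancer_parts.append(c)
        patient_parts.append(p)
    referrals = pd.concat(ref_parts, ignore_index=True)
    cancer = pd.concat(cancer_parts, ignore_index=True)
    patients = pd.concat(patient_parts, ignore_index=True)

    if scenario.multi_cpp_rate > 0 and len(scenario.cpps) > 1 and len(referrals):
        n_extra = int(np.floor(scenario.multi_cpp_rate * len(referrals)))
        if n_extra:
            pick = rng.choice(len(referrals), size=n_extra, replace=False)
            cpp_ids = [c.cpp_id for c in scenario.cpps]
            extra = referrals.iloc[pick].copy()
            shifted = [
                cpp_ids[(cpp_ids.index(c) + 1) % len(cpp_ids)] for c in extra["cpp_id"]
            ]
            extra["cpp_id"] = shifted
            year_end = pd.Timestamp(year=scenario.study_year, month=12, day=31)
            extra["wfs_date"] = (extra["wfs_date"] + pd.Timedelta(days=14)).clip(
                upper=year_end
            )
            extra["stop_date"] = pd.NaT
            extra["stop_code"] = None
            referrals = pd.concat([referrals, extra], ignore_index=True)

    referrals["stop_date"] = pd.to_datetime(referrals["stop_date"])
    cancer = attach_diagnosis_groups(cancer, catalogue)
    return referrals, cancer, patients


def write_files(
    scenario: ScenarioConfig,
    out_dir: str | Path,
    catalogue: Catalogue | None = None,
) -> dict[str, Path]:
    """Generate a scenario and write the three CSV tables (ISO dates)."""
    referrals, cancer, patients = generate(scenario, catalogue)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, datecols in (
        ("referrals", referrals, ["wfs_date", "stop_date"]),
        ("cancer", cancer.drop(columns="diagnosis_group"), ["diagnosis_date"]),
        ("patients", patients, ["death_date"]),
    ):
        frame = df.copy()
        for col in datecols:
            frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    """Load a :class:`ScenarioConfig` from a YAML file.

    Layout: top-level ``study_year``, ``censor_date``, ``seed``,
    ``multi_cpp_rate`` plus a ``cpps`` list of :class:`CppScenario` field
    mappings (hazards as ``{event: rate}`` or ``{event: [[days, rate], ...]}``).
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    blocks = []
    for entry in raw.pop("cpps"):
        hazards = {
            k: v if isinstance(v, (int, float)) else [tuple(seg) for seg in v]
            for k, v in entry.pop("hazards", {}).items()
        }
        if "other_icd_codes" in entry:
            entry["other_icd_codes"] = tuple(entry["other_icd_codes"])
        blocks.append(CppScenario(hazards=hazards, **entry))
    return ScenarioConfig(cpps=tuple(blocks), **raw)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def cpp_scenario_from_shares(
    cpp_id: str,
    n_patients: int,
    rejected_pct: float,
    dx_after_pct: float,
    psd_pct: float | None,
    late_psd_pct_of_rejected: float = 0.0,
    late_other_pct_of_rejected: float = 0.0,
    cnm_pct: float = 0.0,
    p_dx_before_wfs: float = 0.15,
    p_treatment_without_dx: float = 0.08,
    mean_stop_days: float = 30.0,
    **overrides,
) -> CppScenario:
    """Back-solve a CPP block from observed outcome shares (% of episodes).

    Inverts the generative model's share algebra under complete follow-up:
    the rejection/criteria-not-met/other-cancer stop shares map directly to
    proportional hazards, the treated share is solved so that the PSD
    diagnosed-on/after-WFS share comes out at ``psd_pct`` given the pre-WFS
    and treated-without-diagnosis fractions, and the late re-diagnosis
    branches use their printed per-rejected percentages.
    """
    p_rej = rejected_pct / 100.0
    p_cnm = cnm_pct / 100.0
    late_psd = late_psd_pct_of_rejected / 100.0
    late_other = late_other_pct_of_rejected / 100.0
    if psd_pct is None:
        p_treat = max(0.0, 1.0 - p_rej - p_cnm - 0.25)
        p_other = max(0.0, dx_after_pct / 100.0 - p_rej * late_other)
        p_before, p_tnd = 0.0, 1.0
    else:
        p_before = p_dx_before_wfs
        p_tnd = p_treatment_without_dx
        psd_from_treated = max(0.0, psd_pct / 100.0 - p_rej * late_psd)
        denom = (1.0 - p_before) * (1.0 - p_tnd)
        p_treat = psd_from_treated / denom if denom > 0 else 0.0
        p_other = max(
            0.0, (dx_after_pct - psd_pct) / 100.0 - p_rej * late_other
        )
    p_choice = overrides.pop("p_patient_choice", 0.03)
    p_medical = overrides.pop("p_other_medical", 0.04)
    total = p_rej + p_treat + p_other + p_cnm + p_choice + p_medical
    if total > 0.995:  # leave a sliver for still-under-investigation
        scale = 0.995 / total
        p_rej, p_treat, p_other, p_cnm, p_choice, p_medical = (
            x * scale for x in (p_rej, p_treat, p_other, p_cnm, p_choice, p_medical)
        )
    hazards = stop_hazards_from_shares(
        {
            "treatment": p_treat,
            "rejection": p_rej,
            "other_cancer": p_other,
            "criteria_not_met": p_cnm,
            "patient_choice": p_choice,
            "other_medical": p_medical,
        },
        mean_stop_days,
    )
    hazards["death"] = overrides.pop("death_hazard", 5e-5)
    psd_dx_hazard = overrides.pop("psd_dx_hazard", 0.0)
    if psd_dx_hazard:
        hazards["psd_dx"] = psd_dx_hazard
    return CppScenario(
        cpp_id=cpp_id,
        n_patients=n_patients,
        p_dx_before_wfs=p_before if psd_pct is not None else 0.0,
        hazards=hazards,
        p_late_psd_after_rejection=late_psd,
        p_late_other_after_rejection=late_other,
        p_treatment_without_dx=p_tnd if psd_pct is not None else 1.0,
        **overrides,
    )


def preset_scenarios(seed: int = 0) -> dict[str, ScenarioConfig]:
    """Named single-CPP archetype scenarios plus a pooled 28-CPP study.

    * ``filter_fast`` — breast-like: filter function, quick diagnosis
      (mean < 10 days), a third of patients already diagnosed at WFS.
    * ``high_rejection`` — urothelial-like: generous inclusion, most
      suspicions rejected.
    * ``treat_no_dx`` — thyroid-like: most patients treated, the majority
      without a registered diagnosis.
    * ``no_psd`` — CUP-like: no primarily suspected diagnosis, cancers
      surface as "other cancer".
    * ``colorectal_2018`` — calibrated to the published 2018 colorectal
      outcome shares (19% diagnosed on/after WFS, 58% rejected) at the
      published volume, with complete follow-up.
    * ``pooled_2018`` — all 28 CPPs at published-like volumes and shares
      with administrative censoring at the study-year end.
    """
    long_censor = {"censor_date": "2019-12-31"}
    breast = CppScenario(
        cpp_id="breast",
        n_patients=2512,
        p_dx_before_wfs=0.35,
        hazards={
            "treatment": 0.45 / 43.0,
            "rejection": 0.50 / 43.0,
            "other_cancer": 0.005 / 43.0,
            "criteria_not_met": 0.01 / 43.0,
            "patient_choice": 0.015 / 43.0,
            "other_medical": 0.02 / 43.0,
            "psd_dx": 1.0 / 7.0,
            "death": 5e-5,
        },
        p_late_psd_after_rejection=0.002,
        p_late_other_after_rejection=0.005,
        p_treatment_without_dx=0.02,
        p_female=0.99,
        age_mean=63,
    )
    urothelial = cpp_scenario_from_shares(
        "urothelial",
        2550,
        rejected_pct=73,
        dx_after_pct=12,
        psd_pct=11,
        late_psd_pct_of_rejected=0.3,
        late_other_pct_of_rejected=1.5,
        cnm_pct=0.2,
        p_dx_before_wfs=0.02,
        p_treatment_without_dx=0.13,
        mean_stop_days=45.0,
        p_female=0.3,
        age_mean=72,
    )
    thyroid = CppScenario(
        cpp_id="thyroid",
        n_patients=114,
        p_dx_before_wfs=0.10,
        hazards={
            "treatment": 0.84 / 40.0,
            "rejection": 0.018 / 40.0,
            "criteria_not_met": 0.01 / 40.0,
            "patient_choice": 0.04 / 40.0,
            "other_medical": 0.05 / 40.0,
            "death": 2e-5,
        },
        p_treatment_without_dx=0.63,
        p_female=0.75,
        age_mean=52,
    )
    cup = CppScenario(
        cpp_id="cup",
        n_patients=220,
        hazards={
            "rejection": 0.33 / 40.0,
            "other_cancer": 0.25 / 40.0,
            "treatment": 0.0,
            "criteria_not_met": 0.02 / 40.0,
            "patient_choice": 0.03 / 40.0,
            "other_medical": 0.25 / 40.0,
            "death": 1e-3,
        },
        p_late_other_after_rejection=0.069,
        p_treatment_without_dx=1.0,
        age_mean=74,
        other_icd_codes=("C80.9", "C50.9", "C34.9", "C7A.9", "C61.9", "C18.9"),
    )
    colorectal = cpp_scenario_from_shares(
        "colorectal",
        3278,
        rejected_pct=58,
        dx_after_pct=19,
        psd_pct=16,
        late_psd_pct_of_rejected=0.1,
        late_other_pct_of_rejected=1.7,
        cnm_pct=1.2,
        p_dx_before_wfs=0.18,
        p_treatment_without_dx=0.08,
        mean_stop_days=28.0,
        age_mean=70,
    )

    presets = {
        "filter_fast": ScenarioConfig(cpps=(breast,), seed=seed, **long_censor),
        "high_rejection": ScenarioConfig(cpps=(urothelial,), seed=seed, **long_censor),
        "treat_no_dx": ScenarioConfig(cpps=(thyroid,), seed=seed, **long_censor),
        "no_psd": ScenarioConfig(cpps=(cup,), seed=seed, **long_censor),
        "colorectal_2018": ScenarioConfig(cpps=(colorectal,), seed=seed, **long_censor),
        "pooled_2018": pooled_2018(seed=seed),
    }
    return presets


#: Published-like 2018 per-CPP volumes and outcome shares used by the pooled
#: preset: (n, rejected %, any dx on/after WFS %, PSD % or None,
#: late PSD % of rejected, late other % of rejected, criteria-not-met %).
_POOLED_SHARES: dict[str, tuple] = {
    "colorectal": (3278, 58, 19, 16, 0.1, 1.7, 1),
    "urothelial": (2550, 73, 12, 11, 0.3, 1.5, 0),
    "breast": (2512, 52, 40, 40, 0.2, 0.5, 1),
    "prostate": (2155, 53, 26, 24, 1.4, 2.4, 1),
    "melanoma": (1668, 29, 37, 31, 0.2, 2.7, 7),
    "lung": (944, 28, 17, 14, 1.1, 1.9, 1),
    "head_neck": (678, 54, 23, 16, 0.0, 1.9, 0),
    "uterine": (347, 43, 25, 19, 1.4, 0.7, 3),
    "nonspecific": (289, 77, 9, None, 0.0, 2.3, 3),
    "pancreatic": (249, 15, 37, 26, 0.0, 5.4, 3),
    "kidney": (231, 24, 15, 12, 1.8, 3.6, 0),
    "lymphoma": (221, 15, 29, 14, 0.0, 2.9, 8),
    "cup": (220, 33, 25, None, 0.0, 6.9, 2),
    "oesophageal_stomach": (191, 16, 64, 58, 0.0, 0.0, 2),
    "brain": (145, 17, 46, 38, 0.0, 4.0, 9),
    "bone_soft_sarcoma": (124, 79, 6, 4, 0.0, 0.0, 1),
    "testicular": (118, 58, 36, 35, 0.0, 0.0, 0),
    "thyroid": (114, 2, 21, 19, 0.0, 0.0, 1),
    "cervix": (95, 19, 24, 20, 0.0, 0.0, 1),
    "liver": (92, 16, 23, 20, 0.0, 6.7, 3),
    "myeloma": (88, 18, 48, 43, 0.0, 6.2, 14),
    "hepatobiliary": (80, 31, 13, 10, 4.0, 0.0, 3),
    "anal": (55, 38, 16, 15, 0.0, 0.0, 7),
    "penile": (48, 54, 19, 19, 0.0, 0.0, 0),
    "vulvar": (42, 24, 14, 12, 0.0, 0.0, 7),
    "acute_leukaemia": (34, 6, 74, 68, 0.0, 50.0, 0),
    "abdominal_sarcoma": (19, 5, 37, 26, 0.0, 0.0, 0),
    "neuroendocrine": (9, 11, 33, 22, 0.0, 0.0, 0),
}

#: Per-CPP overrides where archetypes are known: fraction diagnosed before
#: WFS, fraction of treated lacking a registered diagnosis, and sex mix.
_POOLED_OVERRIDES: dict[str, dict] = {
    "breast": {"p_dx_before_wfs": 0.35, "p_female": 0.99, "psd_dx_hazard": 1 / 7},
    "urothelial": {"p_dx_before_wfs": 0.02, "p_treatment_without_dx": 0.13, "p_female": 0.3},
    "kidney": {"p_dx_before_wfs": 0.42, "p_treatment_without_dx": 0.25},
    "thyroid": {"p_dx_before_wfs": 0.10, "p_treatment_without_dx": 0.63, "p_female": 0.75},
    "prostate": {"p_female": 0.0},
    "testicular": {"p_female": 0.0, "age_mean": 38},
    "penile": {"p_female": 0.0},
    "uterine": {"p_female": 1.0},
    "cervix": {"p_female": 1.0, "age_mean": 50},
    "vulvar": {"p_female": 1.0},
    "melanoma": {"age_mean": 62},
    "cup": {
        "other_icd_codes": ("C80.9", "C50.9", "C34.9", "C7A.9", "C61.9", "C18.9"),
    },
}


def pooled_2018(seed: int = 0, scale: float = 1.0) -> ScenarioConfig:
    """All 28 CPPs at published-like 2018 volumes and outcome shares.

    *scale* shrinks every block's patient count (floor, minimum 1) for
    quick smoke runs.  Administrative censoring follows the study design:
    episodes open at the year end stay under investigation.
    """
    from .datasets import regional_2018_inclusion

    incl = regional_2018_inclusion()
    cpps = []
    for cpp_id, (n, rej, dx, psd, lp, lo, cnm) in _POOLED_SHARES.items():
        overrides = dict(_POOLED_OVERRIDES.get(cpp_id, {}))
        group = cpp_id.upper()
        if psd is not None and group in incl.index:
            # published inclusion proportion -> never-referred background rate
            p_incl = incl.loc[group, "n_in_cpp"] / incl.loc[group, "n_patients"]
            dx_share = overrides.get("p_dx_before_wfs", 0.15) + psd / 100.0
            overrides.setdefault(
                "background_cancer_rate", dx_share * (1.0 / p_incl - 1.0)
            )
        cpps.append(
            cpp_scenario_from_shares(
                cpp_id,
                max(1, int(n * scale)),
                rejected_pct=rej,
                dx_after_pct=dx,
                psd_pct=psd,
                late_psd_pct_of_rejected=lp,
                late_other_pct_of_rejected=lo,
                cnm_pct=cnm,
                **overrides,
            )
        )
    return ScenarioConfig(
        cpps=tuple(cpps),
        study_year=2018,
        censor_date="2018-12-31",
        seed=seed,
        multi_cpp_rate=0.0,
    )
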