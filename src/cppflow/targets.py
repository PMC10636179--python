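"""National CPP target evaluation and excess investigation time.

Two targets are evaluated:

* **Inclusion target** — at least 70% of patients diagnosed with a CPP's
  primarily suspected diagnosis (PSD) should have been investigated through
  that CPP.
* **Lead-time target** — at least 80% of included patients should end their
  investigation (treatment start or any other stop) within the CPP's
  recommended lead time.  Lead times vary by treatment modality; lacking
  modality data the evaluation conservatively uses each CPP's longest lead
  time.

For CPPs failing the lead-time target, observed investigation times are
linearly rescaled by the smallest factor that makes 80% of them fall within
the lead time; the gap between observed and rescaled mean times is the
*excess investigation time* attributable to missing the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import Catalogue, CohortConfig
from .states import StateTrajectory, round_half_up

INCLUSION_THRESHOLD = 70.0  # percent
LEAD_TIME_THRESHOLD = 0.8  # proportion


def investigation_time(referral) -> float | None:
    """Days from well-founded suspicion to investigation end, or None.

    Any stop code counts as the end of investigation; an episode without a
    stop date is still under investigation (censored) and returns ``None``.
    """
    get = referral.get if hasattr(referral, "get") else lambda k, d=None: getattr(referral, k, d)
    stop = get("stop_date")
    if stop is None or pd.isna(stop):
        return None
    return int((pd.Timestamp(stop) - pd.Timestamp(get("wfs_date"))).days)


def investigation_times(referrals: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`investigation_time` over a referral table (NaN = censored)."""
    return (referrals["stop_date"] - referrals["wfs_date"]).dt.days


# ---------------------------------------------------------------------------
# Inclusion target
# ---------------------------------------------------------------------------


def inclusion_target(
    cancer: pd.DataFrame,
    referrals: pd.DataFrame,
    catalogue: Catalogue,
    config: CohortConfig | None = None,
    threshold: float = INCLUSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-PSD-group inclusion target table.

    For each of the catalogue's PSD groups: the number of registered
    diagnoses, of distinct diagnosed patients, and of those patients with
    any referral to the corresponding CPP in the study window (the full
    referral table, before the exactly-one-CPP cohort filter).  The
    ``met`` flag compares the unrounded proportion against *threshold*;
    the printed proportion is rounded half-up to integer percent.
    """
    refs = referrals
    if config is not None:
        refs = refs[refs["wfs_date"].dt.year == config.study_year]
    group_to_cpp = {
        c.psd_group: c.cpp_id for c in catalogue if c.psd_group is not None
    }
    rows = []
    for group in catalogue.psd_groups:
        sub = cancer[cancer["diagnosis_group"] == group]
        n_dx = len(sub)
        patients = set(sub["patient_id"])
        cpp_id = group_to_cpp[group]
        in_cpp = set(refs.loc[refs["cpp_id"] == cpp_id, "patient_id"]) & patients
        prop = 100.0 * len(in_cpp) / len(patients) if patients else float("nan")
        rows.append(
            {
                "diagnosis_group": group,
                "cpp_id": cpp_id,
                "n_diagnoses": n_dx,
                "n_patients": len(patients),
                "n_in_cpp": len(in_cpp),
                "proportion_pct": round_half_up(prop) if patients else float("nan"),
                "met": bool(prop >= threshold) if patients else False,
            }
        )
    table = pd.DataFrame(rows).set_index("diagnosis_group")
    return table.sort_values("n_diagnoses", ascending=False)


def inclusion_target_from_counts(
    counts: pd.DataFrame, threshold: float = INCLUSION_THRESHOLD
) -> pd.DataFrame:
    """Apply the inclusion rule to pre-aggregated (n_patients, n_in_cpp) counts.

    Useful for published summary tables where patient-level data are not
    available.  Adds ``proportion_pct`` (half-up integer percent) and
    ``met`` (unrounded proportion ≥ *threshold*).
    """
    out = counts.copy()
    prop = 100.0 * out["n_in_cpp"] / out["n_patients"]
    out["proportion_pct"] = prop.map(lambda p: round_half_up(p) if np.isfinite(p) else p)
    out["met"] = prop >= threshold
    return out


# ---------------------------------------------------------------------------
# Lead-time target
# ---------------------------------------------------------------------------


def lead_time_target(
    trajectories: Sequence[StateTrajectory],
    catalogue: Catalogue,
    threshold: float = LEAD_TIME_THRESHOLD,
    censored_as_failure: bool = False,
) -> pd.DataFrame:
    """Per-CPP lead-time target table (CPPs without lead times excluded).

    ``proportion_within_pct`` is the share of completed investigations
    ending within the CPP's longest lead time; censored episodes are
    excluded from the denominator unless *censored_as_failure*.  ``met``
    compares the unrounded share against *threshold*.
    """
    by_cpp: dict[str, list[StateTrajectory]] = {}
    for t in trajectories:
        by_cpp.setdefault(t.cpp_id, []).append(t)
    rows = []
    for cpp in catalogue:
        if cpp.lead_time_max_days is None:
            continue
        trajs = by_cpp.get(cpp.cpp_id, [])
        times = [t.stop_day for t in trajs if t.stop_day is not None]
        n_censored = sum(1 for t in trajs if t.stop_day is None)
        n_eval = len(times) + (n_censored if censored_as_failure else 0)
        if n_eval:
            within = sum(1 for d in times if d <= cpp.lead_time_max_days)
            prop = within / n_eval
        else:
            prop = float("nan")
        rows.append(
            {
                "cpp_id": cpp.cpp_id,
                "lead_time_min_days": cpp.lead_time_min_days,
                "lead_time_used_days": cpp.lead_time_max_days,
                "n_evaluable": n_eval,
                "n_censored": n_censored,
                "proportion_within_pct": round_half_up(100 * prop)
                if n_eval
                else float("nan"),
                "met": bool(prop >= threshold) if n_eval else False,
            }
        )
    return pd.DataFrame(rows).set_index("cpp_id")


def lead_time_target_from_proportions(
    proportions: pd.Series | Mapping[str, float],
    threshold: float = LEAD_TIME_THRESHOLD,
) -> pd.Series:
    """Met flags for pre-aggregated per-CPP within-lead-time percentages."""
    s = pd.Series(proportions, dtype=float)
    return s >= 100.0 * threshold


# ---------------------------------------------------------------------------
# Rescaling and excess time
# ---------------------------------------------------------------------------


def rescale_times(
    times: Sequence[float], lead_time: float, target: float = LEAD_TIME_THRESHOLD
) -> tuple[float, np.ndarray]:
    """Linearly rescale investigation times to just meet the lead-time target.

    If the share of *times* within *lead_time* already reaches *target*, the
    scale factor is 1 and the times are unchanged.  Otherwise the factor is
    ``lead_time / Q`` where Q is the empirical *target*-quantile (inverse
    CDF, no interpolation): the smallest observed time t with
    ``share(times <= t) >= target``.  The rescaled times then satisfy the
    target by construction.
    """
    arr = np.asarray(list(times), dtype=float)
    if arr.size == 0:
        raise ValueError("times must be non-empty")
    if lead_time <= 0:
        raise ValueError("lead_time must be positive")
    if np.mean(arr <= lead_time) >= target:
        return 1.0, arr.copy()
    srt = np.sort(arr)
    k = int(np.ceil(target * arr.size))
    q = srt[k - 1]
    scale = float(lead_time / q)
    return scale, scale * arr


@dataclass(frozen=True)
class ExcessSummary:
    """Excess-time table plus the most-used failing CPPs and their share."""

    table: pd.DataFrame
    top_cpps: list[str]
    top_share_of_total_excess: float


def excess_summary(
    times_by_cpp: Mapping[str, Sequence[float]],
    catalogue: Catalogue,
    k: int = 10,
    target: float = LEAD_TIME_THRESHOLD,
) -> ExcessSummary:
    """Observed vs rescaled mean investigation time per CPP.

    Per CPP with a specified lead time and at least one completed
    investigation: the observed mean, the mean after rescaling to meet the
    lead-time target, the per-patient and total excess days
    (``n · (mean_observed − mean_rescaled)``), and the scale factor.  The
    ``top_cpps`` are the *k* largest CPPs (by completed investigations)
    among those failing the target, with their share of the total excess.
    """
    rows = []
    for cpp in catalogue:
        if cpp.lead_time_max_days is None:
            continue
        times = list(times_by_cpp.get(cpp.cpp_id, ()))
        if not times:
            continue
        scale, rescaled = rescale_times(times, cpp.lead_time_max_days, target)
        mean_obs = float(np.mean(times))
        mean_res = float(np.mean(rescaled))
        n = len(times)
        rows.append(
            {
                "cpp_id": cpp.cpp_id,
                "n": n,
                "lead_time_used_days": cpp.lead_time_max_days,
                "scale_factor": scale,
                "mean_observed_days": mean_obs,
                "mean_rescaled_days": mean_res,
                "excess_days_per_patient": mean_obs - mean_res,
                "total_excess_days": n * (mean_obs - mean_res),
                "met": scale == 1.0,
            }
        )
    table = pd.DataFrame(rows).set_index("cpp_id")
    failing = table[~table["met"]]
    top = failing.sort_values("n", ascending=False).head(k)
    total_excess = float(table["total_excess_days"].sum())
    top_share = (
        float(top["total_excess_days"].sum() / total_excess) if total_excess > 0 else 0.0
    )
    return ExcessSummary(
        table=table.sort_values("n", ascending=False),
        top_cpps=list(top.index),
        top_share_of_total_excess=top_share,
    )
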