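"""State-transition representation of CPP episodes.

Each patient episode is mapped onto a piecewise-constant path through a
fixed set of states on the days-since-WFS axis (day 0 = well-founded
suspicion).  Investigation and treatment states are split by whether the
patient has the primarily suspected diagnosis (PSD); a rejected suspicion
can later be followed by a registered PSD or other cancer, which the model
represents as dedicated "late diagnosis" states.  Death is absorbing; the
other post-stop states are treated as absorbing within the analysis horizon
except for transitions to death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import Catalogue, CohortConfig


class StateId(IntEnum):
    """States of the pathway model, in canonical (stacking) order."""

    IN_CPP_NO_DX = 0
    IN_CPP_WITH_DX = 1
    TREAT_NO_DX = 2
    TREAT_WITH_DX = 3
    REJECTED = 4
    REJECTED_LATE_PSD = 5
    REJECTED_LATE_OTHER = 6
    OTHER_CANCER = 7
    CRITERIA_NOT_MET = 8
    PATIENT_CHOICE = 9
    OTHER_MEDICAL = 10
    DEATH = 11


N_STATES = len(StateId)
STATE_NAMES = [s.name for s in StateId]

#: States a patient cannot leave within the horizon (death excepted).
ABSORBING_EXCEPT_DEATH = frozenset(
    {
        StateId.REJECTED_LATE_PSD,
        StateId.REJECTED_LATE_OTHER,
        StateId.OTHER_CANCER,
        StateId.CRITERIA_NOT_MET,
        StateId.PATIENT_CHOICE,
        StateId.OTHER_MEDICAL,
        StateId.TREAT_WITH_DX,
    }
)

#: Arrow set of the model.  Reconstructed from the pathway's event logic:
#: a diagnosis moves a no-dx state to its with-dx sibling, stop codes leave
#: the investigation states, a rejected suspicion may be followed by a late
#: PSD/other diagnosis, and death is reachable from everywhere.
ALLOWED_TRANSITIONS: frozenset[tuple[StateId, StateId]] = frozenset(
    {(s, s) for s in StateId}
    | {(s, StateId.DEATH) for s in StateId}
    | {
        (StateId.IN_CPP_NO_DX, StateId.IN_CPP_WITH_DX),
        (StateId.IN_CPP_NO_DX, StateId.TREAT_NO_DX),
        (StateId.IN_CPP_NO_DX, StateId.TREAT_WITH_DX),
        (StateId.IN_CPP_NO_DX, StateId.REJECTED),
        (StateId.IN_CPP_NO_DX, StateId.OTHER_CANCER),
        (StateId.IN_CPP_NO_DX, StateId.CRITERIA_NOT_MET),
        (StateId.IN_CPP_NO_DX, StateId.PATIENT_CHOICE),
        (StateId.IN_CPP_NO_DX, StateId.OTHER_MEDICAL),
        (StateId.IN_CPP_WITH_DX, StateId.TREAT_WITH_DX),
        (StateId.IN_CPP_WITH_DX, StateId.REJECTED),
        (StateId.IN_CPP_WITH_DX, StateId.OTHER_CANCER),
        (StateId.IN_CPP_WITH_DX, StateId.CRITERIA_NOT_MET),
        (StateId.IN_CPP_WITH_DX, StateId.PATIENT_CHOICE),
        (StateId.IN_CPP_WITH_DX, StateId.OTHER_MEDICAL),
        (StateId.TREAT_NO_DX, StateId.TREAT_WITH_DX),
        (StateId.REJECTED, StateId.REJECTED_LATE_PSD),
        (StateId.REJECTED, StateId.REJECTED_LATE_OTHER),
    }
)


class MappingError(ValueError):
    """An episode's events cannot be mapped onto the model."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (tables print 0.5 -> 1, not banker's 0)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class StateTrajectory:
    """One episode's state path on the days-since-WFS axis.

    ``segments`` is an ordered list of ``(state, entry_day, exit_day)`` with
    ``exit_day`` ``None`` for the final open segment; segments are contiguous
    and the first starts at day 0.  ``censor_day`` is the day observation
    ends administratively (``None`` when the episode is fully observed over
    any horizon of interest).
    """

    patient_id: str
    cpp_id: str
    segments: list[tuple[StateId, int, int | None]]
    censor_day: int | None = None
    psd_dx_day: int | None = None
    other_dx_day: int | None = None
    stop_day: int | None = None
    stop_code: str | None = None
    sex: str | None = None
    age_at_wfs: int | None = None

    def state_at(self, day: int) -> StateId | None:
        """State occupied on *day*, or ``None`` if beyond censoring."""
        if day < 0 or (self.censor_day is not None and day >= self.censor_day):
            return None
        for state, entry, exit_ in self.segments:
            if day >= entry and (exit_ is None or day < exit_):
                return state
        return None

    def visited(self, state: StateId) -> bool:
        return any(s == state for s, _, _ in self.segments)

    def entry_day(self, state: StateId) -> int | None:
        for s, entry, _ in self.segments:
            if s == state:
                return entry
        return None

    def validate(self) -> None:
        """Check contiguity, day-0 start and the transition whitelist."""
        if not self.segments:
            raise MappingError("empty trajectory")
        if self.segments[0][1] != 0:
            raise MappingError("first segment must start at day 0")
        prev_state, prev_exit = None, 0
        for state, entry, exit_ in self.segments:
            if entry != prev_exit:
                raise MappingError("segments must be contiguous")
            if exit_ is not None and exit_ <= entry:
                raise MappingError("segments must have positive length")
            if prev_state is not None and (prev_state, state) not in ALLOWED_TRANSITIONS:
                raise MappingError(f"transition {prev_state.name} -> {state.name} not allowed")
            prev_state, prev_exit = state, exit_
        if prev_exit is not None:
            raise MappingError("final segment must be open-ended")


_STOP_STATE = {
    "SUSPICION_REJECTED": StateId.REJECTED,
    "OTHER_CANCER": StateId.OTHER_CANCER,
    "CRITERIA_NOT_MET": StateId.CRITERIA_NOT_MET,
    "PATIENT_CHOICE": StateId.PATIENT_CHOICE,
    "OTHER_MEDICAL": StateId.OTHER_MEDICAL,
}


def _day(date, wfs) -> int | None:
    if date is None or pd.isna(date):
        return None
    return int((pd.Timestamp(date) - pd.Timestamp(wfs)).days)


def map_trajectory(
    referral,
    censor_date,
    window_days: int = 183,
) -> StateTrajectory:
    """Map one linked cohort episode to its state trajectory.

    *referral* is a mapping/namedtuple/Series carrying ``patient_id,
    cpp_id, wfs_date, stop_date, stop_code, psd_dx_date, other_dx_date``
    and optionally ``death_date, sex, birth_year``.  The start state is
    ``IN_CPP_WITH_DX`` when the PSD diagnosis falls on or before day 0; a
    PSD diagnosis during the episode moves the no-dx state to its with-dx
    sibling; stop codes map to their states (treatment split by diagnosis
    on or before the stop day); a diagnosis within *window_days* while
    rejected moves to the late-PSD/other states; death is absorbing.  The
    path is truncated at *censor_date*.
    """
    get = referral.get if hasattr(referral, "get") else lambda k, d=None: getattr(referral, k, d)
    wfs = get("wfs_date")
    psd_day = _day(get("psd_dx_date"), wfs)
    other_day = _day(get("other_dx_date"), wfs)
    stop_day = _day(get("stop_date"), wfs)
    death_day = _day(get("death_date"), wfs)
    censor_day = _day(censor_date, wfs)
    stop_code = get("stop_code")
    if stop_code is not None and pd.isna(stop_code):
        stop_code = None

    if stop_day is not None and stop_day < 0:
        raise MappingError(f"{get('patient_id')}: stop before WFS")
    if death_day is not None and death_day < 0:
        raise MappingError(f"{get('patient_id')}: death before WFS")
    if censor_day is None or censor_day < 0:
        raise MappingError(f"{get('patient_id')}: censor date before WFS")

    events: list[tuple[int, int, str]] = []  # (day, priority, kind)
    if death_day is not None:
        events.append((death_day, 0, "death"))
    if stop_day is not None:
        events.append((stop_day, 1, "stop"))
    if psd_day is not None and psd_day > 0:
        events.append((psd_day, 2, "psd_dx"))
    if other_day is not None and other_day > 0:
        events.append((other_day, 3, "other_dx"))
    events.sort()

    start = (
        StateId.IN_CPP_WITH_DX
        if psd_day is not None and psd_day <= 0
        else StateId.IN_CPP_NO_DX
    )
    segments: list[tuple[StateId, int, int | None]] = []
    current, entered = start, 0

    def move(to: StateId, day: int) -> None:
        nonlocal current, entered
        if to == current:
            return
        if day > entered:
            segments.append((current, entered, day))
        current, entered = to, day

    for day, _, kind in events:
        if day >= censor_day or current == StateId.DEATH:
            continue
        if kind == "death":
            move(StateId.DEATH, day)
        elif kind == "stop":
            if stop_code == "TREATMENT_START":
                with_dx = psd_day is not None and psd_day <= stop_day
                move(StateId.TREAT_WITH_DX if with_dx else StateId.TREAT_NO_DX, day)
            else:
                move(_STOP_STATE[stop_code], day)
        elif kind == "psd_dx":
            if current == StateId.IN_CPP_NO_DX:
                move(StateId.IN_CPP_WITH_DX, day)
            elif current == StateId.TREAT_NO_DX:
                move(StateId.TREAT_WITH_DX, day)
            elif current == StateId.REJECTED and day <= window_days:
                move(StateId.REJECTED_LATE_PSD, day)
        elif kind == "other_dx":
            if current == StateId.REJECTED and day <= window_days:
                move(StateId.REJECTED_LATE_OTHER, day)

    segments.append((current, entered, None))

    birth_year = get("birth_year")
    age = None
    if birth_year is not None and not pd.isna(birth_year):
        age = int(pd.Timestamp(wfs).year - int(birth_year))
    sex = get("sex")
    traj = StateTrajectory(
        patient_id=str(get("patient_id")),
        cpp_id=str(get("cpp_id")),
        segments=segments,
        censor_day=censor_day,
        psd_dx_day=psd_day,
        other_dx_day=other_day,
        stop_day=stop_day if stop_day is None or stop_day < censor_day else None,
        stop_code=stop_code if stop_day is not None and stop_day < censor_day else None,
        sex=None if sex is None or pd.isna(sex) else str(sex),
        age_at_wfs=age,
    )
    traj.validate()
    return traj


def map_cohort(
    linked_cohort: pd.DataFrame,
    config: CohortConfig,
) -> list[StateTrajectory]:
    """Map every linked cohort episode (see :func:`registry.link_diagnoses`)."""
    return [
        map_trajectory(row, config.censor_date, config.post_wfs_window_days)
        for row in linked_cohort.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------


@dataclass
class OccupancyCurve:
    """Day × state matrix of cohort proportions.

    ``values`` is indexed by day 0..horizon with one column per state name;
    rows sum to one wherever ``n_at_risk`` is positive and are NaN (flagged
    undefined) where every patient is censored.
    """

    values: pd.DataFrame
    n_at_risk: pd.Series
    horizon_days: int

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (day, state, proportion, n_at_risk) table."""
        tidy = self.values.reset_index(names="day").melt(
            id_vars="day", var_name="state", value_name="proportion"
        )
        tidy["n_at_risk"] = tidy["day"].map(self.n_at_risk)
        return tidy.sort_values(["day", "state"], kind="stable").reset_index(drop=True)


def state_matrix(
    trajectories: Sequence[StateTrajectory], horizon: int
) -> np.ndarray:
    """Encode trajectories as an (n, horizon+1) int8 day-state matrix.

    Entry ``[i, d]`` is the state id occupied by episode *i* on day *d*, or
    −1 where the episode is censored (day ≥ censor_day).
    """
    n = len(trajectories)
    mat = np.full((n, horizon + 1), -1, dtype=np.int8)
    for i, traj in enumerate(trajectories):
        end_obs = horizon + 1
        if traj.censor_day is not None:
            end_obs = min(end_obs, traj.censor_day)
        for state, entry, exit_ in traj.segments:
            hi = end_obs if exit_ is None else min(exit_, end_obs)
            lo = max(entry, 0)
            if lo < hi:
                mat[i, lo:hi] = int(state)
    return mat


def occupancy_empirical(
    trajectories: Sequence[StateTrajectory], horizon: int
) -> OccupancyCurve:
    """Empirical state occupancy among episodes still under observation.

    ``value(day, state)`` = (# uncensored-at-day episodes in *state*) /
    (# uncensored-at-day episodes).  Days where every episode is censored
    get NaN proportions and ``n_at_risk`` 0.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    mat = state_matrix(trajectories, horizon)
    days = np.arange(horizon + 1)
    counts = np.stack(
        [(mat == s).sum(axis=0) for s in range(N_STATES)], axis=1
    ).astype(float)
    at_risk = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts / at_risk[:, None]
    props[at_risk == 0] = np.nan
    values = pd.DataFrame(props, index=pd.Index(days, name="day"), columns=STATE_NAMES)
    return OccupancyCurve(
        values=values,
        n_at_risk=pd.Series(at_risk.astype(int), index=values.index, name="n_at_risk"),
        horizon_days=horizon,
    )


# ---------------------------------------------------------------------------
# Outcome tabulation (Table-1-style)
# ---------------------------------------------------------------------------


def _pct_int(n: int, total: int) -> float:
    return round_half_up(100.0 * n / total) if total else float("nan")


def _pct_1dp(n: int, total: int) -> float:
    return round_half_up(100.0 * n / total, 1) if total else float("nan")


def tabulate_outcomes(
    trajectories: Sequence[StateTrajectory],
    window_days: int = 183,
    catalogue: Catalogue | None = None,
) -> pd.DataFrame:
    """Per-CPP outcome table on the six-month window.

    Columns: total episodes; any cancer diagnosis on/after WFS n (%) of
    total; of which PSD n (%); suspicion rejected n (%); of which later PSD
    / later other cancer n (% of rejected, one decimal); criteria not met
    n (%); of which later diagnosed with cancer n (% of criteria-not-met).
    Percentages are rounded half-up at the printed precision; empty CPPs
    yield NaN percentages.  When *catalogue* is given, PSD columns of
    pathways without a PSD are marked NaN.
    """
    rows = {}
    by_cpp: dict[str, list[StateTrajectory]] = {}
    for t in trajectories:
        by_cpp.setdefault(t.cpp_id, []).append(t)
    for cpp_id, trajs in sorted(by_cpp.items()):
        total = len(trajs)

        def in_window(day):
            return day is not None and 0 <= day <= window_days

        dx_after = [t for t in trajs if in_window(t.psd_dx_day) or in_window(t.other_dx_day)]
        psd_after = [t for t in trajs if in_window(t.psd_dx_day)]
        rejected = [t for t in trajs if t.visited(StateId.REJECTED)]
        late_psd = [t for t in trajs if t.visited(StateId.REJECTED_LATE_PSD)]
        late_other = [t for t in trajs if t.visited(StateId.REJECTED_LATE_OTHER)]
        cnm = [t for t in trajs if t.visited(StateId.CRITERIA_NOT_MET)]
        cnm_later = [
            t
            for t in cnm
            if (
                (in_window(t.psd_dx_day) and t.psd_dx_day > t.entry_day(StateId.CRITERIA_NOT_MET))
                or (in_window(t.other_dx_day) and t.other_dx_day > t.entry_day(StateId.CRITERIA_NOT_MET))
            )
        ]
        no_psd_cpp = (
            catalogue is not None
            and cpp_id in catalogue.cpps
            and not catalogue[cpp_id].has_psd
        )
        rows[cpp_id] = {
            "total": total,
            "dx_on_after_wfs_n": len(dx_after),
            "dx_on_after_wfs_pct": _pct_int(len(dx_after), total),
            "psd_n": float("nan") if no_psd_cpp else len(psd_after),
            "psd_pct": float("nan") if no_psd_cpp else _pct_int(len(psd_after), total),
            "rejected_n": len(rejected),
            "rejected_pct": _pct_int(len(rejected), total),
            "late_psd_n": float("nan") if no_psd_cpp else len(late_psd),
            "late_psd_pct_of_rejected": float("nan")
            if no_psd_cpp
            else _pct_1dp(len(late_psd), len(rejected)),
            "late_other_n": len(late_other),
            "late_other_pct_of_rejected": _pct_1dp(len(late_other), len(rejected)),
            "criteria_not_met_n": len(cnm),
            "criteria_not_met_pct": _pct_int(len(cnm), total),
            "cnm_later_cancer_n": len(cnm_later),
            "cnm_later_cancer_pct": _pct_int(len(cnm_later), len(cnm)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "cpp_id"
    return table.sort_values("total", ascending=False)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

#: Day-slice summary groupings (state-occupancy shares at a day cut).
_SLICE_GROUPS = {
    "still_investigated": (StateId.IN_CPP_NO_DX, StateId.IN_CPP_WITH_DX),
    "with_psd": (
        StateId.IN_CPP_WITH_DX,
        StateId.TREAT_WITH_DX,
        StateId.REJECTED_LATE_PSD,
    ),
    "started_treatment": (StateId.TREAT_NO_DX, StateId.TREAT_WITH_DX),
    "rejected": (
        StateId.REJECTED,
        StateId.REJECTED_LATE_PSD,
        StateId.REJECTED_LATE_OTHER,
    ),
}


def stratify(
    trajectories: Sequence[StateTrajectory],
    by: str,
    horizon: int = 180,
    catalogue: Catalogue | None = None,
    age_cut: int = 70,
    cuts: Sequence[int] = (28, 38, 98),
) -> tuple[dict[str, OccupancyCurve], pd.DataFrame]:
    """Stratified occupancy curves and day-slice summaries.

    *by* is one of ``sex``, ``age70`` (< / ≥ *age_cut* at WFS) or
    ``filter_function`` (CPP catalogue flag, requires *catalogue*).  Returns
    per-stratum curves and a table of grouped state shares (in percent) at
    each day cut.
    """
    if by == "sex":
        key = lambda t: t.sex
    elif by == "age70":
        key = lambda t: (
            None
            if t.age_at_wfs is None
            else (f"age_lt_{age_cut}" if t.age_at_wfs < age_cut else f"age_ge_{age_cut}")
        )
    elif by == "filter_function":
        if catalogue is None:
            raise ValueError("filter_function stratification requires a catalogue")
        flags = {c.cpp_id: c.has_filter_function for c in catalogue}
        key = lambda t: (
            "filter_function" if flags.get(t.cpp_id) else "no_filter_function"
        )
    else:
        raise ValueError(f"unknown stratification key: {by!r}")

    strata: dict[str, list[StateTrajectory]] = {}
    for t in trajectories:
        k = key(t)
        if k is not None:
            strata.setdefault(str(k), []).append(t)

    curves = {k: occupancy_empirical(v, horizon) for k, v in sorted(strata.items())}
    records = []
    for name, curve in curves.items():
        for day in cuts:
            if day > horizon:
                continue
            row = {"stratum": name, "day": day, "n_at_risk": int(curve.n_at_risk.loc[day])}
            for label, group in _SLICE_GROUPS.items():
                share = sum(curve.values.loc[day, s.name] for s in group)
                row[label + "_pct"] = round_half_up(100.0 * share) if not math.isnan(share) else float("nan")
            records.append(row)
    return curves, pd.DataFrame.from_records(records)
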