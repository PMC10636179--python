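"""Discrete-time state-transition model over the days-since-WFS axis.

The model runs in daily cycles.  Transition probabilities are estimated
nonparametrically from observed trajectories in one of two modes:

``calendar_time``
    P_t(s -> s') = (# transitions s -> s' between day t and t+1) /
    (# episodes in s at day t), with censored episodes leaving the risk set
    at their censoring day.

``sojourn_time``
    For a designated set of states (default: the two investigation states
    and the rejected state) the exit hazards are indexed by days since state
    entry instead of calendar day — a semi-Markov construction implemented
    by expanding each designated state into daily "tunnel" states.  All
    other states stay calendar-indexed.

Propagation multiplies the cohort distribution through the daily matrices
(on the sojourn-expanded space in ``sojourn_time`` mode, marginalized back
for reporting); microsimulation samples individual paths from the same
estimate and is the Monte-Carlo counterpart of exact propagation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .states import (
    N_STATES,
    STATE_NAMES,
    OccupancyCurve,
    StateId,
    StateTrajectory,
    state_matrix,
)

#: States whose exit probabilities depend on time since entry by default.
DEFAULT_SOJOURN_STATES = frozenset(
    {StateId.IN_CPP_NO_DX, StateId.IN_CPP_WITH_DX, StateId.REJECTED}
)


@dataclass(frozen=True)
class InitialDistribution:
    """Day-0 distribution over the two entry states.

    Only the investigation states are reachable at day 0: patients start in
    the CPP either without the PSD (about 80% in pooled 2018 data) or with
    it already registered.
    """

    p_no_dx: float
    p_with_dx: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_no_dx <= 1 and 0 <= self.p_with_dx <= 1):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(self.p_no_dx + self.p_with_dx - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    def vector(self) -> np.ndarray:
        v = np.zeros(N_STATES)
        v[StateId.IN_CPP_NO_DX] = self.p_no_dx
        v[StateId.IN_CPP_WITH_DX] = self.p_with_dx
        return v


@dataclass
class TransitionEstimate:
    """Nonparametric daily transition estimate with at-risk counts.

    ``counts[s]`` is a (grid, n_states) array of observed transition counts
    out of state *s* and ``at_risk[s]`` the matching risk-set sizes; the
    grid is calendar days for calendar-indexed states and sojourn days for
    designated states (``sojourn_time`` mode only).  Cells with zero at-risk
    default to self-transition (probability 1) — no extrapolation.
    """

    mode: str
    horizon: int
    counts: dict[int, np.ndarray]
    at_risk: dict[int, np.ndarray]
    sojourn_states: frozenset[int]
    smoothing: int = 0
    n_observed: np.ndarray | None = None  # episodes under observation per day
    day0_distribution: np.ndarray | None = None  # observed state shares at day 0

    def _smoothed(self, s: int) -> tuple[np.ndarray, np.ndarray]:
        c, r = self.counts[s], self.at_risk[s]
        if self.smoothing <= 0:
            return c, r
        w = 2 * self.smoothing + 1
        kernel = np.ones(w)
        pad = self.smoothing
        csm = np.stack(
            [np.convolve(np.pad(c[:, j], pad, mode="edge"), kernel, "valid") for j in range(c.shape[1])],
            axis=1,
        )
        rsm = np.convolve(np.pad(r, pad, mode="edge"), kernel, "valid")
        return csm, rsm

    def row(self, s: int, index: int) -> np.ndarray:
        """Transition probability row for state *s* at grid day *index*."""
        c, r = self._smoothed(s)
        if index >= len(r) or r[index] == 0:
            out = np.zeros(N_STATES)
            out[s] = 1.0
            return out
        return c[index] / r[index]

    def transition_matrix(self, t: int) -> np.ndarray:
        """Row-stochastic P_t over the plain state space (calendar mode)."""
        if self.mode != "calendar_time":
            raise ValueError("plain matrices only defined in calendar_time mode")
        return np.stack([self.row(s, t) for s in range(N_STATES)])

    def grid_length(self, s: int) -> int:
        return len(self.at_risk[s])

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "horizon": self.horizon,
            "states": STATE_NAMES,
            "sojourn_states": sorted(self.sojourn_states),
            "smoothing": self.smoothing,
            "counts": {str(s): self.counts[s].tolist() for s in self.counts},
            "at_risk": {str(s): self.at_risk[s].tolist() for s in self.at_risk},
            "n_observed": None if self.n_observed is None else self.n_observed.tolist(),
            "day0_distribution": None
            if self.day0_distribution is None
            else self.day0_distribution.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TransitionEstimate":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        payload = json.loads(text)
        return cls(
            mode=payload["mode"],
            horizon=payload["horizon"],
            counts={int(s): np.asarray(v, dtype=float) for s, v in payload["counts"].items()},
            at_risk={int(s): np.asarray(v, dtype=float) for s, v in payload["at_risk"].items()},
            sojourn_states=frozenset(payload["sojourn_states"]),
            smoothing=payload["smoothing"],
            n_observed=None
            if payload["n_observed"] is None
            else np.asarray(payload["n_observed"]),
            day0_distribution=None
            if payload.get("day0_distribution") is None
            else np.asarray(payload["day0_distribution"], dtype=float),
        )


def _sojourn_ages(mat: np.ndarray) -> np.ndarray:
    """Days since entering the current state, per episode-day cell."""
    n, T = mat.shape
    ages = np.zeros_like(mat, dtype=np.int32)
    for t in range(1, T):
        same = (mat[:, t] == mat[:, t - 1]) & (mat[:, t] >= 0)
        ages[:, t] = np.where(same, ages[:, t - 1] + 1, 0)
    return ages


def estimate(
    trajectories: Sequence[StateTrajectory],
    mode: str = "calendar_time",
    smoothing: int = 0,
    horizon: int | None = None,
    sojourn_states: frozenset[int] | None = None,
) -> TransitionEstimate:
    """Estimate daily transition probabilities from observed trajectories.

    See the module docstring for the two modes.  *horizon* defaults to the
    latest day any episode is observed; *smoothing* is the half-width (in
    days) of an optional moving-average window applied to both transition
    and at-risk counts, which preserves row-stochasticity.
    """
    if mode not in ("calendar_time", "sojourn_time"):
        raise ValueError(f"unknown mode: {mode!r}")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if sojourn_states is None:
        sojourn_states = frozenset(int(s) for s in DEFAULT_SOJOURN_STATES)
    if mode == "calendar_time":
        sojourn_states = frozenset()

    if horizon is None:
        horizon = 0
        for t in trajectories:
            end = t.censor_day if t.censor_day is not None else 0
            horizon = max(horizon, end)
    mat = state_matrix(trajectories, horizon)
    T = horizon  # transitions observed at t = 0 .. horizon-1

    frm = mat[:, :-1]
    to = mat[:, 1:]
    valid = (frm >= 0) & (to >= 0)
    n_observed = valid.sum(axis=0)

    counts: dict[int, np.ndarray] = {}
    at_risk: dict[int, np.ndarray] = {}

    tt = np.broadcast_to(np.arange(T), frm.shape)
    if sojourn_states:
        ages = _sojourn_ages(mat)[:, :-1]
    for s in range(N_STATES):
        sel = valid & (frm == s)
        if s in sojourn_states:
            grid = ages[sel]
            glen = max(int(grid.max()) + 1, 1) if grid.size else 1
        else:
            grid = tt[sel]
            glen = T if T > 0 else 1
        c = np.zeros((glen, N_STATES))
        r = np.zeros(glen)
        np.add.at(c, (grid, to[sel]), 1.0)
        np.add.at(r, grid, 1.0)
        counts[s], at_risk[s] = c, r

    day0 = mat[:, 0]
    day0 = day0[day0 >= 0]
    day0_distribution = np.bincount(day0, minlength=N_STATES).astype(float)
    if day0_distribution.sum() > 0:
        day0_distribution /= day0_distribution.sum()

    return TransitionEstimate(
        mode=mode,
        horizon=T,
        counts=counts,
        at_risk=at_risk,
        sojourn_states=sojourn_states,
        smoothing=smoothing,
        n_observed=n_observed,
        day0_distribution=day0_distribution,
    )


def _curve(values: np.ndarray, n_observed, horizon: int) -> OccupancyCurve:
    df = pd.DataFrame(
        values, index=pd.Index(np.arange(horizon + 1), name="day"), columns=STATE_NAMES
    )
    if n_observed is None:
        n = pd.Series(0, index=df.index, name="n_at_risk")
    else:
        n_obs = np.asarray(n_observed)
        n = pd.Series(
            [int(n_obs[min(t, len(n_obs) - 1)]) if len(n_obs) else 0 for t in df.index],
            index=df.index,
            name="n_at_risk",
        )
    return OccupancyCurve(values=df, n_at_risk=n, horizon_days=horizon)


def propagate(
    est: TransitionEstimate,
    initial: InitialDistribution,
    horizon: int,
    carry_forward: bool = False,
) -> OccupancyCurve:
    """Propagate the cohort distribution through the estimated model.

    occupancy(0) = *initial*; occupancy(t+1) = occupancy(t) · P_t.  In
    ``sojourn_time`` mode the product runs on the sojourn-expanded space and
    is marginalized back per day.  Days beyond the estimated range raise
    unless *carry_forward* re-uses the last estimated day.
    """
    if horizon > est.horizon and not carry_forward:
        raise ValueError(
            f"horizon {horizon} beyond estimated range {est.horizon}; "
            "enable carry_forward to extend with the last estimated day"
        )
    out = np.zeros((horizon + 1, N_STATES))
    if est.mode == "calendar_time":
        occ = initial.vector()
        out[0] = occ
        for t in range(horizon):
            tc = min(t, est.horizon - 1)
            occ = occ @ est.transition_matrix(tc)
            out[t + 1] = occ
        return _curve(out, est.n_observed, horizon)

    # sojourn-expanded propagation
    soj = sorted(est.sojourn_states)
    plain = np.zeros(N_STATES)
    tunnels = {s: np.zeros(horizon + 1) for s in soj}
    init = initial.vector()
    for s in range(N_STATES):
        if init[s] == 0:
            continue
        if s in tunnels:
            tunnels[s][0] = init[s]
        else:
            plain[s] = init[s]

    def marginal() -> np.ndarray:
        v = plain.copy()
        for s in soj:
            v[s] += tunnels[s].sum()
        return v

    out[0] = marginal()
    for t in range(horizon):
        tc = min(t, est.horizon - 1)
        new_plain = np.zeros(N_STATES)
        new_tunnels = {s: np.zeros(horizon + 1) for s in soj}
        # plain (calendar-indexed) states
        for s in range(N_STATES):
            mass = plain[s]
            if mass == 0:
                continue
            row = est.row(s, tc)
            for s2 in range(N_STATES):
                flow = mass * row[s2]
                if flow == 0:
                    continue
                if s2 in new_tunnels:
                    if s2 == s:
                        new_plain[s] += flow  # unreachable: plain s not designated
                    else:
                        new_tunnels[s2][0] += flow
                else:
                    new_plain[s2] += flow
        # designated states, sojourn-indexed
        for s in soj:
            m = tunnels[s]
            glen = est.grid_length(s)
            for u in np.nonzero(m)[0]:
                mass = m[u]
                row = est.row(s, min(int(u), glen - 1)) if u < glen else None
                if row is None:
                    # beyond observed sojourn range: stay put
                    new_tunnels[s][min(u + 1, horizon)] += mass
                    continue
                for s2 in range(N_STATES):
                    flow = mass * row[s2]
                    if flow == 0:
                        continue
                    if s2 == s:
                        new_tunnels[s][min(u + 1, horizon)] += flow
                    elif s2 in new_tunnels:
                        new_tunnels[s2][0] += flow
                    else:
                        new_plain[s2] += flow
        plain, tunnels = new_plain, new_tunnels
        out[t + 1] = marginal()
    return _curve(out, est.n_observed, horizon)


def microsimulate(
    est: TransitionEstimate,
    n: int,
    seed: int,
    horizon: int,
    initial: InitialDistribution | None = None,
    carry_forward: bool = True,
) -> np.ndarray:
    """Sample *n* independent state paths (an (n, horizon+1) int8 matrix).

    The Monte-Carlo counterpart of :func:`propagate`: paths are drawn from
    the same daily transition rows, so at large *n* the path-wise occupancy
    converges to the exact propagation.  *initial* defaults to the
    estimate's observed day-0 distribution.  Reproducible per *seed*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if initial is None:
        if est.day0_distribution is None or est.day0_distribution.sum() == 0:
            raise ValueError("estimate has no day-0 information; pass initial")
        p0 = est.day0_distribution
    else:
        p0 = initial.vector()

    states = rng.choice(N_STATES, size=n, p=p0).astype(np.int16)
    ages = np.zeros(n, dtype=np.int32)
    paths = np.empty((n, horizon + 1), dtype=np.int8)
    paths[:, 0] = states

    for t in range(horizon):
        tc = min(t, est.horizon - 1) if carry_forward else t
        nxt = states.copy()
        r = rng.random(n)
        for s in np.unique(states):
            idx = np.nonzero(states == s)[0]
            if s in est.sojourn_states and est.mode == "sojourn_time":
                glen = est.grid_length(int(s))
                rows = np.stack(
                    [est.row(int(s), min(int(u), glen - 1)) for u in np.minimum(ages[idx], glen - 1)]
                )
            else:
                row = est.row(int(s), tc)
                rows = np.broadcast_to(row, (len(idx), N_STATES))
            cum = np.cumsum(rows, axis=1)
            nxt[idx] = (r[idx, None] > cum).sum(axis=1)
        moved = nxt != states
        ages = np.where(moved, 0, ages + 1)
        states = nxt
        paths[:, t + 1] = states
    return paths


def occupancy_from_paths(paths: np.ndarray) -> OccupancyCurve:
    """Empirical occupancy of simulated (uncensored) paths."""
    n, T = paths.shape
    counts = np.stack([(paths == s).sum(axis=0) for s in range(N_STATES)], axis=1)
    values = counts / n
    curve = _curve(values.astype(float), np.full(T, n), T - 1)
    return curve


def summarize(
    trajectories: Sequence[StateTrajectory], window_days: int = 183
) -> dict:
    """Headline flow statistics with explicit denominators.

    Means are taken over the episodes reaching the event; shares report
    their denominator under ``n``.  A statistic whose denominator is empty
    is ``None`` (undefined), never 0.
    """
    dx_days = [
        t.psd_dx_day
        for t in trajectories
        if t.psd_dx_day is not None and 0 <= t.psd_dx_day <= window_days
    ]
    treated = [t for t in trajectories if t.stop_code == "TREATMENT_START"]
    treat_days = [t.stop_day for t in treated]
    treated_after_dx = [
        t for t in treated if t.psd_dx_day is not None and t.psd_dx_day <= t.stop_day
    ]
    start_with_dx = [
        t for t in trajectories if t.psd_dx_day is not None and t.psd_dx_day <= 0
    ]
    n = len(trajectories)
    return {
        "mean_days_to_diagnosis": {
            "value": float(np.mean(dx_days)) if dx_days else None,
            "n": len(dx_days),
            "denominator": "episodes with a PSD diagnosis on/after WFS",
        },
        "mean_days_to_treatment": {
            "value": float(np.mean(treat_days)) if treat_days else None,
            "n": len(treat_days),
            "denominator": "episodes stopping with treatment start",
        },
        "share_treated_after_diagnosis": {
            "value": len(treated_after_dx) / len(treated) if treated else None,
            "n": len(treated),
            "denominator": "episodes stopping with treatment start",
        },
        "share_starting_with_diagnosis": {
            "value": len(start_with_dx) / n if n else None,
            "n": n,
            "denominator": "all episodes",
        },
    }
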