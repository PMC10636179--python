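"""Stacked patient-flow diagrams and excess-time bar charts.

The flow diagram stacks per-state occupancy areas over days since WFS:
investigation states at the bottom, treatment above, the rejection band
(with the late-PSD re-diagnoses drawn as a thin black stripe inside it),
the exclusion codes, and death on top.  The exact published ordering and
palette are not fully recoverable, so both are config-overridable defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .states import StateId, OccupancyCurve

#: Bottom-to-top stacking order.
DEFAULT_STATE_ORDER: tuple[StateId, ...] = (
    StateId.IN_CPP_NO_DX,
    StateId.IN_CPP_WITH_DX,
    StateId.TREAT_NO_DX,
    StateId.TREAT_WITH_DX,
    StateId.REJECTED,
    StateId.REJECTED_LATE_PSD,
    StateId.REJECTED_LATE_OTHER,
    StateId.OTHER_CANCER,
    StateId.CRITERIA_NOT_MET,
    StateId.PATIENT_CHOICE,
    StateId.OTHER_MEDICAL,
    StateId.DEATH,
)

DEFAULT_PALETTE: dict[str, str] = {
    "IN_CPP_NO_DX": "#f5d547",  # yellow: investigated, no diagnosis
    "IN_CPP_WITH_DX": "#ef8a17",  # orange: investigated, diagnosed
    "TREAT_NO_DX": "#f4a199",  # light red
    "TREAT_WITH_DX": "#b81d13",  # dark red: treatment after diagnosis
    "REJECTED": "#58a55c",  # green band
    "REJECTED_LATE_PSD": "#000000",  # black stripe inside the green band
    "REJECTED_LATE_OTHER": "#2e5d34",
    "OTHER_CANCER": "#3b6fb6",  # blue
    "CRITERIA_NOT_MET": "#8e6bb0",
    "PATIENT_CHOICE": "#c9c9c9",
    "OTHER_MEDICAL": "#8c8c8c",
    "DEATH": "#3d3d3d",
}


class RenderError(ValueError):
    """The render spec does not cover the curve's states."""


@dataclass(frozen=True)
class RenderSpec:
    """Stacking order, palette and output format for flow diagrams."""

    state_order: tuple[StateId, ...] = DEFAULT_STATE_ORDER
    palette: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    horizon: int | None = None
    image_format: str = "png"
    csv_precision: int = 10

    def __post_init__(self) -> None:
        if len(set(self.state_order)) != len(self.state_order):
            raise RenderError("state_order contains duplicates")
        missing = [s.name for s in self.state_order if s.name not in self.palette]
        if missing:
            raise RenderError(f"palette missing colors for: {', '.join(missing)}")


def render_flow(
    curve: OccupancyCurve,
    out_path: str | Path,
    spec: RenderSpec | None = None,
    title: str | None = None,
) -> tuple[Path, Path]:
    """Render a stacked flow diagram; write the image and its tidy CSV.

    The CSV (``<out>.csv``) holds exactly the plotted values — day, state,
    proportion, n_at_risk — serialized at fixed precision so it round-trips
    the plot data.  Days where occupancy is undefined (everyone censored)
    are dropped from both outputs.  Raises :class:`RenderError` if the
    curve has occupancy in a state absent from the spec's order.
    """
    spec = spec or RenderSpec()
    values = curve.values
    missing = [
        c
        for c in values.columns
        if c not in {s.name for s in spec.state_order}
        and np.nansum(values[c].to_numpy()) > 0
    ]
    if missing:
        raise RenderError(f"states missing from render spec: {', '.join(missing)}")

    defined = ~values.isna().any(axis=1)
    values = values[defined]
    if spec.horizon is not None:
        values = values.loc[values.index <= spec.horizon]
    days = values.index.to_numpy()
    ordered = [s.name for s in spec.state_order if s.name in values.columns]
    stack = values[ordered].to_numpy().T

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.stackplot(
        days,
        stack,
        labels=ordered,
        colors=[spec.palette[s] for s in ordered],
        linewidth=0,
    )
    ax.set_xlim(days.min() if len(days) else 0, days.max() if len(days) else 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("days since well-founded suspicion")
    ax.set_ylabel("proportion of patients")
    if title:
        ax.set_title(title)
    ax.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    tidy = (
        values[ordered]
        .reset_index(names="day")
        .melt(id_vars="day", var_name="state", value_name="proportion")
    )
    tidy["n_at_risk"] = tidy["day"].map(curve.n_at_risk)
    csv_path = out_path.with_suffix(out_path.suffix + ".csv")
    tidy.to_csv(csv_path, index=False, float_format=f"%.{spec.csv_precision}g")
    return out_path, csv_path


def render_excess(
    excess_table: pd.DataFrame,
    out_path: str | Path,
    cpp_order: list[str] | None = None,
) -> Path:
    """Variable-width excess-time bars for CPPs failing the lead-time target.

    Bar width is proportional to the number of completed investigations;
    the grey portion is the hypothetical mean investigation time had the
    lead-time target been met (rescaled), the red portion the excess.
    """
    table = excess_table
    if cpp_order is not None:
        table = table.loc[cpp_order]
    widths = table["n"].to_numpy(dtype=float)
    lefts = np.concatenate([[0.0], np.cumsum(widths)[:-1]])
    gap = widths.sum() * 0.01
    lefts = lefts + gap * np.arange(len(widths))

    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.bar(
        lefts,
        table["mean_rescaled_days"],
        width=widths,
        align="edge",
        color="#9c9c9c",
        label="within lead-time mean (rescaled)",
    )
    ax.bar(
        lefts,
        table["excess_days_per_patient"],
        width=widths,
        align="edge",
        bottom=table["mean_rescaled_days"],
        color="#c23b22",
        label="excess time",
    )
    for left, width, cpp in zip(lefts, widths, table.index):
        ax.text(
            left + width / 2,
            -1.5,
            cpp,
            rotation=90,
            ha="center",
            va="top",
            fontsize=7,
        )
    ax.set_ylabel("mean investigation time (days)")
    ax.set_xticks([])
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
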