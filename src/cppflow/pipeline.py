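"""End-to-end pipeline orchestration.

A single YAML config drives the full analysis: simulate (or load) the three
registry tables, build the cohort, link diagnoses, map trajectories,
estimate and propagate the transition model, evaluate both national
targets, quantify excess investigation time, and render the flow diagrams.
Every stage's outputs land in the configured results directory together
with a machine-readable run manifest (input hashes, seed, versions), so a
fixed config and seed reproduce the numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .registry import (
    Catalogue,
    CohortConfig,
    attach_diagnosis_groups,
    build_cohort,
    link_diagnoses,
    load_catalogue,
    read_cancer_register,
    read_patients,
    read_referrals,
)
from .states import map_cohort, occupancy_empirical, stratify, tabulate_outcomes
from .synthetic import preset_scenarios, scenario_from_yaml, write_files
from .targets import excess_summary, inclusion_target, lead_time_target
from .transitions import InitialDistribution, estimate, propagate, summarize
from .viz import RenderSpec, render_excess, render_flow

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full analysis described by *config*; returns the manifest.

    Config keys: ``output_dir`` (required); input via either ``scenario``
    (preset name), ``scenario_file`` (YAML scenario) or ``inputs``
    (mapping with ``referrals``/``cancer``/``patients`` CSV paths);
    ``seed``; ``study_year``; ``censor_date``; ``horizon`` (days, default
    180); ``strata`` (subset of sex/age70/filter_function); ``per_cpp``
    (list of CPP ids to render individually, or ``all``); ``catalogue``
    (path, defaults to the bundled one).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    horizon = int(config.get("horizon", 180))
    catalogue = load_catalogue(config.get("catalogue"))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "horizon": horizon,
        "stages": [],
        "inputs": {},
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    # -- stage 1: inputs ----------------------------------------------------
    stage("inputs")
    try:
        if "inputs" in config:
            paths = {k: Path(v) for k, v in config["inputs"].items()}
            for key in ("referrals", "cancer", "patients"):
                if key not in paths:
                    raise StageError(f"inputs: missing {key} path")
                if not paths[key].exists():
                    raise StageError(f"inputs: no such file: {paths[key]}")
        else:
            if "scenario_file" in config:
                scenario = scenario_from_yaml(config["scenario_file"])
            else:
                name = config.get("scenario", "pooled_2018")
                presets = preset_scenarios(seed=seed)
                if name not in presets:
                    raise StageError(
                        f"inputs: unknown preset {name!r}; "
                        f"available: {', '.join(sorted(presets))}"
                    )
                scenario = presets[name]
            sim_dir = out_dir / "simulated"
            paths = write_files(scenario, sim_dir, catalogue)
            manifest["scenario"] = config.get("scenario", config.get("scenario_file"))
        manifest["inputs"] = {k: _sha256(p) for k, p in paths.items()}
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"inputs: {exc}") from exc

    referrals = read_referrals(paths["referrals"])
    cancer = read_cancer_register(paths["cancer"], catalogue)
    patients = read_patients(paths["patients"])

    study_year = int(config.get("study_year", 2018))
    censor_date = config.get("censor_date")
    if censor_date is None:
        censor_date = max(
            referrals["wfs_date"].max(),
            referrals["stop_date"].max(),
            cancer["diagnosis_date"].max(),
        )
    cohort_cfg = CohortConfig(study_year=study_year, censor_date=pd.Timestamp(censor_date))

    # -- stage 2: cohort ----------------------------------------------------
    stage("cohort")
    try:
        cohort, exclusions = build_cohort(referrals, patients, cohort_cfg)
        (out_dir / "exclusions.json").write_text(json.dumps(exclusions, indent=2))
    except Exception as exc:
        raise StageError(f"cohort: {exc}") from exc

    # -- stage 3: linkage + mapping ------------------------------------------
    stage("map")
    try:
        linked = link_diagnoses(cohort, cancer, catalogue, cohort_cfg)
        trajectories = map_cohort(linked, cohort_cfg)
    except Exception as exc:
        raise StageError(f"map: {exc}") from exc

    # -- stage 4: occupancy + model -------------------------------------------
    stage("model")
    try:
        emp = occupancy_empirical(trajectories, horizon)
        emp.to_tidy().to_csv(out_dir / "occupancy_empirical.csv", index=False)
        est = estimate(trajectories, mode="calendar_time", horizon=horizon)
        est.to_json(out_dir / "transition_estimate.json")
        day0 = emp.values.iloc[0]
        initial = InitialDistribution(
            p_no_dx=float(day0["IN_CPP_NO_DX"]),
            p_with_dx=float(day0["IN_CPP_WITH_DX"]),
        )
        model_curve = propagate(est, initial, horizon)
        model_curve.to_tidy().to_csv(out_dir / "occupancy_model.csv", index=False)
        with open(out_dir / "flow_summary.json", "w") as fh:
            json.dump(summarize(trajectories), fh, indent=2)
    except Exception as exc:
        raise StageError(f"model: {exc}") from exc

    # -- stage 5: tables ------------------------------------------------------
    stage("tables")
    try:
        outcomes = tabulate_outcomes(
            trajectories, cohort_cfg.post_wfs_window_days, catalogue
        )
        outcomes.to_csv(out_dir / "outcomes_table.csv")
        inclusion = inclusion_target(cancer, referrals, catalogue, cohort_cfg)
        inclusion.to_csv(out_dir / "inclusion_table.csv")
        lead = lead_time_target(trajectories, catalogue)
        lead.to_csv(out_dir / "lead_time_table.csv")
        times_by_cpp: dict[str, list[int]] = {}
        for t in trajectories:
            if t.stop_day is not None:
                times_by_cpp.setdefault(t.cpp_id, []).append(t.stop_day)
        excess = excess_summary(times_by_cpp, catalogue)
        excess.table.to_csv(out_dir / "excess_table.csv")
        (out_dir / "excess_summary.json").write_text(
            json.dumps(
                {
                    "top_cpps": excess.top_cpps,
                    "top_share_of_total_excess": excess.top_share_of_total_excess,
                },
                indent=2,
            )
        )
    except Exception as exc:
        raise StageError(f"tables: {exc}") from exc

    # -- stage 6: strata ------------------------------------------------------
    stage("strata")
    try:
        frames = []
        for by in config.get("strata", ["sex", "age70", "filter_function"]):
            _, summary = stratify(trajectories, by, horizon, catalogue=catalogue)
            summary.insert(0, "by", by)
            frames.append(summary)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out_dir / "strata_summary.csv", index=False
            )
    except Exception as exc:
        raise StageError(f"strata: {exc}") from exc

    # -- stage 7: plots -------------------------------------------------------
    stage("plots")
    try:
        spec = RenderSpec()
        render_flow(emp, out_dir / "flow_pooled.png", spec, title="All CPPs pooled")
        per_cpp = config.get("per_cpp", [])
        if per_cpp == "all":
            per_cpp = sorted({t.cpp_id for t in trajectories})
        for cpp_id in per_cpp:
            sub = [t for t in trajectories if t.cpp_id == cpp_id]
            if not sub:
                raise StageError(f"plots: no trajectories for CPP {cpp_id!r}")
            render_flow(
                occupancy_empirical(sub, horizon),
                out_dir / f"flow_{cpp_id}.png",
                spec,
                title=cpp_id,
            )
        failing = excess.table[~excess.table["met"]]
        if len(failing):
            render_excess(
                failing.loc[[c for c in excess.top_cpps]],
                out_dir / "excess_bars.png",
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"plots: {exc}") from exc

    manifest["outputs"] = sorted(
        str(p.relative_to(out_dir)) for p in out_dir.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
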