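"""Configuration-driven orchestration of the full analysis.

Stages: simulate → preprocess → first-level → second-level → report. Every
stage persists its artifacts (epoch/beta-map bundles, TSV tables, JSON
summaries) under the output directory, and a rerun with the same config and
seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, ComponentSpec, NoiseModel, make_cohort
from .design import build_design
from .epochs import (
    EpochSet,
    baseline_correct,
    reject_improbable,
    select_analysis_window,
    smooth_temporal,
    write_bundle,
)
from .exceptions import DesignError, ParameterError
from .firstlevel import fit_subject_maps, group_onesample_map, write_betamap
from .moderation import fit_moderated_map, mask_map, residualize, window_score

__all__ = ["ComponentWindow", "SecondLevelSet", "PipelineConfig", "run_pipeline", "write_report"]

TASKS = ("gonogo", "sst", "miflat", "twostep")
TASK_REGRESSOR = {"gonogo": "trial_type", "sst": "trial_type", "miflat": "valence",
                  "twostep": "valence"}

# default peak-search regions per task: ROI channels and minimum latency
DEFAULT_PEAK_SEARCH = {
    "gonogo": {"channels": ["FC1", "FCz", "Cz", "CPz", "CP1", "CP2"], "window": (300.0, 700.0)},
    "sst": {"channels": ["Cz", "CPz", "CP1", "CP2", "CP4", "Pz", "P1", "P2"],
            "window": (400.0, 700.0)},
    "miflat": {"channels": ["CPz", "CP1", "CP2", "Pz", "P1", "P2"], "window": (350.0, 700.0)},
    "twostep": {"channels": ["CPz", "CP1", "CP2", "Pz", "P1", "P2"], "window": (350.0, 700.0)},
}


@dataclass
class ComponentWindow:
    """A named feedback component: source task, electrode, ms window."""

    task: str
    electrode: str
    window: tuple


@dataclass
class SecondLevelSet:
    """One second-level analysis: y task × x component × moderator."""

    y_task: str
    x_component: str
    moderator: str  # oci_r | negative_urgency | residual_oci_r | residual_urgency


DEFAULT_COMPONENT_WINDOWS = {
    "p3b_miflat": ComponentWindow("miflat", "Pz", (500.0, 520.0)),
    "p3_twostep": ComponentWindow("twostep", "CP1", (440.0, 460.0)),
}


def _default_second_level():
    return [
        SecondLevelSet(y, x, "oci_r")
        for x in ("p3b_miflat", "p3_twostep")
        for y in ("sst", "gonogo")
    ]


@dataclass
class PipelineConfig:
    """Validated end-to-end configuration (see `PipelineConfig.validate`)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    baseline_window: tuple = (-200.0, 0.0)
    z_thresh: float = 5.0
    analysis_window: tuple = (-100.0, 700.0)
    alpha: float = 0.025
    component_windows: dict = field(
        default_factory=lambda: {
            k: ComponentWindow(v.task, v.electrode, tuple(v.window))
            for k, v in DEFAULT_COMPONENT_WINDOWS.items()
        }
    )
    second_level: list = field(default_factory=_default_second_level)
    p_mask: float = 0.010
    jn_threshold: float = 0.01
    peak_search: dict = field(
        default_factory=lambda: {
            k: {"channels": list(v["channels"]), "window": tuple(v["window"])}
            for k, v in DEFAULT_PEAK_SEARCH.items()
        }
    )
    seed: int = 0

    def validate(self):
        self.cohort.validate()
        montage = set(self.cohort.channels)
        for name, cw in self.component_windows.items():
            if cw.task not in TASKS:
                raise ParameterError(f"component {name!r} references unknown task {cw.task!r}")
            if cw.electrode not in montage:
                raise ParameterError(f"component {name!r} electrode {cw.electrode!r} not in montage")
            if cw.window[0] < self.analysis_window[0] or cw.window[1] > self.analysis_window[1]:
                raise ParameterError(
                    f"component {name!r} window {cw.window} outside analysis window"
                )
        for s in self.second_level:
            if s.y_task not in ("gonogo", "sst"):
                raise ParameterError(f"second-level y task must be gonogo|sst, got {s.y_task!r}")
            if s.x_component not in self.component_windows:
                raise ParameterError(f"unknown x component {s.x_component!r}")
            if s.moderator not in (
                "oci_r", "negative_urgency", "residual_oci_r", "residual_urgency"
            ):
                raise ParameterError(f"unknown moderator {s.moderator!r}")
        for task, spec in self.peak_search.items():
            missing = [c for c in spec["channels"] if c not in montage]
            if missing:
                raise ParameterError(f"peak-search channels {missing} not in montage ({task})")
        for name, v in (("alpha", self.alpha), ("p_mask", self.p_mask),
                        ("jn_threshold", self.jn_threshold)):
            if not 0 < v < 1:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")

    # -- YAML round trip -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            if "noise" in c:
                c["noise"] = NoiseModel(**c["noise"])
            if "components" in c:
                c["components"] = {k: ComponentSpec(**v) for k, v in c["components"].items()}
            kwargs["cohort"] = CohortConfig(**c)
        if "component_windows" in kwargs:
            kwargs["component_windows"] = {
                k: ComponentWindow(v["task"], v["electrode"], tuple(v["window"]))
                for k, v in kwargs["component_windows"].items()
            }
        if "second_level" in kwargs:
            kwargs["second_level"] = [SecondLevelSet(**s) for s in kwargs["second_level"]]
        for key in ("baseline_window", "analysis_window"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def preprocess_epochs(epochs: EpochSet, config: PipelineConfig):
    """Baseline-correct, reject improbable epochs, smooth, select window."""
    ep = baseline_correct(epochs, config.baseline_window)
    ep, rejected = reject_improbable(ep, config.z_thresh)
    ep = smooth_temporal(ep)
    ep = select_analysis_window(ep, config.analysis_window)
    return ep, rejected


def _moderator_values(name: str, traits: pd.DataFrame) -> np.ndarray:
    oci = traits["oci_r"].to_numpy(float)
    nu = traits["negative_urgency"].to_numpy(float)
    if name == "oci_r":
        return oci
    if name == "negative_urgency":
        return nu
    if name == "residual_oci_r":
        return residualize(oci, nu)
    if name == "residual_urgency":
        return residualize(nu, oci)
    raise ParameterError(f"unknown moderator {name!r}")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"package": "trialwise", "version": __version__},
        "seed": config.seed,
        "stages": {},
    }

    # -- simulate -------------------------------------------------------------
    cohort = make_cohort(config.cohort, seed=config.seed)
    sim_dir = out / "sim"
    cohort.traits.to_csv(out / "traits.tsv", sep="\t", index=False)
    cohort.truth.to_json(out / "truth.json")
    for subject, per_task in cohort.epochs.items():
        for task, ep in per_task.items():
            write_bundle(ep, sim_dir / subject / task)
    report["stages"]["simulate"] = {
        "n_subjects": config.cohort.n_subjects,
        "tasks": dict(config.cohort.tasks),
        "channels": list(config.cohort.channels),
        "fs": config.cohort.fs,
    }

    # -- preprocess + first level --------------------------------------------
    # subjects whose task design is degenerate (e.g. a short two-step block
    # yielding only gains) are excluded from that task's analyses, mirroring
    # usability-based subject exclusion in real studies
    maps: dict = {t: {} for t in TASKS}
    counts = {
        t: {"epochs_rejected": 0, "design_rows_dropped": 0, "subjects_excluded": []}
        for t in TASKS
    }
    fl_dir = out / "first_level"
    for subject in cohort.subjects:
        for task in TASKS:
            ep, rejected = preprocess_epochs(cohort.epochs[subject][task], config)
            counts[task]["epochs_rejected"] += int(rejected.size)
            try:
                design = build_design(ep.trial_table, task)
            except DesignError:
                counts[task]["subjects_excluded"].append(subject)
                continue
            counts[task]["design_rows_dropped"] += design.n_dropped
            bmap = fit_subject_maps(ep, design)
            write_betamap(bmap, fl_dir / subject / task)
            maps[task][subject] = bmap
    report["stages"]["preprocess"] = counts

    group_dir = out / "group"
    group_dir.mkdir(parents=True, exist_ok=True)
    peaks = []
    group_maps = {}
    for task in TASKS:
        gmap = group_onesample_map(
            list(maps[task].values()), TASK_REGRESSOR[task], alpha=config.alpha
        )
        group_maps[task] = gmap
        spec = config.peak_search[task]
        pk = gmap.find_peak(spec["channels"], spec["window"], polarity="positive")
        peaks.append({"task": task, **pk.row(), "found": pk.found})
    report["stages"]["first_level"] = {
        task: {
            "critical_p": group_maps[task].critical_p,
            "n_significant": int(group_maps[task].significant.sum()),
            "n_cells": int(group_maps[task].significant.size),
            "df": group_maps[task].df,
        }
        for task in TASKS
    }
    report["peaks"] = peaks

    # -- second level ----------------------------------------------------------
    sl_dir = out / "second_level"
    sl_dir.mkdir(parents=True, exist_ok=True)
    sl_reports = []
    for s in config.second_level:
        cw = config.component_windows[s.x_component]
        subjects = [
            sub for sub in cohort.subjects
            if sub in maps[s.y_task] and sub in maps[cw.task]
        ]
        x = [
            window_score(
                maps[cw.task][sub], cw.electrode, cw.window,
                TASK_REGRESSOR[cw.task], s.x_component,
            )
            for sub in subjects
        ]
        traits = cohort.traits.set_index("subject").loc[subjects].reset_index()
        m_vals = _moderator_values(s.moderator, traits)
        fit = fit_moderated_map(
            [maps[s.y_task][sub] for sub in subjects], x, m_vals,
            y_regressor=TASK_REGRESSOR[s.y_task],
            moderator=s.moderator, x_component=s.x_component,
        )
        tag = f"{s.y_task}~{s.x_component}x{s.moderator}"
        fit.to_frame().to_csv(sl_dir / f"{tag}.tsv", sep="\t", index=False)
        masked = mask_map(fit, config.p_mask, "interaction")
        pk_int = fit.peak("interaction", p_mask=config.p_mask)
        entry = {
            "set": tag,
            "n_subjects": len(subjects),
            "y_task": s.y_task,
            "x_component": s.x_component,
            "moderator": s.moderator,
            "df": fit.df,
            "n_unmasked_interaction": masked["n_unmasked"],
            "main_peak": fit.peak("main"),
            "interaction_peak": pk_int,
        }
        if pk_int is not None:
            jn = fit.johnson_neyman(
                pk_int["electrode"], pk_int["time_ms"], threshold=config.jn_threshold
            )
            entry["jn"] = {
                "electrode": jn.electrode,
                "time_ms": jn.time_ms,
                "boundaries": jn.boundaries,
                "significant_intervals": jn.significant_intervals,
                "moderator_range": jn.moderator_range,
                "threshold": jn.threshold,
            }
        sl_reports.append(entry)
    report["second_level"] = sl_reports

    write_report(report, out)
    return report


def write_report(report: dict, out_dir) -> None:
    """Write the JSON run report and the TSV peak table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
    if report.get("peaks"):
        pd.DataFrame(report["peaks"]).to_csv(out / "peaks.tsv", sep="\t", index=False)
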