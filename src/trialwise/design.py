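"""Single-trial design matrices for the four tasks.

The predictor of interest is always a −1/+1 coded trial contrast (go −1 vs
nogo/successful-stop +1; gain −1 vs loss +1), accompanied by centred
nuisance regressors (inter-trial interval in seconds; arrow direction in
the SST). Design builders return the retained trial row indices so the
epoch array can be filtered consistently when rows are dropped (failed
stops, zero-point feedback).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, DesignError

__all__ = [
    "DesignMatrix",
    "build_design_gonogo",
    "build_design_sst",
    "build_design_feedback",
]


@dataclass
class DesignMatrix:
    """Named regressor columns with coding metadata.

    ``rows`` indexes the trials of the originating table that the design
    retains; ``X`` has one row per retained trial. The first column is the
    intercept.
    """

    names: list[str]
    X: np.ndarray
    rows: np.ndarray
    coding: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.rows = np.asarray(self.rows, dtype=int)
        if self.X.shape != (self.rows.size, len(self.names)):
            raise DesignError(
                f"design shape {self.X.shape} inconsistent with "
                f"{self.rows.size} rows x {len(self.names)} columns"
            )
        for j, name in enumerate(self.names):
            if name == "intercept":
                continue
            col = self.X[:, j]
            if np.ptp(col) == 0:
                raise DesignError(f"column {name!r} is constant; design is degenerate")
            if self.coding.get(name) == "pm1" and not np.isin(col, (-1.0, 1.0)).all():
                raise DesignError(f"column {name!r} must contain only -1/+1")

    @property
    def n_rows(self) -> int:
        return self.rows.size

    @property
    def n_cols(self) -> int:
        return len(self.names)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)


def _code_pm1(values, mapping, what: str) -> np.ndarray:
    values = np.asarray(values)
    unknown = set(np.unique(values)) - set(mapping)
    if unknown:
        raise DataError(f"unknown {what} level(s) {sorted(unknown)}; expected {sorted(mapping)}")
    return np.vectorize(mapping.get)(values).astype(float)


def build_design_gonogo(trial_table: pd.DataFrame) -> DesignMatrix:
    """[intercept, trial_type (go −1 / nogo +1), ITI centred (s)]."""
    tt = _code_pm1(trial_table["trial_type"], {"go": -1.0, "nogo": 1.0}, "trial_type")
    iti = trial_table["iti"].to_numpy(float)
    X = np.column_stack([np.ones(len(tt)), tt, iti - iti.mean()])
    return DesignMatrix(
        ["intercept", "trial_type", "iti"],
        X,
        np.arange(len(tt)),
        coding={"trial_type": "pm1", "iti": "centered"},
    )


def build_design_sst(trial_table: pd.DataFrame) -> DesignMatrix:
    """[intercept, trial_type (go −1 / successful stop +1), arrow_direction
    (−1/+1), ITI centred]. Failed-stop trials are dropped (the contrast is
    go vs *successful* stop); the count is recorded in ``n_dropped``."""
    tt = trial_table["trial_type"].to_numpy()
    unknown = set(np.unique(tt)) - {"go", "stop"}
    if unknown:
        raise DataError(f"unknown trial_type level(s) {sorted(unknown)}")
    keep = (tt == "go") | ((tt == "stop") & (trial_table["stop_success"].to_numpy() == 1.0))
    rows = np.nonzero(keep)[0]
    sub = trial_table.iloc[rows]
    contrast = np.where(sub["trial_type"] == "stop", 1.0, -1.0)
    arrow = _code_pm1(sub["arrow_direction"], {"left": -1.0, "right": 1.0}, "arrow_direction")
    iti = sub["iti"].to_numpy(float)
    X = np.column_stack([np.ones(rows.size), contrast, arrow, iti - iti.mean()])
    return DesignMatrix(
        ["intercept", "trial_type", "arrow_direction", "iti"],
        X,
        rows,
        coding={"trial_type": "pm1", "arrow_direction": "pm1", "iti": "centered"},
        n_dropped=int(len(trial_table) - rows.size),
    )


def build_design_feedback(
    trial_table: pd.DataFrame, task: str, miflat_coding: str = "context"
) -> DesignMatrix:
    """Feedback-valence design, [intercept, valence].

    MIFLAT codes valence at the context level by default: gain context −1,
    loss-avoidance context +1, all feedback trials retained
    (``miflat_coding='outcome'`` instead codes the delivered outcome,
    positive feedback −1 / negative +1). Two-step drops zero-point feedback
    and codes losses (< 0 points) +1, gains (> 0) −1.
    """
    if task == "miflat":
        if miflat_coding == "context":
            valence = _code_pm1(
                trial_table["context"], {"gain": -1.0, "loss_avoidance": 1.0}, "context"
            )
        elif miflat_coding == "outcome":
            valence = _code_pm1(
                trial_table["outcome"],
                {"gain": -1.0, "loss_omission": -1.0, "gain_omission": 1.0, "loss": 1.0},
                "outcome",
            )
        else:
            raise DataError(f"miflat_coding must be context|outcome, got {miflat_coding!r}")
        rows = np.arange(len(trial_table))
        dropped = 0
    elif task == "twostep":
        points = trial_table["outcome_points"].to_numpy(float)
        rows = np.nonzero(points != 0)[0]
        if rows.size == 0:
            raise DesignError("all two-step outcomes are zero points; design is empty")
        valence = np.where(points[rows] < 0, 1.0, -1.0)
        dropped = int(len(trial_table) - rows.size)
    else:
        raise DataError(f"feedback design is defined for miflat|twostep, got {task!r}")
    X = np.column_stack([np.ones(rows.size), valence])
    return DesignMatrix(
        ["intercept", "valence"], X, rows, coding={"valence": "pm1"}, n_dropped=dropped
    )


def build_design(trial_table: pd.DataFrame, task: str) -> DesignMatrix:
    """Dispatch to the task-appropriate design builder."""
    if task == "gonogo":
        return build_design_gonogo(trial_table)
    if task == "sst":
        return build_design_sst(trial_table)
    return build_design_feedback(trial_table, task)
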