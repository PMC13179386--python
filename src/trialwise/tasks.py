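"""Task event-stream simulators.

Four tasks are emulated at the fidelity the downstream regressions need:

* go/nogo — withhold a prepotent response on exactly 25% of trials;
* stop-signal (SST) — stop an initiated response on exactly 25% of trials,
  with a staircase-tracked stop-signal delay holding stop success near 50%
  under an independent horse-race model;
* monetary incentive flanker (MIFLAT) — balanced potential-gain and
  loss-avoidance contexts with performance-contingent feedback;
* two-step — 80/20 common/rare first-stage transitions and a point outcome
  following a Gaussian-step random walk reflected at +5 and −4 points.

Each simulator returns a :class:`TaskEvents` with a per-trial DataFrame and
is fully deterministic given its seed. Choice behaviour (e.g. two-step
first-stage choices) is random: the simulators reproduce the statistical
structure of the event streams, not reinforcement learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "TaskEvents",
    "SSTRespondent",
    "Staircase",
    "RewardWalk",
    "simulate_gonogo_events",
    "simulate_sst_events",
    "simulate_miflat_events",
    "simulate_twostep_events",
]

ITI_RANGE_S = (0.8, 1.2)  # uniform inter-trial-interval jitter, seconds


@dataclass
class TaskEvents:
    """Event stream for one task: a label plus one row per trial."""

    task: str
    trials: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _itis(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(*ITI_RANGE_S, size=n)


# ---------------------------------------------------------------------------
# go/nogo
# ---------------------------------------------------------------------------

def simulate_gonogo_events(n_trials: int, seed=None) -> TaskEvents:
    """Go/nogo event stream with exactly 25% nogo trials in random order."""
    if n_trials % 4 != 0:
        raise ParameterError(f"n_trials must be divisible by 4 (25% nogo), got {n_trials}")
    rng = np.random.default_rng(seed)
    n_nogo = n_trials // 4
    types = np.array(["nogo"] * n_nogo + ["go"] * (n_trials - n_nogo))
    rng.shuffle(types)
    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "trial_type": types,
            "iti": _itis(rng, n_trials),
        }
    )
    return TaskEvents("gonogo", table, {"n_trials": n_trials})


# ---------------------------------------------------------------------------
# stop-signal task
# ---------------------------------------------------------------------------

@dataclass
class SSTRespondent:
    """Independent-race respondent: Gaussian go-RT and stop-process finish
    times (ms). A stop succeeds iff SSD + stop finish < go finish."""

    go_mu: float = 450.0
    go_sd: float = 80.0
    stop_mu: float = 200.0
    stop_sd: float = 40.0

    def validate(self):
        if self.go_sd <= 0 or self.stop_sd < 0:
            raise ParameterError(
                f"respondent RT scales must be positive (go_sd={self.go_sd}, stop_sd={self.stop_sd})"
            )


@dataclass
class Staircase:
    """One-up/one-down SSD tracker: +step after a successful stop, −step
    after a failed one, floored at 0 ms."""

    initial_ssd: float = 200.0
    step: float = 50.0

    def validate(self):
        if self.initial_ssd <= 0:
            raise ParameterError(f"initial SSD must be > 0, got {self.initial_ssd}")
        if self.step <= 0:
            raise ParameterError(f"staircase step must be > 0, got {self.step}")


def simulate_sst_events(
    n_trials: int,
    respondent: SSTRespondent | None = None,
    staircase: Staircase | None = None,
    seed=None,
) -> TaskEvents:
    """Stop-signal event stream: exactly 25% stop trials, staircase SSD.

    With overlapping continuous finish-time distributions the one-up/one-down
    staircase converges to ~50% successful stops.
    """
    if n_trials % 4 != 0:
        raise ParameterError(f"n_trials must be divisible by 4 (25% stop), got {n_trials}")
    respondent = respondent or SSTRespondent()
    staircase = staircase or Staircase()
    respondent.validate()
    staircase.validate()
    rng = np.random.default_rng(seed)
    n_stop = n_trials // 4
    is_stop = np.array([True] * n_stop + [False] * (n_trials - n_stop))
    rng.shuffle(is_stop)
    arrows = rng.choice(["left", "right"], size=n_trials)
    go_rt = rng.normal(respondent.go_mu, respondent.go_sd, size=n_trials)
    stop_finish = rng.normal(respondent.stop_mu, respondent.stop_sd, size=n_trials)

    ssd = float(staircase.initial_ssd)
    ssds = np.full(n_trials, np.nan)
    success = np.full(n_trials, np.nan)
    for i in range(n_trials):
        if is_stop[i]:
            ssds[i] = ssd
            won = ssd + stop_finish[i] < go_rt[i]
            success[i] = float(won)
            ssd = max(0.0, ssd + staircase.step if won else ssd - staircase.step)
    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "trial_type": np.where(is_stop, "stop", "go"),
            "arrow_direction": arrows,
            "iti": _itis(rng, n_trials),
            "ssd_ms": ssds,
            "stop_success": success,
            "go_rt_ms": go_rt,
        }
    )
    return TaskEvents(
        "sst",
        table,
        {
            "n_trials": n_trials,
            "stop_success_rate": float(np.nanmean(success)),
            "respondent": vars(respondent),
            "staircase": vars(staircase),
        },
    )


# ---------------------------------------------------------------------------
# monetary incentive flanker task
# ---------------------------------------------------------------------------

def simulate_miflat_events(
    n_trials: int,
    error_rate: float = 0.1,
    slow_rate: float = 0.15,
    seed=None,
) -> TaskEvents:
    """MIFLAT event stream: balanced gain / loss-avoidance contexts.

    In the potential-gain context a fast correct response yields a gain and a
    bad (erroneous or slow) one a gain omission; in the loss-avoidance
    context a bad response yields a loss and a good one a loss omission.
    """
    if n_trials % 2 != 0:
        raise ParameterError(f"n_trials must be even for balanced contexts, got {n_trials}")
    for name, r in (("error_rate", error_rate), ("slow_rate", slow_rate)):
        if not 0 <= r <= 1:
            raise ParameterError(f"{name} must be in [0, 1], got {r}")
    p_bad = min(1.0, error_rate + slow_rate)
    rng = np.random.default_rng(seed)
    contexts = np.array(["gain"] * (n_trials // 2) + ["loss_avoidance"] * (n_trials // 2))
    rng.shuffle(contexts)
    bad = rng.random(n_trials) < p_bad
    outcome = np.where(
        contexts == "gain",
        np.where(bad, "gain_omission", "gain"),
        np.where(bad, "loss", "loss_omission"),
    )
    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "context": contexts,
            "outcome": outcome,
            "iti": _itis(rng, n_trials),
        }
    )
    return TaskEvents(
        "miflat",
        table,
        {"n_trials": n_trials, "error_rate": error_rate, "slow_rate": slow_rate},
    )


# ---------------------------------------------------------------------------
# two-step task
# ---------------------------------------------------------------------------

@dataclass
class RewardWalk:
    """Gaussian-step reward walk reflected at integer point bounds."""

    step_sd: float = 1.0
    lower: float = -4.0
    upper: float = 5.0
    start: float = 0.0

    def validate(self):
        if not self.lower < 0 < self.upper:
            raise ParameterError(
                f"walk bounds must straddle zero with lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.step_sd < 0:
            raise ParameterError(f"step sd must be >= 0, got {self.step_sd}")


def _reflect(x: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Fold a free walk into [lower, upper] by iterated boundary reflection
    (triangle-wave map with period 2*(upper-lower))."""
    span = upper - lower
    y = np.mod(x - lower, 2 * span)
    return lower + np.where(y <= span, y, 2 * span - y)


def simulate_twostep_events(
    n_trials: int,
    walk: RewardWalk | None = None,
    p_common: float = 0.8,
    seed=None,
) -> TaskEvents:
    """Two-step event stream: 80/20 common/rare transitions and a reflected
    reward walk emitting integer point outcomes within [lower, upper].

    First-stage choices are random (no learning model); the emitted
    ``outcome_points`` are the reflected walk rounded to the nearest
    integer, so the bounds (+5 space treasure, −4 anti-matter) are
    attainable. Zero-point outcomes are legal here and only excluded later
    by design building.
    """
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    if not 0 < p_common < 1:
        raise ParameterError(f"p_common must be in (0, 1), got {p_common}")
    walk = walk or RewardWalk()
    walk.validate()
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, 2, size=n_trials)
    common = rng.random(n_trials) < p_common
    planet = np.where(common, choice, 1 - choice)
    steps = rng.normal(0.0, walk.step_sd, size=n_trials) if walk.step_sd > 0 else np.zeros(n_trials)
    state = _reflect(walk.start + np.cumsum(steps), walk.lower, walk.upper)
    points = np.rint(state).astype(int)
    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "choice": choice,
            "transition_type": np.where(common, "common", "rare"),
            "planet": planet,
            "outcome_points": points,
            "iti": _itis(rng, n_trials),
        }
    )
    return TaskEvents(
        "twostep",
        table,
        {"n_trials": n_trials, "p_common": p_common, "walk": vars(walk)},
    )
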