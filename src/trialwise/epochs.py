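"""Epoched EEG container, bundle I/O, and single-subject preprocessing.

An :class:`EpochSet` holds a ``[trial, channel, time]`` voltage array (µV)
together with the channel names, the time axis in milliseconds relative to
the locking event, the sampling rate and a per-trial covariate table. The
preprocessing operators implemented here are the ones the two-level analysis
applies to epochs before fitting:

* baseline correction against the pre-stimulus window,
* 5-point centred temporal smoothing,
* rejection of statistically improbable epochs,
* restriction to the analysis window.

Every operator returns a new :class:`EpochSet`, preserves trial-table
alignment and channel order, and appends a line to the provenance log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .exceptions import DataError, FormatError, ParameterError

__all__ = [
    "EpochSet",
    "write_bundle",
    "read_bundle",
    "baseline_correct",
    "smooth_temporal",
    "reject_improbable",
    "select_analysis_window",
    "pick_channels",
]

_TIME_TOL = 1e-6


@dataclass
class EpochSet:
    """Trials × channels × time voltage array with aligned trial covariates.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Voltages in µV.
    channels : list of str
        Unique channel names, ordered as the channel axis.
    times : ndarray
        Sample times in ms relative to the locking event; strictly
        increasing and uniformly spaced at ``1000 / fs``.
    fs : float
        Sampling rate in Hz.
    trial_table : pandas.DataFrame
        One row per trial, aligned to the trial axis.
    provenance : dict
        Carries ``subject``, ``task`` and an applied-operations ``log``.
    """

    data: np.ndarray
    channels: list[str]
    times: np.ndarray
    fs: float
    trial_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise DataError(f"data must be 3-D [trial, channel, time], got ndim={self.data.ndim}")
        n_tr, n_ch, n_t = self.data.shape
        if len(self.channels) != n_ch:
            raise DataError(f"{len(self.channels)} channel names for channel axis of length {n_ch}")
        if len(set(self.channels)) != len(self.channels):
            raise DataError("channel names must be unique")
        if self.times.shape != (n_t,):
            raise DataError(f"times length {self.times.size} != time axis length {n_t}")
        if n_t > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise DataError("times must be strictly increasing")
            expected = 1000.0 / self.fs
            if np.any(np.abs(steps - expected) > _TIME_TOL * max(1.0, expected)):
                raise DataError(f"times must be uniformly spaced at {expected} ms (1000/fs)")
        if len(self.trial_table) != n_tr:
            raise DataError(
                f"trial_table has {len(self.trial_table)} rows but data has {n_tr} trials"
            )
        self.provenance = dict(self.provenance)
        self.provenance.setdefault("log", [])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise DataError(f"channel {name!r} not in montage {self.channels}") from None

    def _logged(self, message: str, **changes) -> "EpochSet":
        prov = dict(self.provenance)
        prov["log"] = list(prov.get("log", [])) + [message]
        return replace(self, provenance=prov, **changes)

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            list(self.channels),
            self.times.copy(),
            self.fs,
            self.trial_table.copy(),
            {**self.provenance, "log": list(self.provenance.get("log", []))},
        )


# ---------------------------------------------------------------------------
# Bundle I/O: directory with JSON manifest, little-endian float32 raw array,
# and a TSV trial table. Deliberately language-agnostic and diff-able.
# ---------------------------------------------------------------------------

def write_bundle(epochs: EpochSet, path) -> None:
    """Write an epoch bundle (manifest.json + data.f32 + trial_table.tsv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": "epoch-bundle",
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "fs": float(epochs.fs),
        "channels": list(epochs.channels),
        "times_ms": [float(t) for t in epochs.times],
        "subject": epochs.provenance.get("subject"),
        "task": epochs.provenance.get("task"),
        "log": list(epochs.provenance.get("log", [])),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    epochs.data.astype("<f4").tofile(path / "data.f32")
    epochs.trial_table.to_csv(path / "trial_table.tsv", sep="\t", index=False)


def read_bundle(path) -> EpochSet:
    """Read an epoch bundle, validating array shape against the manifest."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    shape = tuple(manifest["shape"])
    raw = np.fromfile(path / "data.f32", dtype="<f4")
    expected = int(np.prod(shape))
    if raw.size != expected:
        raise FormatError(
            f"data.f32 holds {raw.size} values but manifest shape {shape} needs {expected}"
        )
    table = pd.read_csv(path / "trial_table.tsv", sep="\t")
    if len(table) != shape[0]:
        raise FormatError(
            f"trial_table has {len(table)} rows but manifest declares {shape[0]} trials"
        )
    if len(manifest["channels"]) != shape[1]:
        raise FormatError(
            f"manifest names {len(manifest['channels'])} channels for axis of length {shape[1]}"
        )
    return EpochSet(
        raw.reshape(shape).astype(float),
        manifest["channels"],
        np.asarray(manifest["times_ms"], dtype=float),
        manifest["fs"],
        table,
        {
            "subject": manifest.get("subject"),
            "task": manifest.get("task"),
            "log": manifest.get("log", []),
        },
    )


# ---------------------------------------------------------------------------
# Preprocessing operators
# ---------------------------------------------------------------------------

def baseline_correct(epochs: EpochSet, window=(-200.0, 0.0)) -> EpochSet:
    """Subtract the mean over the pre-stimulus ``[lo, hi)`` window per
    trial and channel. Default window is the 200 ms pre-stimulus interval."""
    lo, hi = float(window[0]), float(window[1])
    mask = (epochs.times >= lo - _TIME_TOL) & (epochs.times < hi - _TIME_TOL)
    if not mask.any():
        raise ParameterError(f"baseline window [{lo}, {hi}) contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs._logged(f"baseline_correct([{lo}, {hi}))", data=epochs.data - base)


def smooth_temporal(epochs: EpochSet) -> EpochSet:
    """5-point centred moving average along time.

    Each sample is averaged with its two preceding and two succeeding
    samples; at the edges the window truncates to the available samples.
    The operator is linear.
    """
    if epochs.n_times < 5:
        raise ParameterError(f"smoothing needs >=5 time samples, got {epochs.n_times}")
    kernel = np.ones(5)
    sums = convolve1d(epochs.data, kernel, axis=2, mode="constant", cval=0.0)
    counts = convolve1d(np.ones(epochs.n_times), kernel, mode="constant", cval=0.0)
    return epochs._logged("smooth_temporal(5-point)", data=sums / counts)


def reject_improbable(epochs: EpochSet, z_thresh: float = 5.0):
    """Reject epochs that are improbable relative to all epochs.

    For every (channel, time) cell a Gaussian is fitted across trials; each
    epoch's improbability score is the mean negative log-density over all
    cells. Epochs whose score exceeds ``mean + z_thresh * SD`` of the score
    distribution are removed in a single pass.

    Returns ``(cleaned EpochSet, ndarray of rejected trial indices)``.
    """
    if epochs.n_trials < 8:
        raise ParameterError(f"improbable-epoch rejection needs >=8 trials, got {epochs.n_trials}")
    if not z_thresh > 0:
        raise ParameterError(f"z_thresh must be > 0, got {z_thresh}")
    mu = epochs.data.mean(axis=0)
    sd = epochs.data.std(axis=0)
    ok = sd > 0
    if not ok.any():
        warnings.warn("all epochs identical at every cell; nothing rejected")
        return epochs._logged(f"reject_improbable(z={z_thresh}, rejected=0)"), np.array([], int)
    # negative log Gaussian density up to the additive constant, averaged
    # over cells with across-trial variance
    n_ok = int(ok.sum())
    safe_sd = np.where(ok, sd, 1.0)
    z2 = ((epochs.data - mu) / safe_sd) ** 2
    scores = (
        0.5 * np.where(ok, z2, 0.0).reshape(epochs.n_trials, -1).sum(axis=1)
        + np.log(safe_sd, where=ok, out=np.zeros_like(sd)).sum()
    ) / n_ok
    s_sd = scores.std()
    if np.isinf(z_thresh) or s_sd == 0:
        rejected = np.array([], dtype=int)
    else:
        rejected = np.nonzero(scores > scores.mean() + z_thresh * s_sd)[0]
    keep = np.setdiff1d(np.arange(epochs.n_trials), rejected)
    out = epochs._logged(
        f"reject_improbable(z={z_thresh}, rejected={rejected.size})",
        data=epochs.data[keep],
        trial_table=epochs.trial_table.iloc[keep].reset_index(drop=True),
    )
    return out, rejected


def pick_channels(epochs: EpochSet, names) -> EpochSet:
    """Restrict the channel axis to the named electrodes (given order)."""
    idx = [epochs.channel_index(n) for n in names]
    if not idx:
        raise ParameterError("empty channel selection")
    return epochs._logged(
        f"pick_channels({list(names)})",
        data=epochs.data[:, idx],
        channels=[epochs.channels[i] for i in idx],
    )


def select_analysis_window(epochs: EpochSet, interval=(-100.0, 700.0)) -> EpochSet:
    """Restrict the time axis to ``[lo, hi]``, endpoints inclusive.

    At 500 Hz the default −100…700 ms window retains 401 samples.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if lo < epochs.times[0] - _TIME_TOL or hi > epochs.times[-1] + _TIME_TOL:
        raise ParameterError(
            f"analysis window [{lo}, {hi}] outside time axis "
            f"[{epochs.times[0]}, {epochs.times[-1]}]"
        )
    mask = (epochs.times >= lo - _TIME_TOL) & (epochs.times <= hi + _TIME_TOL)
    return epochs._logged(
        f"select_analysis_window([{lo}, {hi}])",
        data=epochs.data[:, :, mask],
        times=epochs.times[mask],
    )
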