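"""Synthetic multi-subject ERP cohort with known ground truth.

The generator embodies the statistical structure the two-level analysis
assumes, so every stage of the pipeline can be verified against known
parameters:

* per-subject questionnaire traits (compulsivity = OCI-R sum 0–72, negative
  urgency sum 12–48) drawn from a correlated bivariate normal, rounded and
  clipped to the theoretical ranges;
* a latent per-subject feedback-effect amplitude (µV per coding unit)
  expressed in the MIFLAT and (with a loading) in the two-step task;
* inhibition-effect amplitudes (go/nogo, SST) coupled to the feedback
  amplitude with a slope that changes linearly with the moderating trait —
  the moderated brain–brain relationship the second level estimates;
* epochs built as drift + condition-dependent component (spatial template ×
  half-cosine temporal kernel × amplitude) + AR(1)-in-time, spatially mixed
  Gaussian noise with occasional high-variance outlier epochs.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .exceptions import ParameterError
from .tasks import (
    RewardWalk,
    SSTRespondent,
    Staircase,
    TaskEvents,
    simulate_gonogo_events,
    simulate_miflat_events,
    simulate_sst_events,
    simulate_twostep_events,
)

__all__ = [
    "DEFAULT_MONTAGE",
    "DESK_MONTAGE",
    "ComponentSpec",
    "NoiseModel",
    "CohortConfig",
    "SyntheticTruth",
    "Cohort",
    "simulate_traits",
    "synthesize_epochs",
    "make_cohort",
]

# 19-channel montage covering every electrode named in downstream reports.
DEFAULT_MONTAGE = [
    "Fz", "F1", "F2", "FC1", "FC2", "FCz", "Cz", "CPz", "CP1", "CP2",
    "CP4", "Pz", "P1", "P2", "PO2", "POz", "Oz", "P10", "IO1",
]
# 16-channel desk-scale montage (all named electrodes, fewer fillers).
DESK_MONTAGE = [
    "Fz", "FC1", "FC2", "FCz", "Cz", "CPz", "CP1", "CP2", "CP4",
    "Pz", "P1", "P2", "PO2", "POz", "P10", "IO1",
]

TRAIT_RANGES = {"oci_r": (0, 72), "negative_urgency": (12, 48)}


@dataclass
class ComponentSpec:
    """An ERP component: spatial centre, temporal peak, half-cosine width.

    The temporal kernel is ``cos(pi * (t - peak) / width)`` on
    ``|t - peak| <= width / 2`` (peak value 1), the spatial template a
    Gaussian falloff over montage-order distance from the centre channel.
    """

    channel: str
    peak_ms: float
    width_ms: float = 300.0
    spatial_sigma: float = 2.0

    def kernel(self, times: np.ndarray) -> np.ndarray:
        u = (times - self.peak_ms) / self.width_ms
        return np.where(np.abs(u) <= 0.5, np.cos(np.pi * u), 0.0)

    def template(self, montage: list[str]) -> np.ndarray:
        if self.channel not in montage:
            raise ParameterError(f"component channel {self.channel!r} not in montage")
        d = np.arange(len(montage)) - montage.index(self.channel)
        return np.exp(-(d**2) / (2 * self.spatial_sigma**2))


@dataclass
class NoiseModel:
    """AR(1)-in-time, spatially mixed Gaussian noise with outlier epochs."""

    ar_coef: float = 0.9
    sd: float = 5.0
    outlier_rate: float = 0.05
    outlier_scale: float = 8.0
    drift_sd: float = 2.0

    def validate(self):
        if not -1 < self.ar_coef < 1:
            raise ParameterError(f"AR coefficient must be in (-1, 1), got {self.ar_coef}")
        if self.sd < 0 or self.drift_sd < 0:
            raise ParameterError("noise SDs must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ParameterError(f"outlier rate must be in [0, 1), got {self.outlier_rate}")
        if self.outlier_scale < 1:
            raise ParameterError(f"outlier scale must be >= 1, got {self.outlier_scale}")


DEFAULT_COMPONENTS = {
    "gonogo": ComponentSpec("Cz", 360.0),
    "sst": ComponentSpec("P2", 560.0),
    "miflat": ComponentSpec("Pz", 510.0),
    "twostep": ComponentSpec("CP1", 450.0),
}


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(
    n: int,
    means=(12.6, 26.3),
    sds=(9.5, 5.9),
    rho: float = 0.18,
    seed=None,
) -> pd.DataFrame:
    """Draw per-subject (OCI-R, negative urgency) sums.

    Bivariate normal with correlation ``rho``, rounded to integers and
    clipped to the theoretical ranges (0–72 and 12–48). Defaults are the
    sample moments of the study population the generator emulates.
    """
    if n < 3:
        raise ParameterError(f"need at least 3 subjects, got {n}")
    if not abs(rho) < 1:
        raise ParameterError(f"|rho| must be < 1, got {rho}")
    if sds[0] <= 0 or sds[1] <= 0:
        raise ParameterError(f"trait SDs must be > 0, got {sds}")
    rng = np.random.default_rng(seed)
    cov = [[sds[0] ** 2, rho * sds[0] * sds[1]], [rho * sds[0] * sds[1], sds[1] ** 2]]
    raw = rng.multivariate_normal(means, cov, size=n)
    oci = np.clip(np.rint(raw[:, 0]), *TRAIT_RANGES["oci_r"]).astype(int)
    nu = np.clip(np.rint(raw[:, 1]), *TRAIT_RANGES["negative_urgency"]).astype(int)
    return pd.DataFrame(
        {"subject": [f"sub-{i:03d}" for i in range(n)], "oci_r": oci, "negative_urgency": nu}
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Generator parameters plus the realised per-subject amplitudes.

    ``subject_effects`` has one row per subject with the traits, the latent
    feedback amplitude ``F`` and the per-task effect amplitudes actually
    injected into the epochs; recovery tests compare pipeline estimates
    against these columns and against ``coupling`` / ``moderation``.
    """

    fb_mean: float
    fb_sd: float
    ts_mean: float
    ts_loading: float
    ts_noise_sd: float
    gng_mean: float
    sst_mean: float
    inh_noise_sd: float
    coupling: float
    moderation: float
    moderator: str
    trait_means: tuple
    trait_sds: tuple
    trait_rho: float
    noise: NoiseModel
    components: dict
    subject_effects: pd.DataFrame

    def validate(self):
        if self.fb_sd < 0 or self.ts_noise_sd < 0 or self.inh_noise_sd < 0:
            raise ParameterError("amplitude SDs must be >= 0")
        self.noise.validate()

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["noise"] = asdict(self.noise)
        payload["components"] = {k: asdict(v) for k, v in self.components.items()}
        payload["subject_effects"] = self.subject_effects.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["noise"] = NoiseModel(**payload["noise"])
        payload["components"] = {
            k: ComponentSpec(**v) for k, v in payload["components"].items()
        }
        payload["subject_effects"] = pd.DataFrame(payload["subject_effects"])
        payload["trait_means"] = tuple(payload["trait_means"])
        payload["trait_sds"] = tuple(payload["trait_sds"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# epoch synthesis
# ---------------------------------------------------------------------------

_CODERS = {
    "gonogo": lambda t: np.where(t["trial_type"] == "nogo", 1.0, -1.0),
    "sst": lambda t: np.where(
        (t["trial_type"] == "stop") & (t["stop_success"] == 1.0),
        1.0,
        np.where(t["trial_type"] == "go", -1.0, 0.0),
    ),
    "miflat": lambda t: np.where(t["context"] == "loss_avoidance", 1.0, -1.0),
    "twostep": lambda t: np.sign(-t["outcome_points"]).astype(float),
}


def condition_codes(events: TaskEvents) -> np.ndarray:
    """Ground-truth condition coding used by the forward model (matches the
    design coding: inhibition/loss +1, go/gain −1, neutral 0)."""
    return np.asarray(_CODERS[events.task](events.trials), dtype=float)


def synthesize_epochs(
    events: TaskEvents,
    base: float,
    effect: float,
    component: ComponentSpec,
    noise: NoiseModel | None = None,
    montage: list[str] | None = None,
    fs: float = 100.0,
    window=(-200.0, 700.0),
    seed=None,
    subject: str | None = None,
) -> EpochSet:
    """Forward-model epochs for one subject and task.

    Each epoch is ``drift + (base + effect × code) × template × kernel +
    noise`` where ``code`` is the ±1 condition coding of the trial, so a
    single-trial regression of the epochs on the coded condition recovers
    ``effect`` at the component's spatiotemporal peak.
    """
    noise = noise or NoiseModel()
    noise.validate()
    montage = list(montage or DESK_MONTAGE)
    lo, hi = float(window[0]), float(window[1])
    if lo > -200.0 or hi < 700.0:
        raise ParameterError(f"epoch window must cover [-200, 700] ms, got [{lo}, {hi}]")
    step = 1000.0 / fs
    times = np.arange(lo, hi + step / 2, step)
    kernel = component.kernel(times)
    if not kernel.any():
        raise ParameterError(
            f"window [{lo}, {hi}] does not cover the component peak at {component.peak_ms} ms"
        )
    template = component.template(montage)
    codes = condition_codes(events)
    n, c, t = len(codes), len(montage), len(times)
    rng = np.random.default_rng(seed)

    amp = base + effect * codes  # (n,)
    signal = amp[:, None, None] * template[None, :, None] * kernel[None, None, :]
    drift = rng.normal(0.0, noise.drift_sd, size=(n, c, 1))
    innov = rng.normal(0.0, noise.sd * np.sqrt(1 - noise.ar_coef**2), size=(n, c, t))
    # AR(1) along time as a lower-triangular convolution (BLAS matmul)
    idx = np.arange(t)
    lag = idx[:, None] - idx[None, :]
    ar_l = np.where(lag >= 0, noise.ar_coef ** np.maximum(lag, 0), 0.0)
    eps = innov @ ar_l.T
    q, _ = np.linalg.qr(rng.normal(size=(c, c)))
    eps = np.matmul(q, eps)
    if noise.outlier_rate > 0:
        outlier = rng.random(n) < noise.outlier_rate
        eps[outlier] *= noise.outlier_scale
    return EpochSet(
        signal + drift + eps,
        montage,
        times,
        fs,
        events.trials.copy(),
        {"subject": subject, "task": events.task, "log": ["synthesize_epochs"]},
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Desk-scale cohort defaults; every field is overridable.

    Effect scales are anchored to the group statistics the analysis is
    meant to reproduce: mean feedback-valence b ≈ 4 µV with between-subject
    SD ≈ 2.4 µV, inhibition b ≈ 5–6 µV, coupling 0.54 µV/µV and moderation
    −0.03 µV/µV per OCI-R unit.
    """

    n_subjects: int = 40
    channels: list = field(default_factory=lambda: list(DESK_MONTAGE))
    fs: float = 100.0
    window: tuple = (-200.0, 700.0)
    tasks: dict = field(
        default_factory=lambda: {"gonogo": 160, "sst": 160, "miflat": 120, "twostep": 120}
    )
    trait_means: tuple = (12.6, 26.3)
    trait_sds: tuple = (9.5, 5.9)
    trait_rho: float = 0.18
    fb_mean: float = 4.0
    fb_sd: float = 2.4
    ts_mean: float = 4.1
    ts_loading: float = 0.7
    ts_noise_sd: float = 1.5
    gng_mean: float = 6.25
    sst_mean: float = 4.86
    inh_noise_sd: float = 2.8
    coupling: float = 0.54
    moderation: float = -0.03
    moderator: str = "oci_r"
    noise: NoiseModel = field(default_factory=NoiseModel)
    components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    miflat_error_rate: float = 0.1
    miflat_slow_rate: float = 0.15
    sst_respondent: SSTRespondent = field(default_factory=SSTRespondent)
    sst_staircase: Staircase = field(default_factory=Staircase)
    twostep_walk: RewardWalk = field(default_factory=RewardWalk)

    def validate(self):
        missing = {"gonogo", "sst", "miflat", "twostep"} - set(self.tasks)
        if missing:
            raise ParameterError(f"cohort config must name all four tasks; missing {sorted(missing)}")
        if self.n_subjects < 3:
            raise ParameterError(f"need at least 3 subjects, got {self.n_subjects}")
        if self.moderator not in TRAIT_RANGES:
            raise ParameterError(f"moderator must be one of {sorted(TRAIT_RANGES)}")
        for task, comp in self.components.items():
            if comp.channel not in self.channels:
                raise ParameterError(
                    f"{task} component channel {comp.channel!r} not in montage"
                )
        self.noise.validate()


@dataclass
class Cohort:
    """Generated cohort: traits, per-subject per-task epochs, ground truth."""

    traits: pd.DataFrame
    epochs: dict  # subject id -> {task -> EpochSet}
    truth: SyntheticTruth

    @property
    def subjects(self) -> list:
        return list(self.traits["subject"])


_EVENT_SIMULATORS = {
    "gonogo": lambda cfg, n, seed: simulate_gonogo_events(n, seed=seed),
    "sst": lambda cfg, n, seed: simulate_sst_events(
        n, respondent=cfg.sst_respondent, staircase=cfg.sst_staircase, seed=seed
    ),
    "miflat": lambda cfg, n, seed: simulate_miflat_events(
        n, error_rate=cfg.miflat_error_rate, slow_rate=cfg.miflat_slow_rate, seed=seed
    ),
    "twostep": lambda cfg, n, seed: simulate_twostep_events(
        n, walk=cfg.twostep_walk, seed=seed
    ),
}


def make_cohort(config: CohortConfig | None = None, seed=None) -> Cohort:
    """Generate a full synthetic cohort with known ground truth.

    The between-subject coupling between the inhibition-effect and the
    feedback-effect amplitude equals ``coupling + moderation × (trait −
    trait mean)`` exactly as recorded in the returned
    :class:`SyntheticTruth`. Deterministic given ``(config, seed)``.
    """
    config = config or CohortConfig()
    config.validate()
    root = np.random.SeedSequence(seed)
    trait_seed, amp_seed, *rest = root.spawn(2 + config.n_subjects)

    traits = simulate_traits(
        config.n_subjects, config.trait_means, config.trait_sds, config.trait_rho,
        seed=trait_seed,
    )
    rng = np.random.default_rng(amp_seed)
    # centre the moderator at the realised cohort mean (rounding/clipping to
    # the theoretical range shifts it off the nominal trait mean), so the
    # coupling contract holds exactly within the cohort
    m = traits[config.moderator].to_numpy(float)
    m_c = m - m.mean()

    f = rng.normal(config.fb_mean, config.fb_sd, size=config.n_subjects)
    f_c = f - config.fb_mean
    eff = {
        "miflat": f,
        "twostep": config.ts_mean
        + config.ts_loading * f_c
        + rng.normal(0.0, config.ts_noise_sd, size=config.n_subjects),
        "gonogo": config.gng_mean
        + (config.coupling + config.moderation * m_c) * f_c
        + rng.normal(0.0, config.inh_noise_sd, size=config.n_subjects),
        "sst": config.sst_mean
        + (config.coupling + config.moderation * m_c) * f_c
        + rng.normal(0.0, config.inh_noise_sd, size=config.n_subjects),
    }
    effects = traits.copy()
    effects["F"] = f
    for task in ("gonogo", "sst", "miflat", "twostep"):
        effects[f"eff_{task}"] = eff[task]

    truth = SyntheticTruth(
        fb_mean=config.fb_mean, fb_sd=config.fb_sd,
        ts_mean=config.ts_mean, ts_loading=config.ts_loading,
        ts_noise_sd=config.ts_noise_sd,
        gng_mean=config.gng_mean, sst_mean=config.sst_mean,
        inh_noise_sd=config.inh_noise_sd,
        coupling=config.coupling, moderation=config.moderation,
        moderator=config.moderator,
        trait_means=tuple(config.trait_means), trait_sds=tuple(config.trait_sds),
        trait_rho=config.trait_rho,
        noise=replace(config.noise),
        components=dict(config.components),
        subject_effects=effects,
    )
    truth.validate()

    base = {"gonogo": 2.0, "sst": 2.0, "miflat": 2.0, "twostep": 2.0}
    epochs: dict = {}
    for i, (subject, subj_seed) in enumerate(zip(traits["subject"], rest)):
        per_task = {}
        for task, (ev_seed, ep_seed) in zip(
            sorted(config.tasks), zip(*[iter(subj_seed.spawn(2 * len(config.tasks)))] * 2)
        ):
            events = _EVENT_SIMULATORS[task](config, config.tasks[task], ev_seed)
            per_task[task] = synthesize_epochs(
                events,
                base=base[task],
                effect=float(eff[task][i]),
                component=config.components[task],
                noise=config.noise,
                montage=config.channels,
                fs=config.fs,
                window=config.window,
                seed=ep_seed,
                subject=subject,
            )
        epochs[subject] = per_task
    return Cohort(traits=traits, epochs=epochs, truth=truth)
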