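"""Synthetic change-point Bernoulli task and synthetic subjects.

The environment is the classic ring-drawing task: on every trial a ring is
drawn green with hidden probability ``p``; after every draw ``p`` is replaced
by a fresh Uniform(0,1) draw with a small, fixed hazard.  Synthetic subjects
report a distorted, noisy transform of the ideal-observer forecast, adjust
the slider only on a random subset of trials (step-hold reporting), and have
lognormal response times whose location can be coupled to the distortion
slope (more repulsive subjects responding faster).

Defaults mirror the study design the analysis targets: 11 subjects, 10
sessions of 1,000 draws, hazard 0.005, an 8.8% marginal adjustment rate, and
reports clamped into [0.01, 0.99].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import BehaviorDataset, ConfigError, DataError

REPORT_CLIP = (0.01, 0.99)
REPORT_START = 0.5  # slider position at the start of every session


@dataclass(frozen=True)
class TaskConfig:
    """Design of the ring-drawing experiment."""

    n_subjects: int = 11
    n_sessions: int = 10
    trials_per_session: int = 1000
    hazard: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "trials_per_session"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        h = self.hazard
        if not (isinstance(h, (int, float, np.floating)) and math.isfinite(h)):
            raise ConfigError(f"hazard must be finite, got {h!r}")
        if not 0.0 <= h <= 1.0:
            raise ConfigError(f"hazard must lie in [0, 1], got {h}")


@dataclass
class TaskEnvironment:
    """Hidden probability path, change flags and ring outcomes.

    Arrays are (n_sessions, trials_per_session); sessions are independent and
    each begins with a fresh uniform draw of ``true_p`` (no change flag on a
    session's first trial — that draw defines the session's initial state).
    """

    true_p: np.ndarray
    change_flag: np.ndarray
    rings: np.ndarray
    hazard: float

    @property
    def n_sessions(self) -> int:
        return self.true_p.shape[0]

    @property
    def trials_per_session(self) -> int:
        return self.true_p.shape[1]


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject.

    ``alpha``/``beta``/``sigma`` are the linear log-odds distortion
    parameters (offset, slope, noise SD on the log-odds scale);
    ``adjust_rate`` is the per-trial probability of revising the slider;
    response times are lognormal with log-scale location
    ``rt_log_mean + rt_beta_coupling * beta`` (negative coupling makes
    repulsive subjects faster).
    """

    alpha: float = 0.0
    beta: float = 1.0
    sigma: float = 0.8
    adjust_rate: float = 0.088
    rt_log_mean: float = 0.4
    rt_log_sd: float = 0.5
    rt_beta_coupling: float = -0.3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if not 0.0 <= self.adjust_rate <= 1.0:
            raise ConfigError("adjust_rate must lie in [0, 1]")
        if self.rt_log_sd < 0:
            raise ConfigError("rt_log_sd must be >= 0")


def generate_environment(
    config: TaskConfig, rng: np.random.Generator | None = None
) -> TaskEnvironment:
    """Draw the hidden Bernoulli path and ring outcomes for one subject.

    Each session starts from ``p ~ Uniform(0, 1)``; before every subsequent
    trial ``p`` is redrawn uniformly with probability ``config.hazard``
    (flagged), and the ring is Bernoulli(``p``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    S, T = config.n_sessions, config.trials_per_session
    candidates = rng.uniform(size=(S, T))
    change = rng.uniform(size=(S, T)) < config.hazard
    change[:, 0] = False
    # index of the draw in force at each trial = last redraw position
    cols = np.arange(T)[None, :]
    fresh = change.copy()
    fresh[:, 0] = True
    last = np.maximum.accumulate(np.where(fresh, cols, -1), axis=1)
    true_p = np.take_along_axis(candidates, last, axis=1)
    rings = (rng.uniform(size=(S, T)) < true_p).astype(np.int8)
    return TaskEnvironment(true_p, change, rings, float(config.hazard))


def simulate_subject(
    env: TaskEnvironment,
    profile: SubjectProfile,
    forecasts: np.ndarray,
    seed: int | np.random.Generator,
    subject_id: int = 1,
) -> BehaviorDataset:
    """Generate one subject's reports given ideal-observer forecasts.

    The report starts every session at 0.5.  On each trial the slider is
    revised with probability ``adjust_rate``; a revision sets the report to
    ``logistic(alpha + beta * logit(B) + eps)`` clamped into [0.01, 0.99],
    with ``eps ~ N(0, sigma^2)``; otherwise the previous value is held.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, T = env.n_sessions, env.trials_per_session
    forecasts = np.asarray(forecasts, float)
    if forecasts.shape not in ((S, T), (S * T,)):
        raise DataError(
            f"forecasts shape {forecasts.shape} does not match environment "
            f"({S} sessions x {T} trials)"
        )
    B = forecasts.reshape(S, T)
    if np.any((B <= 0.0) | (B >= 1.0)):
        raise DataError("forecasts must lie strictly inside (0, 1)")

    adjust = rng.uniform(size=(S, T)) < profile.adjust_rate
    eps = rng.normal(0.0, profile.sigma, size=(S, T))
    fresh_vals = expit(profile.alpha + profile.beta * logit(B) + eps)
    fresh_vals = np.clip(fresh_vals, *REPORT_CLIP)

    # step-hold: forward-fill the last adjusted value, 0.5 before the first
    cols = np.arange(T)[None, :]
    last = np.maximum.accumulate(np.where(adjust, cols, -1), axis=1)
    padded = np.concatenate(
        [np.full((S, 1), REPORT_START), fresh_vals], axis=1
    )
    reports = np.take_along_axis(padded, last + 1, axis=1)

    rt_mu = profile.rt_log_mean + profile.rt_beta_coupling * profile.beta
    rts = rng.lognormal(rt_mu, profile.rt_log_sd, size=(S, T))

    frame = pd.DataFrame(
        {
            "subject_id": subject_id,
            "session": np.repeat(np.arange(1, S + 1), T),
            "trial": np.tile(np.arange(1, T + 1), S),
            "ring": env.rings.ravel(),
            "true_p": env.true_p.ravel(),
            "report": reports.ravel(),
            "response_time_s": rts.ravel(),
        }
    )
    return BehaviorDataset(frame, provenance="synthetic")


def default_profiles(
    n_subjects: int = 11, seed: int | np.random.Generator = 0
) -> list[SubjectProfile]:
    """Draw a heterogeneous cohort spanning conservative-to-repulsive biases.

    Ranges emulate the spread documented for human cohorts on this task:
    alpha in [-0.1, 0.3], beta in [0.4, 1.8], sigma in [0.4, 1.2], with the
    8.8% marginal adjustment rate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        SubjectProfile(
            alpha=rng.uniform(-0.1, 0.3),
            beta=rng.uniform(0.4, 1.8),
            sigma=rng.uniform(0.4, 1.2),
        )
        for _ in range(n_subjects)
    ]


def generate_cohort(
    config: TaskConfig,
    profiles: list[SubjectProfile] | None = None,
    seed: int | None = None,
    observer_q: float = 1.0,
) -> BehaviorDataset:
    """Simulate the full cohort: independent environments, one per subject.

    Each subject gets an independent environment stream, ideal-observer
    forecasts at the true hazard, and step-hold distorted reports.  Fully
    deterministic under ``seed`` (defaults to ``config.seed``).
    """
    from .observer import forecast_environment  # local import: cycle avoidance

    if profiles is None:
        profiles = default_profiles(
            config.n_subjects, np.random.default_rng(config.seed + 1)
        )
    if not profiles:
        raise ConfigError("profile list is empty")
    if len(profiles) != config.n_subjects:
        raise ConfigError(
            f"need {config.n_subjects} profiles, got {len(profiles)}"
        )
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    parts = []
    for sid, (profile, ss) in enumerate(
        zip(profiles, master.spawn(config.n_subjects)), start=1
    ):
        env_ss, beh_ss = ss.spawn(2)
        env = generate_environment(config, np.random.default_rng(env_ss))
        B = forecast_environment(env, hazard=config.hazard, q=observer_q)
        parts.append(
            simulate_subject(
                env, profile, B, np.random.default_rng(beh_ss), subject_id=sid
            )
        )
    frame = pd.concat([p.frame for p in parts], ignore_index=True)
    return BehaviorDataset(frame, provenance="synthetic")
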