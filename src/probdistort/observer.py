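"""Ideal-observer forecasts for the change-point Bernoulli process.

The observer knows the generative model: the hidden green-ring probability
``p`` starts from Uniform(0,1) and is replaced by a fresh uniform draw with
per-trial hazard ``h``.  The posterior over ``p`` is tracked on a fixed
midpoint grid, which handles both the exact Bayesian update (``q = 1``) and
the quasi-Bayesian update in which the single-trial likelihood is raised to
a power ``q`` (``q < 1`` under-weights evidence, ``q > 1`` over-weights it,
``q < 0`` moves the posterior against the evidence).

Timing is prequential: the forecast attached to trial ``t`` is the predictive
green probability for trial ``t``'s ring, formed after observing rings
``1..t-1`` and after the possible post-draw replacement of ``p`` — hence the
``(1-h)<p> + h/2`` hazard mixing.  The pre-data forecast is exactly 0.5.

``brute_force_forecast`` is an independent oracle: it enumerates every
placement of change points in short sequences and computes the predictive
probability in closed form from Beta integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data import DataError
from .task import TaskEnvironment

GRID_SIZE = 1001
FORECAST_CLIP = 1e-9  # numerical guard before log-odds transforms


class ParameterError(ValueError):
    pass


@dataclass
class ForecastSeries:
    """Per-trial forecasts from one model, aligned with the trial rows."""

    model_tag: str  # bayes | quasi_bayes | delta | ptn
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any((self.values <= 0.0) | (self.values >= 1.0)):
            raise DataError("forecasts must lie strictly inside (0, 1)")


def _grid(m: int) -> np.ndarray:
    return (np.arange(m) + 0.5) / m


def run_filter(
    rings,
    hazard: float,
    q: float = 1.0,
    m: int = GRID_SIZE,
    mixing: str = "predictive",
) -> ForecastSeries:
    """Grid change-point filter; returns one forecast per ring (prequential).

    ``mixing="predictive"`` (default) reports the green probability for the
    upcoming ring including the hazard step; ``"posterior_mean"`` reports the
    posterior mean of the current ``p`` without hazard mixing.
    """
    rings = np.asarray(rings, dtype=np.int64)
    if rings.ndim != 1 or not np.isin(rings, (0, 1)).all():
        raise DataError("rings must be a 1-D binary sequence")
    if not np.isfinite(hazard) or not 0.0 <= hazard <= 1.0:
        raise ParameterError(f"hazard must lie in [0, 1], got {hazard!r}")
    if not np.isfinite(q):
        raise ParameterError(f"q must be finite, got {q!r}")
    if m < 101:
        raise ParameterError("grid must have at least 101 nodes")

    nodes = _grid(m)
    lik_green = nodes**q
    lik_red = (1.0 - nodes) ** q
    w = np.full(m, 1.0 / m)
    h = float(hazard)
    out = np.empty(len(rings))
    mean = 0.5  # uniform prior mean: the pre-data forecast
    for t, s in enumerate(rings):
        out[t] = mean
        w = w * (lik_green if s == 1 else lik_red)
        tot = w.sum()
        if not np.isfinite(tot) or tot <= 0.0:
            raise FloatingPointError(
                f"posterior weights degenerate at trial {t + 1} (q={q}, "
                f"hazard={hazard}): sum={tot!r}"
            )
        w = w / tot
        post_mean = float(w @ nodes)
        if mixing == "predictive":
            w = (1.0 - h) * w + h / m
            mean = (1.0 - h) * post_mean + h * 0.5
        elif mixing == "posterior_mean":
            w = (1.0 - h) * w + h / m
            mean = post_mean
        else:
            raise ParameterError(f"unknown mixing {mixing!r}")
    out = np.clip(out, FORECAST_CLIP, 1.0 - FORECAST_CLIP)
    tag = "bayes" if q == 1.0 else "quasi_bayes"
    return ForecastSeries(tag, out, {"hazard": h, "q": float(q), "m": m})


def predictive_after(rings, hazard: float, q: float = 1.0, m: int = GRID_SIZE) -> float:
    """Predictive green probability for the trial following ``rings``."""
    rings = np.asarray(rings, dtype=np.int64)
    ext = np.append(rings, 0)  # dummy ring; its forecast is what we want
    return float(run_filter(ext, hazard, q=q, m=m).values[-1])


def brute_force_forecast(rings, hazard: float) -> float:
    """Exact predictive forecast by enumerating change-point placements.

    For a sequence of ``t`` rings there are ``2^(t-1)`` placements of change
    points in the gaps between trials.  Each placement ``c`` has prior weight
    ``h^|c| (1-h)^(t-1-|c|)``; a segment holding ``k`` greens out of ``m``
    draws contributes marginal likelihood ``k!(m-k)!/(m+1)!`` (the Beta
    integral under the uniform prior), and the predictive for the next draw
    given no further change is the Laplace rule ``(k_last+1)/(m_last+2)``.
    The returned value mixes in the hazard:
    ``sum_c w_c [(1-h) m_last(c) + h/2]``.
    """
    rings = np.asarray(rings, dtype=np.int64)
    t = len(rings)
    if t > 14:
        raise ParameterError(
            f"brute force enumeration refuses t={t} > 14 (2^(t-1) placements)"
        )
    if not 0.0 <= hazard <= 1.0:
        raise ParameterError(f"hazard must lie in [0, 1], got {hazard!r}")
    if t == 0:
        return 0.5
    h = float(hazard)
    csum = np.concatenate([[0], np.cumsum(rings)])

    from math import factorial

    def seg_marglik(a: int, b: int) -> float:
        # rings[a:b], uniform prior on the segment's p: k!(m-k)!/(m+1)!
        m_ = b - a
        k_ = int(csum[b] - csum[a])
        return factorial(k_) * factorial(m_ - k_) / factorial(m_ + 1)

    total_w = 0.0
    total_f = 0.0
    gaps = list(range(1, t))  # change before trial index g (0-based gap g)
    for r in range(len(gaps) + 1):
        for cuts in combinations(gaps, r):
            bounds = [0, *cuts, t]
            w = h**r * (1.0 - h) ** (t - 1 - r)
            for a, b in zip(bounds[:-1], bounds[1:]):
                w *= seg_marglik(a, b)
            a_last, b_last = bounds[-2], bounds[-1]
            m_last = b_last - a_last
            k_last = int(csum[b_last] - csum[a_last])
            pred = (k_last + 1) / (m_last + 2)
            total_w += w
            total_f += w * ((1.0 - h) * pred + h * 0.5)
    return total_f / total_w


def forecast_environment(
    env: TaskEnvironment, hazard: float, q: float = 1.0, m: int = GRID_SIZE
) -> np.ndarray:
    """Forecasts for every session of a simulated environment (restarted)."""
    out = np.empty_like(env.true_p)
    for s in range(env.n_sessions):
        out[s] = run_filter(env.rings[s], hazard, q=q, m=m).values
    return out


def forecast_dataset(data, hazard: float, q: float = 1.0, m: int = GRID_SIZE) -> ForecastSeries:
    """Ideal-observer forecasts aligned row-by-row with a behavioral dataset.

    The filter is restarted at every session boundary, so forecasts within a
    session depend only on that session's earlier rings.
    """
    frame = data.frame
    if frame["ring"].isna().any():
        row = frame[frame["ring"].isna()].iloc[0]
        raise DataError(
            "missing ring for subject "
            f"{row['subject_id']}, session {row['session']}, trial {row['trial']}"
        )
    values = np.empty(len(frame))
    for (_, _), g in data.groupby_session():
        series = run_filter(g["ring"].to_numpy(), hazard, q=q, m=m)
        values[g.index.to_numpy()] = series.values
    tag = "bayes" if q == 1.0 else "quasi_bayes"
    return ForecastSeries(tag, values, {"hazard": float(hazard), "q": float(q), "m": m})
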