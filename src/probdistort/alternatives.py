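"""Alternative forecasting models: quasi-Bayes, delta rule, and PTN.

Three report-generating accounts are fitted against the distorted-Bayes
benchmark, all with zero-mean Gaussian noise on the log-odds of the model
forecast (no intercept, no slope — the forecast itself carries the bias):

* quasi-Bayes (QB): the change-point filter with the likelihood raised to an
  exponent ``q`` (``q = 1`` recovers the exact Bayesian benchmark);
* delta rule: ``D_t = D_{t-1} + delta * (s_t - D_{t-1})`` — error-driven
  exponential smoothing of the ring stream;
* probability theory plus noise (PTN): the fraction of green rings in the
  trailing window of ``n`` draws, with each ring mis-recorded with
  probability ``d``, giving expected forecast ``(1-2d) * k/n + d``.

All forecasts are prequential (attached to the following trial), start at
0.5, and reset at session boundaries.  Fitting is conditional on adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.signal import lfilter
from scipy.special import logit

from .data import BehaviorDataset, DataError
from .llo import LinearLogOddsModel, ModelSpec, bic
from .observer import ForecastSeries, run_filter

SIGMA_FLOOR = 1e-6


class ParameterError(ValueError):
    pass


def delta_rule_forecast(rings, delta: float, d0: float = 0.5) -> ForecastSeries:
    """Error-driven point forecast; the value for trial t is D_{t-1}."""
    if not 0.0 <= delta <= 1.0:
        raise ParameterError(f"delta must lie in [0, 1], got {delta!r}")
    rings = np.asarray(rings, float)
    if delta == 0.0:
        values = np.full(len(rings), d0)
    else:
        # D_t = (1-delta) D_{t-1} + delta s_t, then shift by one trial
        d = lfilter([delta], [1.0, -(1.0 - delta)], rings, zi=[(1.0 - delta) * d0])[0]
        values = np.concatenate([[d0], d[:-1]])
    values = np.clip(values, 1e-9, 1 - 1e-9)
    return ForecastSeries("delta", values, {"delta": float(delta), "d0": d0})


def ptn_forecast(
    rings, n: int, d: float, rng: np.random.Generator | None = None
) -> ForecastSeries:
    """Windowed frequency estimate with recording errors.

    ``k_t`` is the green count in the trailing window of ``min(t, n)`` draws
    ending at trial ``t`` (early trials use all available draws); the
    expected forecast ``(1-2d) k_t/window + d`` is attached to trial ``t+1``.
    Pass ``rng`` to flip each recorded ring with probability ``d``
    stochastically instead of using the expectation.
    """
    if n < 1 or int(n) != n:
        raise ParameterError(f"n must be a positive integer, got {n!r}")
    if not 0.0 <= d < 0.5:
        raise ParameterError(f"d must lie in [0, 0.5), got {d!r}")
    n = int(n)
    rings = np.asarray(rings, np.int64)
    if rng is not None and d > 0:
        flips = rng.uniform(size=len(rings)) < d
        rings = np.where(flips, 1 - rings, rings)
    csum = np.concatenate([[0], np.cumsum(rings)])
    t = np.arange(1, len(rings) + 1)
    window = np.minimum(t, n)
    k = csum[t] - csum[t - window]
    frac = (1.0 - 2.0 * d) * (k / window) + d
    values = np.concatenate([[0.5], frac[:-1]])
    values = np.clip(values, 1e-9, 1 - 1e-9)
    return ForecastSeries("ptn", values, {"n": n, "d": float(d)})


@dataclass
class ForecastNoiseFit:
    """Gaussian log-odds noise fit of reports around a candidate forecast."""

    sigma: float
    llf: float
    nobs: int
    floored: bool = False


def fit_forecast_model(y_logodds, forecasts) -> ForecastNoiseFit:
    """Zero-mean Gaussian MLE of log-odds residuals (no intercept/slope)."""
    y = np.asarray(y_logodds, float)
    f = forecasts.values if isinstance(forecasts, ForecastSeries) else np.asarray(forecasts, float)
    if len(y) == 0:
        raise DataError("empty sample")
    if len(y) != len(f):
        raise DataError("forecasts and reports misaligned")
    # forecasts get the numerical log-odds guard, not the behavioral
    # 0.01/0.99 report coding (they may legitimately be more extreme)
    x = logit(np.clip(f, 1e-9, 1.0 - 1e-9))
    resid = y - x
    sigma = float(np.sqrt(np.mean(resid**2)))
    floored = sigma < SIGMA_FLOOR
    sigma = max(sigma, SIGMA_FLOOR)
    n = len(y)
    ll = float(
        -0.5 * (n * np.log(2 * np.pi * sigma**2) + np.sum(resid**2) / sigma**2)
    )
    return ForecastNoiseFit(sigma=sigma, llf=ll, nobs=n, floored=floored)


def _session_series(frame: pd.DataFrame, maker) -> np.ndarray:
    """Apply a per-session forecast constructor and align to rows."""
    out = np.empty(len(frame))
    for _, g in frame.groupby(["subject_id", "session"], sort=False):
        out[g.index.to_numpy() - frame.index[0]] = maker(
            g["ring"].to_numpy()
        ).values
    return out


def _fit_scalar(objective, bounds, xatol=1e-4):
    res = minimize_scalar(objective, bounds=bounds, method="bounded", options={"xatol": xatol})
    x = float(res.x)
    at_boundary = min(x - bounds[0], bounds[1] - x) < 10 * xatol
    return x, at_boundary


@dataclass
class AltSubjectFit:
    """Per-subject estimates for the alternative-model comparison."""

    subject_id: object
    nobs: int
    beta: float  # benchmark distorted-Bayes slope, for correlation checks
    bic_benchmark: float
    sigma_benchmark: float
    q: float
    sigma_q: float
    bic_q: float
    delta: float
    sigma_delta: float
    bic_delta: float
    n: int
    d: float
    sigma_ptn: float
    bic_ptn: float
    boundary_flags: tuple = ()


def fit_alt_suite(
    data: BehaviorDataset,
    hazard: float,
    sample: pd.DataFrame | None = None,
    q_bounds: tuple = (-1.0, 3.0),
    n_max: int = 50,
    grid_m: int = 1001,
) -> pd.DataFrame:
    """Fit QB, delta-rule and PTN per subject, conditional on adjustment.

    The outer optimisations are: bounded scalar search for ``q`` on
    ``q_bounds`` and for ``delta`` on [0, 1]; an integer grid over
    ``n in 1..n_max`` with a bounded search over ``d`` in [0, 0.5) at each
    ``n``.  The inner step is always the closed-form Gaussian noise fit.
    Parameter counts: QB and delta k=2 (model parameter + noise SD),
    PTN k=3.  The distorted-Bayes benchmark (per-subject alpha, beta, sigma
    on the exact Bayesian forecast; k=3) is fitted on the same sample for
    the delta-BIC comparison.
    """
    from .llo import extract_adjustments
    from .observer import forecast_dataset

    if sample is None:
        bayes = forecast_dataset(data, hazard=hazard, m=grid_m)
        sample = extract_adjustments(data, bayes)
    rows = []
    for subject_id, subj_rows in data.frame.groupby("subject_id", sort=False):
        subj_sample = sample[sample["subject_id"] == subject_id]
        adj = subj_sample["adjusted"].to_numpy()
        y = subj_sample["y"].to_numpy()[adj]
        x_bayes = subj_sample["x"].to_numpy()[adj]
        nobs = len(y)
        if nobs < 4:
            raise DataError(
                f"subject {subject_id}: {nobs} adjustment events is too few"
            )
        frame = subj_rows.reset_index(drop=True)

        # benchmark: distorted Bayes with free (alpha, beta, sigma)
        bench = LinearLogOddsModel(
            y, x_bayes, np.repeat(subject_id, nobs), ModelSpec("shared", "shared", "shared")
        ).fit()
        bic_bench = bic(bench.llf, 3, nobs)

        flags = []

        def series_ll(values):
            return fit_forecast_model(y, values[adj])

        def qb_values(q):
            return _session_series(
                frame, lambda r: run_filter(r, hazard, q=q, m=grid_m)
            )

        q_hat, q_bound = _fit_scalar(
            lambda q: -series_ll(qb_values(q)).llf, q_bounds, xatol=1e-3
        )
        if q_bound:
            flags.append("q")
        qb_fit = series_ll(qb_values(q_hat))

        d_hat, d_bound = _fit_scalar(
            lambda dl: -series_ll(
                _session_series(frame, lambda r: delta_rule_forecast(r, dl))
            ).llf,
            (0.0, 1.0),
        )
        if d_bound:
            flags.append("delta")
        delta_fit = series_ll(
            _session_series(frame, lambda r: delta_rule_forecast(r, d_hat))
        )

        best = None
        for n_try in range(1, n_max + 1):
            dd, _ = _fit_scalar(
                lambda dd: -series_ll(
                    _session_series(frame, lambda r: ptn_forecast(r, n_try, dd))
                ).llf,
                (0.0, 0.499),
            )
            f = series_ll(
                _session_series(frame, lambda r: ptn_forecast(r, n_try, dd))
            )
            if best is None or f.llf > best[2].llf:
                best = (n_try, dd, f)
        n_hat, dflip_hat, ptn_fit = best
        if n_hat == n_max:
            flags.append("ptn_n")

        rows.append(
            AltSubjectFit(
                subject_id=subject_id,
                nobs=nobs,
                beta=bench.beta_mean,
                bic_benchmark=bic_bench,
                sigma_benchmark=bench.sigma_mean,
                q=q_hat,
                sigma_q=qb_fit.sigma,
                bic_q=bic(qb_fit.llf, 2, nobs),
                delta=d_hat,
                sigma_delta=delta_fit.sigma,
                bic_delta=bic(delta_fit.llf, 2, nobs),
                n=n_hat,
                d=dflip_hat,
                sigma_ptn=ptn_fit.sigma,
                bic_ptn=bic(ptn_fit.llf, 3, nobs),
                boundary_flags=tuple(flags),
            )
        )
    table = pd.DataFrame([vars(r) for r in rows])
    for m in ("q", "delta", "ptn"):
        table[f"dbic_{m}"] = table[f"bic_{m}"] - table["bic_benchmark"]
        table[f"dsigma_{m}"] = table[f"sigma_{m}"] - table["sigma_benchmark"]
    return table
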