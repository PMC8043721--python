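"""Linear log-odds (LLO) distortion model and its ML fitter.

The model relates a subject's reported probability ``R`` to the ideal
observer's forecast ``B`` on the log-odds scale::

    logit(R) = alpha + beta * logit(B) + eps,   eps ~ N(0, sigma^2)

``alpha`` captures uniform over/under-estimation, ``beta`` conservatism
(beta < 1, compression toward 0.5) versus repulsion (beta > 1), and ``sigma``
trial-level stochasticity.  A :class:`ModelSpec` says which of the three
parameters are fixed at null values, shared across subjects, or free per
subject, and whether the fit uses all trials or only trials on which the
slider actually moved (conditional on adjustment — the step-hold pattern of
reporting otherwise dampens the estimated slope).

:class:`LinearLogOddsModel` is the model object; ``fit()`` returns
:class:`LLOResults` carrying estimates, log-likelihood, parameter count and
BIC.  Estimation is deterministic: closed-form least squares when a single
noise group is involved, otherwise iterated weighted least squares
alternating ``(alpha, beta) | sigma`` with the profiled ML update of sigma,
started from the pooled closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logit

from .data import BehaviorDataset, DataError
from .observer import ForecastSeries
from .task import REPORT_CLIP, REPORT_START

ALPHA_SCHEMES = ("zero", "shared", "subject")
BETA_SCHEMES = ("zero", "one", "shared", "subject")
SIGMA_SCHEMES = ("shared", "subject")
CONDITIONINGS = ("all", "adjust")

SIGMA_FLOOR = 1e-12


class SingularityError(np.linalg.LinAlgError):
    """Design matrix has no unique least-squares solution."""


class ParameterError(ValueError):
    pass


def clip_report(r):
    """Clamp reports into [0.01, 0.99] (certainty coded as 0.99 / 0.01)."""
    arr = np.asarray(r, float)
    if np.any((arr < 0.0) | (arr > 1.0) | ~np.isfinite(arr)):
        raise DataError("report outside [0, 1]")
    clipped = np.clip(arr, *REPORT_CLIP)
    return clipped if arr.ndim else float(clipped)


@dataclass(frozen=True)
class ModelSpec:
    """Parameter-sharing scheme for one LLO model variant."""

    alpha: str = "subject"
    beta: str = "subject"
    sigma: str = "subject"
    conditioning: str = "adjust"

    def __post_init__(self) -> None:
        if self.alpha not in ALPHA_SCHEMES:
            raise ParameterError(f"alpha scheme {self.alpha!r}")
        if self.beta not in BETA_SCHEMES:
            raise ParameterError(f"beta scheme {self.beta!r}")
        if self.sigma not in SIGMA_SCHEMES:
            raise ParameterError(f"sigma scheme {self.sigma!r}")
        if self.conditioning not in CONDITIONINGS:
            raise ParameterError(f"conditioning {self.conditioning!r}")
        if self.beta == "zero" and self.alpha != "zero":
            raise ParameterError(
                "beta fixed at zero is only combined with alpha fixed at "
                "zero (the random-response benchmark)"
            )

    @property
    def label(self) -> str:
        if self.alpha == "zero" and self.beta == "zero":
            return "Random benchmark"
        parts = []
        if self.alpha != "zero":
            parts.append("{alpha_i}" if self.alpha == "subject" else "alpha")
        if self.beta in ("shared", "subject"):
            parts.append("{beta_i}" if self.beta == "subject" else "beta")
        parts.append("{sigma_i}" if self.sigma == "subject" else "sigma")
        return ", ".join(parts)

    def n_free(self, n_subjects: int) -> int:
        k = 0
        k += {"zero": 0, "shared": 1, "subject": n_subjects}[self.alpha]
        k += {"zero": 0, "one": 0, "shared": 1, "subject": n_subjects}[self.beta]
        k += {"shared": 1, "subject": n_subjects}[self.sigma]
        return k


#: The model suite in its canonical presentation order: random benchmark,
#: homogeneous variants, then increasingly heterogeneous variants.
TABLE1_SPECS: list[ModelSpec] = [
    ModelSpec("zero", "zero", "shared"),
    ModelSpec("zero", "one", "shared"),
    ModelSpec("shared", "one", "shared"),
    ModelSpec("zero", "shared", "shared"),
    ModelSpec("shared", "shared", "shared"),
    ModelSpec("subject", "shared", "shared"),
    ModelSpec("shared", "subject", "shared"),
    ModelSpec("shared", "shared", "subject"),
    ModelSpec("subject", "shared", "subject"),
    ModelSpec("shared", "subject", "subject"),
    ModelSpec("subject", "subject", "subject"),
]


def bic(ll: float, k: int, n: int) -> float:
    """Bayes Information Criterion, ``-2 LL + k ln(N)`` (natural log)."""
    if n < 1:
        raise ParameterError(f"N must be >= 1, got {n}")
    if k < 0:
        raise ParameterError(f"k must be >= 0, got {k}")
    return -2.0 * ll + k * math.log(n)


def extract_adjustments(
    data: BehaviorDataset,
    forecasts: ForecastSeries | np.ndarray,
    first_trial_adjusts: bool = True,
) -> pd.DataFrame:
    """Log-odds sample with per-trial adjustment flags.

    A trial is an adjustment when its report differs from the previous
    trial's report within the same session; a session's first trial is
    flagged iff its report moved off the 0.5 slider start (disable with
    ``first_trial_adjusts=False`` to never flag first trials).

    Returns a frame with ``subject_id, session, trial, x, y, adjusted`` where
    ``x = logit(B)`` and ``y = logit(clip_report(R))``.
    """
    frame = data.frame
    values = forecasts.values if isinstance(forecasts, ForecastSeries) else np.asarray(forecasts, float)
    if len(values) != len(frame):
        raise DataError(
            f"forecast length {len(values)} does not match {len(frame)} trials"
        )
    reports = frame["report"].to_numpy(float)
    prev = np.empty_like(reports)
    prev[0] = REPORT_START
    prev[1:] = reports[:-1]
    first = np.zeros(len(frame), bool)
    starts = np.flatnonzero(
        (frame["trial"].to_numpy() == 1)
    )
    first[starts] = True
    prev[first] = REPORT_START
    adjusted = reports != prev
    if not first_trial_adjusts:
        adjusted[first] = False
    return pd.DataFrame(
        {
            "subject_id": frame["subject_id"],
            "session": frame["session"],
            "trial": frame["trial"],
            "x": logit(np.clip(values, 1e-9, 1 - 1e-9)),
            "y": logit(clip_report(reports)),
            "adjusted": adjusted,
        }
    )


@dataclass
class LLOResults:
    """Estimates and fit statistics for one fitted LLO specification.

    Per-subject views (``alpha_by_subject`` etc.) broadcast shared or fixed
    parameters across subjects; the scalar summaries (``alpha_mean`` etc.)
    are unweighted across-subject means, the convention used when a single
    headline number is quoted for a heterogeneous fit.
    """

    spec: ModelSpec
    subjects: list
    alpha_by_subject: pd.Series
    beta_by_subject: pd.Series
    sigma_by_subject: pd.Series
    llf: float
    k: int
    nobs: int
    iterations: int
    converged: bool
    final_ll_change: float

    @property
    def bic(self) -> float:
        return bic(self.llf, self.k, self.nobs)

    @property
    def alpha_mean(self) -> float:
        return float(self.alpha_by_subject.mean())

    @property
    def beta_mean(self) -> float:
        return float(self.beta_by_subject.mean())

    @property
    def sigma_mean(self) -> float:
        return float(self.sigma_by_subject.mean())

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha_by_subject,
                "beta": self.beta_by_subject,
                "sigma": self.sigma_by_subject,
            }
        )

    def loglik(self, y, x, subject) -> float:
        """Gaussian log-likelihood of new data under the frozen estimates."""
        y = np.asarray(y, float)
        x = np.asarray(x, float)
        subject = pd.Index(subject)
        a = self.alpha_by_subject.reindex(subject).to_numpy()
        b = self.beta_by_subject.reindex(subject).to_numpy()
        s = self.sigma_by_subject.reindex(subject).to_numpy()
        if np.isnan(a).any() or np.isnan(s).any():
            raise DataError("data contain subjects absent from the fit")
        r = y - a - b * x
        return float(
            -0.5 * np.sum(np.log(2 * np.pi * s**2) + (r / s) ** 2)
        )

    def summary(self) -> str:
        lines = [
            "Linear log-odds distortion model",
            f"  spec:        {self.spec.label} "
            f"(conditioning: {self.spec.conditioning})",
            f"  N = {self.nobs}, k = {self.k}, "
            f"LL = {self.llf:.3f}, BIC = {self.bic:.3f}",
            f"  converged: {self.converged} "
            f"({self.iterations} iterations, dLL = {self.final_ll_change:.2e})",
            f"  alpha = {self.alpha_mean:.4f}  beta = {self.beta_mean:.4f}  "
            f"sigma = {self.sigma_mean:.4f}  (across-subject means)",
        ]
        if self.spec.alpha == "subject" or self.spec.beta == "subject" or self.spec.sigma == "subject":
            lines.append("  per-subject estimates:")
            lines.append(
                self.params_frame().to_string(float_format=lambda v: f"{v:.4f}")
            )
        return "\n".join(lines)


class LinearLogOddsModel:
    """ML estimation of the LLO distortion under a parameter-sharing scheme.

    Parameters
    ----------
    y, x : array-like
        Log-odds of clipped reports and of ideal-observer forecasts.
    subject : array-like
        Subject identifier per observation.
    spec : ModelSpec
        Which parameters are fixed, shared, or per-subject.
    """

    def __init__(self, y, x, subject, spec: ModelSpec = ModelSpec()):
        self.y = np.asarray(y, float)
        self.x = np.asarray(x, float)
        self.subject = np.asarray(subject)
        if not (len(self.y) == len(self.x) == len(self.subject)):
            raise DataError("y, x and subject must have equal lengths")
        if not np.isfinite(self.y).all() or not np.isfinite(self.x).all():
            raise DataError("y and x must be finite")
        self.spec = spec
        self._codes, uniques = pd.factorize(self.subject)
        self.subjects = list(uniques)
        self.n_subjects = len(self.subjects)
        self.k = spec.n_free(self.n_subjects)
        if len(self.y) < self.k + 1:
            raise DataError(
                f"need at least k+1 = {self.k + 1} observations, have {len(self.y)}"
            )
        if "subject" in (spec.alpha, spec.beta, spec.sigma):
            counts = np.bincount(self._codes)
            if counts.min() < 2:
                raise DataError(
                    "every subject needs >= 2 observations under a "
                    "per-subject scheme"
                )

    @classmethod
    def from_sample(cls, sample: pd.DataFrame, spec: ModelSpec = ModelSpec()):
        """Build from an ``extract_adjustments`` frame, applying conditioning."""
        if spec.conditioning == "adjust":
            sample = sample[sample["adjusted"]]
        return cls(
            sample["y"].to_numpy(),
            sample["x"].to_numpy(),
            sample["subject_id"].to_numpy(),
            spec,
        )

    @classmethod
    def from_dataframe(
        cls,
        data: BehaviorDataset,
        forecasts: ForecastSeries | np.ndarray,
        spec: ModelSpec = ModelSpec(),
    ):
        return cls.from_sample(extract_adjustments(data, forecasts), spec)

    # -- design ------------------------------------------------------------
    def _design(self):
        n = len(self.y)
        cols = []
        slots = []  # (param, subject-or-None)
        onehot = None
        if "subject" in (self.spec.alpha, self.spec.beta):
            onehot = np.zeros((n, self.n_subjects))
            onehot[np.arange(n), self._codes] = 1.0
        if self.spec.alpha == "shared":
            cols.append(np.ones(n))
            slots.append(("alpha", None))
        elif self.spec.alpha == "subject":
            cols.append(onehot)
            slots.extend(("alpha", s) for s in self.subjects)
        if self.spec.beta == "shared":
            cols.append(self.x)
            slots.append(("beta", None))
        elif self.spec.beta == "subject":
            cols.append(onehot * self.x[:, None])
            slots.extend(("beta", s) for s in self.subjects)
        X = (
            np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
            if cols
            else np.empty((n, 0))
        )
        offset = self.x if self.spec.beta == "one" else np.zeros(n)
        return X, offset, slots

    def fit(self, tol: float = 1e-8, maxiter: int = 500) -> LLOResults:
        """Maximize the Gaussian log-likelihood; deterministic IWLS."""
        X, offset, slots = self._design()
        n, p = X.shape
        if p and np.linalg.matrix_rank(X) < p:
            raise SingularityError(
                "design is rank deficient (e.g. all forecasts identical "
                "with a free slope)"
            )
        yw = self.y - offset
        sig_codes = (
            self._codes
            if self.spec.sigma == "subject"
            else np.zeros(n, dtype=int)
        )
        n_sig = sig_codes.max() + 1
        group_n = np.bincount(sig_codes, minlength=n_sig).astype(float)

        def solve(weights):
            if p == 0:
                return np.empty(0), yw
            sw = np.sqrt(weights)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
            return coef, yw - X @ coef

        def sigmas(resid):
            ss = np.bincount(sig_codes, weights=resid**2, minlength=n_sig)
            return np.maximum(np.sqrt(ss / group_n), SIGMA_FLOOR)

        def ll_of(resid, sig):
            ss = np.bincount(sig_codes, weights=resid**2, minlength=n_sig)
            return float(
                -0.5
                * np.sum(
                    group_n * np.log(2 * np.pi * sig**2) + ss / sig**2
                )
            )

        coef, resid = solve(np.ones(n))
        sig = sigmas(resid)
        ll = ll_of(resid, sig)
        it, change, converged = 1, np.inf, False
        for it in range(2, maxiter + 1):
            coef_new, resid = solve((1.0 / sig**2)[sig_codes])
            sig = sigmas(resid)
            ll_new = ll_of(resid, sig)
            change = ll_new - ll
            coef, ll = coef_new, ll_new
            if abs(change) < tol:
                converged = True
                break
        else:
            warnings.warn(
                f"LLO fit did not converge in {maxiter} iterations "
                f"(last LL change {change:.3e})",
                RuntimeWarning,
                stacklevel=2,
            )

        # unpack coefficients into per-subject series
        idx = pd.Index(self.subjects)
        alpha = pd.Series(0.0, index=idx)
        beta = pd.Series(
            1.0 if self.spec.beta == "one" else 0.0, index=idx
        )
        for value, (param, subj) in zip(coef, slots):
            if param == "alpha":
                if subj is None:
                    alpha[:] = value
                else:
                    alpha[subj] = value
            else:
                if subj is None:
                    beta[:] = value
                else:
                    beta[subj] = value
        if self.spec.sigma == "subject":
            sigma = pd.Series(sig[: self.n_subjects], index=idx)
        else:
            sigma = pd.Series(float(sig[0]), index=idx)
        return LLOResults(
            spec=self.spec,
            subjects=self.subjects,
            alpha_by_subject=alpha,
            beta_by_subject=beta,
            sigma_by_subject=sigma,
            llf=ll,
            k=self.k,
            nobs=n,
            iterations=it,
            converged=converged,
            final_ll_change=float(change) if np.isfinite(change) else 0.0,
        )


def table1_suite(
    sample: pd.DataFrame,
    conditioning: str = "adjust",
    specs: list[ModelSpec] | None = None,
) -> list[LLOResults]:
    """Fit the full model suite on one sample; canonical order, BIC attached.

    ``sort_key`` on the returned results is their BIC; use
    :func:`suite_table` for a tabular view ranked or in presentation order.
    """
    if specs is None:
        specs = TABLE1_SPECS
    specs = [replace(s, conditioning=conditioning) for s in specs]
    return [
        LinearLogOddsModel.from_sample(sample, spec).fit() for spec in specs
    ]


def suite_table(results: list[LLOResults], rank: bool = False) -> pd.DataFrame:
    rows = [
        {
            "model": r.spec.label,
            "alpha": r.alpha_mean,
            "beta": r.beta_mean,
            "sigma": r.sigma_mean,
            "k": r.k,
            "neg_ll": -r.llf,
            "bic": r.bic,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    return table.sort_values("bic", ignore_index=True) if rank else table
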