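"""Heterogeneity and stability statistics for fitted distortion parameters.

Given session-wise ML fits of the fully heterogeneous linear log-odds model
(one (alpha, beta, sigma) triplet per subject-session), this module asks
whether subject-level biases are stable traits: within- versus
between-subject variance decomposition with a bootstrap F ratio, one-way
ANOVAs across sessions within median-split halves, early/late session
correlations, correlations between the distortion slope and timing behavior
(response times and adjustment lags), bootstrap confidence intervals for
subject parameters, and Wilcoxon signed-rank tests against null benchmark
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import BehaviorDataset, DataError
from .llo import LinearLogOddsModel, ModelSpec

PARAMS = ("alpha", "beta", "sigma")


class ParameterError(ValueError):
    pass


def _closed_form_llo(y: np.ndarray, x: np.ndarray):
    """OLS (alpha, beta) with ML sigma — the single-subject free fit."""
    mx, my = x.mean(), y.mean()
    vx = np.mean(x * x) - mx * mx
    if vx <= 0:
        raise np.linalg.LinAlgError("all forecasts identical; slope undefined")
    beta = (np.mean(x * y) - mx * my) / vx
    alpha = my - beta * mx
    resid = y - alpha - beta * x
    sigma = float(np.sqrt(np.mean(resid**2)))
    return float(alpha), float(beta), sigma


def sessionwise_fits(
    sample: pd.DataFrame, min_adjustments: int = 10
) -> pd.DataFrame:
    """Fit the free (alpha, beta, sigma) model to every subject-session.

    Uses adjustment events only.  Sessions with fewer than
    ``min_adjustments`` events are withheld with a warning, never silently.
    """
    rows = []
    for (subj, sess), g in sample.groupby(["subject_id", "session"], sort=False):
        g = g[g["adjusted"]]
        if len(g) < min_adjustments:
            warnings.warn(
                f"subject {subj} session {sess}: only {len(g)} adjustment "
                f"events (< {min_adjustments}); session withheld",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        try:
            a, b, s = _closed_form_llo(g["y"].to_numpy(), g["x"].to_numpy())
        except np.linalg.LinAlgError:
            warnings.warn(
                f"subject {subj} session {sess}: degenerate design; withheld",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        rows.append(
            {"subject_id": subj, "session": sess, "alpha": a, "beta": b,
             "sigma": s, "n_obs": len(g)}
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    sample: pd.DataFrame, b: int = 1000, seed: int = 0, level: float = 0.95
) -> pd.DataFrame:
    """Percentile bootstrap CIs for each subject's (alpha, beta, sigma).

    Trial-level resampling with replacement within each subject's
    conditional-on-adjustment sample; re-estimation uses the closed-form
    single-subject fit.
    """
    if b < 100:
        raise ParameterError(f"need at least 100 bootstrap iterations, got {b}")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    rows = []
    for subj, g in sample.groupby("subject_id", sort=False):
        g = g[g["adjusted"]]
        y = g["y"].to_numpy()
        x = g["x"].to_numpy()
        n = len(y)
        if n < 2:
            raise DataError(f"subject {subj}: too few adjustment events")
        a0, b0, s0 = _closed_form_llo(y, x)
        idx = rng.integers(0, n, size=(b, n))
        xs, ys = x[idx], y[idx]
        mx, my = xs.mean(axis=1), ys.mean(axis=1)
        vx = (xs * xs).mean(axis=1) - mx * mx
        vx = np.where(vx > 0, vx, np.nan)
        betas = ((xs * ys).mean(axis=1) - mx * my) / vx
        alphas = my - betas * mx
        resid = ys - alphas[:, None] - betas[:, None] * xs
        sigmas = np.sqrt((resid**2).mean(axis=1))
        for name, point, draws in (
            ("alpha", a0, alphas), ("beta", b0, betas), ("sigma", s0, sigmas)
        ):
            lo, hi = np.nanpercentile(draws, [lo_q, hi_q])
            rows.append(
                {"subject_id": subj, "parameter": name, "estimate": point,
                 "ci_low": float(lo), "ci_high": float(hi)}
            )
    return pd.DataFrame(rows)


@dataclass
class VarianceDecomposition:
    parameter: str
    within_var: float
    between_var: float
    ratio: float  # mean within-subject variance / between-subject variance
    f_boot: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def variance_decomposition(
    table: pd.DataFrame, b: int = 10_000, seed: int = 0
) -> list[VarianceDecomposition]:
    """Within- vs between-subject variance of session-wise parameters.

    ``ratio`` is mean within-subject variance over between-subject variance
    of the subject means; the bootstrap resamples sessions within subjects
    (within partition) and subject means (between partition), yielding a
    distribution of the ratio with a percentile 95% CI.
    """
    subjects = table["subject_id"].unique()
    if len(subjects) < 2:
        raise DataError("need >= 2 subjects")
    rng = np.random.default_rng(seed)
    out = []
    for param in PARAMS:
        per_subj = [
            table.loc[table["subject_id"] == s, param].to_numpy()
            for s in subjects
        ]
        if min(len(v) for v in per_subj) < 2:
            raise DataError("need >= 2 sessions per subject")
        within = float(np.mean([v.var(ddof=1) for v in per_subj]))
        means = np.array([v.mean() for v in per_subj])
        between = float(means.var(ddof=1))
        if between <= 0 or within <= 0:
            out.append(
                VarianceDecomposition(param, within, between, np.nan,
                                      np.nan, np.nan, np.nan, degenerate=True)
            )
            continue
        within_draws = np.zeros(b)
        for v in per_subj:
            idx = rng.integers(0, len(v), size=(b, len(v)))
            within_draws += v[idx].var(axis=1, ddof=1)
        within_draws /= len(per_subj)
        idx = rng.integers(0, len(means), size=(b, len(means)))
        between_draws = means[idx].var(axis=1, ddof=1)
        ok = between_draws > 0
        ratios = within_draws[ok] / between_draws[ok]
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        out.append(
            VarianceDecomposition(
                param, within, between, within / between,
                float(np.median(ratios)), float(lo), float(hi),
            )
        )
    return out


def within_between_ttest(table: pd.DataFrame) -> pd.DataFrame:
    """Welch t-test variant of the within/between comparison.

    Compares, per parameter, the log within-subject session variances (one
    per subject) against the log squared deviations of subject means from
    the grand mean.  This is a documented variant of an under-specified
    published test; the bootstrap F ratio is the primary analysis.
    """
    subjects = table["subject_id"].unique()
    rows = []
    for param in PARAMS:
        per_subj = [
            table.loc[table["subject_id"] == s, param].to_numpy()
            for s in subjects
        ]
        within = np.array([v.var(ddof=1) for v in per_subj])
        means = np.array([v.mean() for v in per_subj])
        dev2 = (means - means.mean()) ** 2
        dev2 = dev2[dev2 > 0]
        t, p = stats.ttest_ind(np.log(within), np.log(dev2), equal_var=False)
        rows.append({"parameter": param, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def median_split_anova(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """One-way ANOVA across sessions within each median-split half.

    Subjects are split at the median of their subject-level mean estimate
    (the median subject goes to the low half); within each half a standard
    one-way ANOVA treats sessions as groups.
    """
    if parameter not in PARAMS:
        raise ParameterError(f"unknown parameter {parameter!r}")
    if table["session"].nunique() < 2:
        raise DataError("need >= 2 sessions")
    subj_means = table.groupby("subject_id")[parameter].mean().sort_values()
    n = len(subj_means)
    low_ids = set(subj_means.index[: (n + 1) // 2])
    rows = []
    for half, ids in (("low", low_ids), ("high", set(subj_means.index) - low_ids)):
        if not ids:
            raise DataError(f"{half} half is empty")
        sub = table[table["subject_id"].isin(ids)]
        groups = [g[parameter].to_numpy() for _, g in sub.groupby("session")]
        f, p = stats.f_oneway(*groups)
        df1 = len(groups) - 1
        df2 = sum(len(g) for g in groups) - len(groups)
        rows.append(
            {"half": half, "parameter": parameter, "F": float(f),
             "df1": df1, "df2": df2, "p": float(p)}
        )
    return pd.DataFrame(rows)


def early_late_correlation(
    table: pd.DataFrame, split_session: int | None = None
) -> pd.DataFrame:
    """Pearson r between subject means of early and late session halves."""
    if table["subject_id"].nunique() < 3:
        raise DataError("need >= 3 subjects")
    if split_session is None:
        sessions = np.sort(table["session"].unique())
        split_session = sessions[len(sessions) // 2 - 1] if len(sessions) > 1 else sessions[0]
    early = table[table["session"] <= split_session]
    late = table[table["session"] > split_session]
    rows = []
    for param in PARAMS:
        e = early.groupby("subject_id")[param].mean()
        l = late.groupby("subject_id")[param].mean()
        joined = pd.concat([e, l], axis=1, keys=["early", "late"]).dropna()
        if joined["early"].var() == 0 or joined["late"].var() == 0:
            rows.append({"parameter": param, "r": np.nan, "p": np.nan,
                         "degenerate": True})
            continue
        r, p = stats.pearsonr(joined["early"], joined["late"])
        rows.append({"parameter": param, "r": float(r), "p": float(p),
                     "degenerate": False})
    return pd.DataFrame(rows)


def timing_summary(
    data: BehaviorDataset, sample: pd.DataFrame, per_session: bool = False
) -> pd.DataFrame:
    """Mean response time and mean adjustment lag per subject (or session).

    The adjustment lag is the number of rings drawn between a subject's
    successive slider revisions within a session (>= 1 by construction).
    """
    keys = ["subject_id", "session"] if per_session else ["subject_id"]
    rt = data.frame.groupby(keys)["response_time_s"].mean()
    lags = {}
    for key, g in sample.groupby(keys if per_session else "subject_id", sort=False):
        gaps = []
        for _, sess in g.groupby("session", sort=False):
            t = sess.loc[sess["adjusted"], "trial"].to_numpy()
            if len(t) > 1:
                gaps.append(np.diff(t))
        lags[key] = float(np.concatenate(gaps).mean()) if gaps else np.nan
    out = rt.to_frame("mean_rt_s")
    out["mean_adjust_lag"] = pd.Series(lags)
    return out.reset_index()


def bias_timing_correlation(
    fits: pd.DataFrame, timing: pd.DataFrame, parameter: str = "beta"
) -> pd.DataFrame:
    """Correlate fitted distortion slopes with timing behavior."""
    keys = [k for k in ("subject_id", "session") if k in fits.columns and k in timing.columns]
    merged = fits.merge(timing, on=keys)
    rows = []
    for col in ("mean_rt_s", "mean_adjust_lag"):
        sub = merged[[parameter, col]].dropna()
        r, p = stats.pearsonr(sub[parameter], sub[col])
        rows.append({"parameter": parameter, "against": col, "r": float(r),
                     "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(values, null_value: float = 0.0) -> tuple[float, float]:
    """Two-sided signed-rank test against a benchmark value.

    Exact sign-pattern p-value for n <= 15 (after dropping exact ties with
    the null), normal approximation otherwise.
    """
    diffs = np.asarray(values, float) - null_value
    diffs = diffs[diffs != 0.0]
    n = len(diffs)
    if n == 0:
        raise DataError("all values tied with the null value")
    if n < 5:
        raise DataError(f"need >= 5 non-tied values, have {n}")
    method = "exact" if n <= 15 else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
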