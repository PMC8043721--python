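import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import probdistort as pdst

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def grid_search_llo_oracle(
    sample, alpha_range=(-1.0, 1.0), beta_range=(-1.0, 3.0), rounds=6, m=401
):
    """Dense zooming grid search for {shared alpha, per-subject beta} with
    sigma profiled out — an estimator-independent oracle for the IWLS fit.

    The profiled Gaussian log-likelihood is unimodal in (alpha, beta), so a
    grid that re-centers and shrinks around the incumbent maximum converges
    to the global optimum.
    """
    groups = [
        (g["x"].to_numpy(), g["y"].to_numpy())
        for _, g in sample.groupby("subject_id")
    ]
    a_lo, a_hi = alpha_range
    b_ranges = [list(beta_range) for _ in groups]
    best = -np.inf
    for _ in range(rounds):
        alphas = np.linspace(a_lo, a_hi, m)[:, None]
        total = np.zeros(m)
        b_idx = []
        for (x, y), (b_lo, b_hi) in zip(groups, b_ranges):
            betas = np.linspace(b_lo, b_hi, m)[None, :]
            sig2 = (
                np.mean(y**2) - 2 * alphas * y.mean()
                - 2 * betas * np.mean(x * y) + alphas**2
                + 2 * alphas * betas * x.mean() + betas**2 * np.mean(x**2)
            )
            ll = -0.5 * len(y) * (np.log(2 * np.pi * sig2) + 1)
            total += ll.max(axis=1)
            b_idx.append(ll.argmax(axis=1))
        a_star = int(total.argmax())
        best = max(best, float(total[a_star]))
        a_step = (a_hi - a_lo) / (m - 1)
        a_lo, a_hi = alphas[a_star, 0] - 3 * a_step, alphas[a_star, 0] + 3 * a_step
        for j, (b_lo, b_hi) in enumerate(b_ranges):
            b_step = (b_hi - b_lo) / (m - 1)
            b_star = b_lo + b_idx[j][a_star] * b_step
            b_ranges[j] = [b_star - 3 * b_step, b_star + 3 * b_step]
    return best


@pytest.fixture(scope="session")
def small_cohort():
    """3 heterogeneous subjects, 2 sessions x 400 trials, with forecasts."""
    cfg = pdst.TaskConfig(n_subjects=3, n_sessions=2, trials_per_session=400, seed=42)
    profiles = [
        pdst.SubjectProfile(alpha=0.05, beta=0.7, sigma=0.6, adjust_rate=0.15),
        pdst.SubjectProfile(alpha=0.15, beta=1.0, sigma=0.9, adjust_rate=0.15),
        pdst.SubjectProfile(alpha=-0.05, beta=1.4, sigma=0.7, adjust_rate=0.15),
    ]
    data = pdst.generate_cohort(cfg, profiles)
    forecasts = pdst.forecast_dataset(data, cfg.hazard)
    sample = pdst.extract_adjustments(data, forecasts)
    return {
        "config": cfg,
        "profiles": profiles,
        "data": data,
        "forecasts": forecasts,
        "sample": sample,
    }


@pytest.fixture()
def logodds_sample():
    """Directly simulated log-odds sample: 3 subjects with known parameters."""
    rng = np.random.default_rng(7)
    import pandas as pd

    truths = {"s1": (0.2, 0.6, 0.5), "s2": (0.0, 1.0, 0.8), "s3": (-0.1, 1.5, 0.6)}
    frames = []
    for subj, (a, b, s) in truths.items():
        x = rng.normal(0.0, 1.8, size=300)
        y = a + b * x + rng.normal(0.0, s, size=300)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subj,
                    "session": np.repeat([1, 2, 3], 100),
                    "trial": np.tile(np.arange(1, 101), 3),
                    "x": x,
                    "y": y,
                    "adjusted": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), truths
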