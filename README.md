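# probdistort

Individual-level probability-distortion analysis for non-stationary
Bernoulli forecasting tasks.

## The problem

In ring-drawing (change-point) tasks, a subject watches draws of green and
red rings from a box whose hidden green probability `p` is occasionally
replaced by a fresh `Uniform(0,1)` draw (per-trial hazard `h`), and
continuously reports the probability that the next ring is green. Pooled
across subjects such reports look strikingly unbiased — yet individual
subjects can be strongly *conservative* (reports compressed toward 0.5) or
*repulsive* (pushed toward the extremes), with the biases cancelling in the
aggregate. This package provides the full toolchain for asking that
question quantitatively: a task and subject simulator, an exact ideal
observer, a family of distortion models with model selection, alternative
(non-Bayesian) forecasting models, and a battery of bias-stability
statistics. It is aimed at computational cognitive modellers who want a
tested, reproducible reference implementation that runs end-to-end on
synthetic data and accepts external trial-level CSVs in the same format.

## The models

The benchmark forecast `B_t` is the posterior-predictive green probability
of a Bayesian observer who knows the generative process, computed by a
change-point filter on a 1,001-node grid (certified against an exact
enumeration oracle). Reports `R_t` are modelled on the log-odds scale by
the **linear log-odds (LLO)** model

    logit(R_t) = α + β · logit(B_t) + ε_t,   ε_t ~ N(0, σ²)

where `α` is additive over/under-estimation, `β < 1` conservatism, `β > 1`
repulsion, and `σ` trial-level noise. Each of `(α, β, σ)` can be fixed at
its null value, shared across subjects, or free per subject; the resulting
model suite is ML-fitted (deterministic iterated weighted least squares
with profiled `σ`) and ranked by `BIC = −2·LL + k·ln N`. Because subjects
revise the slider only occasionally (step-hold reporting, ≈8.8% of
trials), fits condition on adjustment events by default — unconditional
fits demonstrably dampen `β`.

Alternatives fitted for comparison: a **quasi-Bayes** filter whose
likelihood is raised to an exponent `q`; the **delta rule**
`D_t = D_{t−1} + δ(s_t − D_{t−1})`; and **probability theory + noise**
(PTN), `F_t = (1−2d)·(k_t/n) + d` over the trailing `n` draws.
Model comparison includes four-fold cross-validation with a composite
Bayes factor `K = K1·K2`, bootstrap confidence intervals, within/between
subject variance decomposition, median-split ANOVAs, early/late session
correlations, and Wilcoxon signed-rank group tests.

## Worked example

```python
import probdistort as pdst

config = pdst.TaskConfig(n_subjects=3, n_sessions=4, trials_per_session=1000, seed=7)
profiles = [
    pdst.SubjectProfile(alpha=0.05, beta=0.6, sigma=0.6),   # conservative
    pdst.SubjectProfile(alpha=0.10, beta=1.0, sigma=0.8),   # unbiased
    pdst.SubjectProfile(alpha=0.00, beta=1.5, sigma=0.7),   # repulsive
]
data = pdst.generate_cohort(config, profiles)
forecasts = pdst.forecast_dataset(data, hazard=config.hazard)
sample = pdst.extract_adjustments(data, forecasts)

model = pdst.LinearLogOddsModel.from_sample(sample, pdst.ModelSpec())
print(model.fit().summary())
```

prints

```
Linear log-odds distortion model
  spec:        {alpha_i}, {beta_i}, {sigma_i} (conditioning: adjust)
  N = 1061, k = 9, LL = -1145.452, BIC = 2353.606
  converged: True (2 iterations, dLL = 0.00e+00)
  alpha = 0.0511  beta = 1.0382  sigma = 0.7176  (across-subject means)
  per-subject estimates:
   alpha   beta  sigma
1 0.0332 0.6009 0.6316
2 0.1107 0.9925 0.7971
3 0.0093 1.5211 0.7242
```

The `N = 1061` adjustment events out of 12,000 trials reflect the 8.8%
step-hold revision rate; the per-subject rows recover the generating
conservative / unbiased / repulsive profiles (`β̂` = 0.60, 0.99, 1.52),
while the across-subject mean `β` = 1.04 looks deceptively unbiased — the
aggregation artifact the analysis is built to expose. Ranking the full
model suite with `pdst.llo.suite_table(pdst.table1_suite(sample), rank=True)`
puts a `{β_i}` heterogeneous model at the top; with this few subjects the
α-homogeneous variant edges out the fully heterogeneous one on BIC
(2342.9 vs 2353.6), exactly the kind of margin the cross-validated
composite Bayes factor (`probdistort.compare.cv_compare`) is there to
adjudicate.

The same pipeline is scriptable from the shell:

```bash
probdistort simulate --config config.yaml --seed 1 --out trials.csv
probdistort fit --in trials.csv --conditioning adjust --out fit.json
probdistort run-all --config config.yaml --out results/
```

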