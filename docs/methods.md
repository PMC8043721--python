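# Methods

## Generative task model

One session is a sequence of `T` Bernoulli draws ("rings"): green with
hidden probability `p`, red otherwise. `p` starts from `Uniform(0, 1)` and,
before every trial after the first, is replaced by a fresh uniform draw
with hazard `h` (the replacement is flagged). Sessions are independent: a
session's first draw of `p` defines its initial state and is never flagged
as a change, and the report slider resets to 0.5. The literature on this
task prints both 0.05 and 0.5% for the hazard; this package defaults to
`h = 0.005` (the value consistent with the companion Bayesian derivation)
and exposes `h` as an ordinary configuration knob, so the 0.05 reading is
one line away.

Defaults mirror the canonical design: 11 subjects × 10 sessions × 1,000
trials, giving 10,000 trials per subject.

## Synthetic subjects

A subject is `(α, β, σ, adjust_rate, rt_log_mean, rt_log_sd,
rt_beta_coupling)`:

* On each trial the slider is revised with probability `adjust_rate`
  (default 0.088, the marginal revision frequency documented for human
  cohorts). A revision sets the report to
  `logistic(α + β·logit(B) + ε)`, `ε ~ N(0, σ²)`, clamped into
  `[0.01, 0.99]`; otherwise the previous report is held (step-hold).
  The trigger is trial-wise Bernoulli — the simplest mechanism that
  reproduces the marginal revision rate and keeps
  conditional-on-adjustment likelihoods well defined. A threshold-based
  revision policy (revise when the internal estimate drifts far enough)
  would be a natural extension but is not the default.
* Response times are lognormal with log-location
  `rt_log_mean + rt_beta_coupling · β` (defaults 0.4 and −0.3, log-SD 0.5,
  i.e. a median inter-click time of about 1.5 s for β = 0). Only the sign
  of the coupling is empirically motivated (repulsive subjects respond
  faster); the magnitude is a convenience so that the bias–timing
  correlation analyses are exercisable on synthetic data.
* `default_profiles` draws cohorts with `α ∈ [−0.1, 0.3]`,
  `β ∈ [0.4, 1.8]`, `σ ∈ [0.4, 1.2]`, spanning the conservative-to-
  repulsive range reported for human subjects.

What the generator does *not* emulate: slider kinematics and partial
drags, payoff schedules and their incentive effects, within-trial timing,
learning or drift in a subject's parameters, and the small trial
exclusions that give real datasets slightly fewer than the full
`subjects × sessions × trials` records. Passing tests therefore certify
the estimation machinery under the model's own assumptions, not the
behavioral realism of any particular cohort.

## Ideal observer

The posterior over `p` is tracked on a fixed midpoint grid of `M = 1,001`
nodes `(i + ½)/M`. Per trial: multiply the weights by the single-trial
likelihood `p^q` (green) or `(1−p)^q` (red), renormalize, then mix with
the uniform distribution, `w ← (1−h)·w + h/M`. The forecast attached to
trial `t` is prequential: the predictive green probability for trial `t`'s
ring formed after rings `1..t−1` *and* after the possible post-draw
replacement — hence `B = (1−h)·⟨p⟩ + h/2`, and the pre-data forecast is
exactly 0.5. Whether the original benchmark reports this predictive value
or the posterior mean of the current `p` is not documented; predictive is
the default, the posterior mean is available via `mixing="posterior_mean"`.

`q` is the quasi-Bayesian exponent on the single-trial likelihood only;
the hazard-mixing step is untouched. `q = 1` is exact Bayes, `q = 0`
ignores evidence (every forecast 0.5), `q < 0` moves the posterior against
the evidence (weights are renormalized after every update, so positivity
is preserved for binary outcomes). Forecasts are clipped to
`[1e−9, 1−1e−9]` before any log-odds transform; this numerical guard is
distinct from the behavioral 0.01/0.99 clamping of *reports*.

The grid representation was chosen over a run-length Beta-mixture because
it handles fractional-power updates (`q ≠ 1`) uniformly; its accuracy is
certified, not assumed: `brute_force_forecast` enumerates all `2^(t−1)`
change-point placements for sequences up to `t = 14` (prior weight
`h^|c|(1−h)^(t−1−|c|)`, Beta-integral segment likelihoods
`k!(m−k)!/(m+1)!`, Laplace-rule predictive `(k+1)/(m+2)` on the last
segment), and the filter agrees with it to better than `1e−5` across
hazards up to 0.3. Doubling the grid changes no forecast by more than
`1e−6`.

## Linear log-odds estimation

Reports are clamped into `[0.01, 0.99]` (published analyses code
certainty reports as 0.99/0.01; clamping all values generalizes this and
is inert for interior values on a 0.01-resolution slider). All logarithms
are natural. A trial is an *adjustment* when its report differs from the
previous trial's report in the same session; a session's first trial
counts as an adjustment iff the report moved off the 0.5 slider start.
That first-trial convention keeps the event definition uniform; the
alternative counting (never flag first trials) is available via
`first_trial_adjusts=False`, since published conditional sample sizes do
not disclose which rule was used.

`LinearLogOddsModel.fit()` maximizes the Gaussian likelihood under the
spec's grouping of `(α, β, σ)` into fixed / shared / per-subject schemes.
When a single noise group is involved the solution is closed-form least
squares. Otherwise the fitter alternates exact coordinate maximizations —
weighted least squares for `(α, β)` given `σ`, then the profiled ML update
`σ_g² = mean of squared residuals in group g` — which makes the
log-likelihood nondecreasing across iterations. Convergence is declared
when the LL improves by less than `1e−8` (far below any reported
precision), with a 500-iteration cap that warns rather than fails.
There is no random initialization: the iteration starts from the pooled
closed form, so fits are bit-reproducible. Degenerate designs (all
forecasts identical with a free slope) raise a singularity error; `σ` is
floored at `1e−12` so noiseless interpolation keeps a finite likelihood.
`k` counts free scalars exactly (e.g. 33 for 11 subjects with all three
parameters free; the random-response benchmark `α = β = 0` has `k = 1`),
and `BIC = −2·LL + k·ln N` exactly. Across-subject summaries of
heterogeneous parameters are unweighted means.

## Alternative forecasting models

All three alternatives are report-generating models with zero-mean
Gaussian noise on the log-odds of the model forecast (no intercept or
slope), fitted conditional on adjustment:

* quasi-Bayes: bounded scalar search for `q ∈ [−1, 3]` (k = 2);
* delta rule: bounded scalar search for `δ ∈ [0, 1]`, `D₀ = 0.5`,
  session-boundary resets (k = 2);
* PTN: integer grid `n ∈ 1..50` × bounded search over `d ∈ [0, 0.5)`
  (k = 3). `k_t` is the *true* green count with the expected recorded
  fraction `(1−2d)(k_t/n) + d` — matching the model's own "expected
  forecast" definition; a stochastic-flip variant is available by passing
  an RNG for sensitivity checks. Early-trial windows use all available
  draws (`min(t, n)`).

The inner step is always the closed-form noise fit
`σ̂² = mean squared log-odds residual`, floored at `1e−6` (flagged) so a
perfect fit keeps a finite likelihood. Optimizer boundary hits are
flagged, never silent. By construction the `q = 1` quasi-Bayes likelihood
equals the distorted-Bayes benchmark with `α = 0, β = 1` fixed — the test
suite asserts this identity.

## Cross-validation and the composite Bayes factor

Observations are assigned to four folds, stratified within subject (so
per-subject parameters are always estimable on every calibration set; a
pooled random partition is available). Each fold's complement is the
calibration set; validation log-likelihoods use frozen calibration
parameters; results are fold-averaged. A single 75/25 split mode exists
for exact protocol parity with descriptions of one calibration/validation
division.

The composite factor combines a BIC-penalized calibration component with
a validation likelihood ratio. The published equation for `log K1`
(`LLcal(M2) − LLcal(M1) − (k1−k2)·ln Ncal`) is implemented verbatim as
`convention="printed"`, but it cannot be positive when the reference both
fits calibration better and has more parameters — while the published
comparison tables report positive values favoring the reference.
Reconstructing those tables from their own BIC columns shows the intended
quantity is the half-BIC difference, so
`convention="bic"` computes `log K1 = (BICcal(M2) − BICcal(M1))/2` and is
used for the headline `log_k` column (positive favors the fully
heterogeneous reference); both conventions are reported, and both are
exactly zero for a model compared against itself.

## Stability statistics

Session-wise fits apply the free `(α, β, σ)` model to each
subject-session's adjustment events (sessions with fewer than 10 events
are withheld with a warning). On these triplets:

* **Variance decomposition** — mean within-subject session variance
  versus between-subject variance of subject means, with the ratio's
  distribution over 10,000 bootstrap resamples (sessions resampled within
  subjects; subject means resampled across subjects) and a percentile 95%
  CI. The published t-test version of this comparison has unexplained
  degrees of freedom; the implemented `within_between_ttest` is a clearly
  labelled Welch-t variant on log variances and log squared deviations,
  and the bootstrap ratio is treated as the primary analysis.
* **Median-split ANOVA** — subjects split at the median subject-level
  estimate (the median subject joins the low half, giving 6/5 halves for
  11 subjects); within each half a one-way ANOVA treats sessions as
  groups.
* **Early/late correlations** — Pearson r (t-based p) between subject
  means over the first and second halves of sessions (1–5 vs 6–10 for the
  default design).
* **Timing** — per-subject mean response time and mean adjustment lag
  (rings between successive revisions within a session), correlated with
  the fitted `β`; with a trial-wise Bernoulli trigger the lag is
  geometric, mean `1/adjust_rate`.
* **Wilcoxon signed-rank** against null benchmarks (`α = 0`, `β = 1`):
  exact sign-pattern p for n ≤ 15 after dropping exact ties, normal
  approximation above.

No multiple-testing correction is applied anywhere in the battery,
matching standard practice for this analysis.

## Numerical and design choices, test scales

* Percentile bootstrap CIs resample trials with replacement within a
  subject's conditional sample and re-estimate with the closed-form
  single-subject fit; fully vectorized and seed-reproducible.
* Bootstrap-coverage calibration is assessed for a subject operating in
  the interior reporting regime (`α = 0.05, β = 0.9, σ = 0.6`). Near the
  0.01/0.99 report coding the plain Gaussian ML is biased by censoring
  (see Limitations), which would contaminate a test whose purpose is
  bootstrap calibration rather than estimator bias.
* Heavy simulation tests use deliberately scaled designs: filter-vs-oracle
  agreement on 200 random sequences of length ≤ 12; alternative-model
  selection consistency over 20 seeds at 2 sessions × 1,500 trials with
  exact-recovery checks at 10,000 trials; dampening (conditional vs
  unconditional slope) over 20 seeds at 5 sessions × 1,000 trials;
  coverage over 200 replicates of 3 sessions × 1,000 trials with
  B = 1,000. These sizes are the package's reproducibility envelope —
  large enough that every claim is comfortably inside its Monte-Carlo
  error.

## Limitations

* Reports are censored at the 0.01/0.99 coding, but the estimator is the
  field's plain Gaussian ML. For strongly repulsive subjects (β near 1.8)
  this biases `β̂` downward by up to ≈0.2 on synthetic data; a
  Tobit-style censored likelihood would remove this but would no longer
  be the estimator whose published results the package mirrors.
* The enumeration oracle is exponential and refuses sequences longer
  than 14; filter accuracy beyond that length rests on grid-resolution
  convergence rather than exact comparison.
* The delta-rule and PTN fits assume the expectation form of PTN; if real
  subjects flip recorded rings stochastically, `σ̂_F` absorbs the extra
  variance.
* Heterogeneity statistics assume sessions are exchangeable within
  subject; slow within-subject drift would masquerade as within-subject
  variance.
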