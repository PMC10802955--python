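# Methods

`mcibench` is a Monte-Carlo benchmark: it simulates right-censored
time-to-MCI cohorts from a fully specified generating mechanism, fits three
survival predictors under one contract, and scores them with
censoring-aware metrics across scenario sweeps. This note documents the
model, the numerical choices, and what the synthetic data can and cannot
tell you.

## Data-generating mechanism

Each subject carries ten independent features mimicking a dementia-cohort
registry slice:

| feature | distribution |
|---|---|
| SEX (1 = female) | Bernoulli(0.5) |
| AGE | Uniform(55, 85) |
| EDUCATION | Uniform(0, 36) |
| MEMORY | Bernoulli(0.083) |
| JUDGMENT | Bernoulli(0.04) |
| DECCLIN | Bernoulli(0.05) |
| TRAVEL | Multinomial(0.95, 0.03, 0.02) on codes 0/1/2 |
| MOTREM | Bernoulli(0.01) |
| COGSTAT | Multinomial(0.70, 0.16, 0.14) on codes 0/1/9 |
| DECIN | Bernoulli(0.12) |

Event times come from inverse-transform sampling with per-subject rate
multiplier λ_i = exp(x_i·β):

- exponential: T = −log(U)/λ
- Weibull: T = (−log(U)/λ)^{1/k}
- log-logistic: T = (1/λ)·(U/(1−U))^{1/k}

with U ~ Uniform(0,1). The shape k defaults to 1.5 for the Weibull and
log-logistic families — a clear but moderate departure from the
exponential, which is what the distribution sweep is designed to probe.
Note a structural property of these samplers: they are accelerated-
failure-time forms, T = (iid noise)/λ up to a monotone transform. For the
Weibull, log T = (log E − log λ)/k rescales signal and noise equally, so
any rank-based accuracy measure is essentially unchanged relative to the
exponential; for the log-logistic at k = 1.5 the log-noise spread
(π/(√3 k) ≈ 1.21) is close to the exponential's (π/√6 ≈ 1.28). The sweep
therefore mainly stresses survival-curve *shape* (and hence Brier-type
calibration), not discrimination; a C-index collapse under these
constructions would require shapes below 1.
Censoring times are max(0, N(μ=2, σ=3.611)): a floored normal, not a
renormalised truncated normal, so roughly 29% of subjects (Φ(−2/3.611))
are censored at exactly t = 0 and contribute no follow-up. The observed
pair is T̃ = min(T_event, T_cens) with event indicator δ = 1 when the
event time wins; a tie counts as an observed event. Internally δ = 1 means
"event observed" (what every fitter expects); exports also carry the
complementary `censored` flag.

### Design coding

Categorical codes are labels, not magnitudes, so TRAVEL and COGSTAT enter
the linear predictor through level indicators (reference level 0); AGE and
EDUCATION enter per decade, centred at their range midpoints (70 years,
18 years). Centring keeps the overall event-time scale insensitive to the
strength calibration below, so the censoring regime is comparable across
calibration levels.

### Generating weights and calibration

The COGSTAT coefficients are fixed at their estimated values: β₁ = 0.57,
β₉ = −0.44 (male reference). The remaining coefficients are not pinned by
any printed estimate, so the package ships a documented default vector
with clinically sensible signs (impairments raise risk: MEMORY 0.90,
JUDGMENT 0.70, DECCLIN 0.60, TRAVEL₁ 0.50, TRAVEL₂ 0.90, MOTREM 0.40,
DECIN 0.70; AGE +0.45/decade; EDUCATION −0.25/decade; SEX −0.10) together
with a one-time calibration: a single multiplier on the non-COGSTAT
weights is bisected until the correctly specified Cox model reaches a
held-out C-index of 0.73 in the baseline scenario (N = 6,000,
exponential, no heterogeneity). The bisection is monotone and converges in
a handful of steps; a 10-replicate run fixed the packaged default
`DEFAULT_BASE_SCALE = 1.54`. `calibrate_base_scale` re-runs the procedure
for any seed.

A structural consequence worth stating: once the overall accuracy is
pinned at C ≈ 0.73, the COGSTAT term's share of the risk-score variance
is fixed at Var(0.57·I₁ − 0.44·I₉) ≈ 0.078 — at most ~9% of the total.
Omitting COGSTAT from training therefore costs only ~1–1.5 C-index
points in this mechanism, regardless of how the other weights are
allocated. Larger published drops for this feature imply a generating
process in which COGSTAT carries several times that variance share, which
is not compatible with the fixed coefficients and marginals above.

### Heterogeneity

Observed heterogeneity enters through two dummy features
f₁ = SEX·I{COGSTAT=1} and f₉ = SEX·I{COGSTAT=9}, whose generating
coefficients shift the female COGSTAT effects by the estimated
interaction means (−0.13, −0.31) at level "small", mean + 1 SD
(SDs 0.13, 0.16) at "medium", and mean + 2 SD at "large". Unobserved
heterogeneity is realised by *omitting* listed features from the released
table after they have shaped the event times.

## Predictors

All three models receive the same indicator-coded design; the Cox model
additionally receives the two heterogeneity dummies in
observed-heterogeneity scenarios (`cox_interaction_dummies`, default =
"when the generating scheme is heterogeneous"). The forest and the
network never see the dummies by default — they are expected to learn any
interaction — and a config flag can override.

**Cox PH** is fitted by damped Newton ascent of the Breslow log partial
likelihood (gradient/Hessian via reverse cumulative sums, O(np²) per
iteration). Step-halving never accepts a non-finite or decreased
likelihood, which keeps separation-prone small cohorts (rare indicators
with ~2 positives in a 200-subject training set) from diverging to NaN;
such fits stop at the best reachable point and are flagged
`converged=False` rather than silently accepted. Ties are handled by the
Breslow approximation (they have measure zero under the continuous
generator). The baseline cumulative hazard is the Breslow estimator;
survival curves are S(t|x) = exp(−Λ₀(t)·e^{x·β}).

**Random survival forest** delegates the ensemble to scikit-survival's
`RandomSurvivalForest`, whose split criterion is the standardized
log-rank statistic; `logrank_split_statistic` implements that formula
directly and the tests verify the library's splits against it. Defaults:
250 trees, √p candidate features per split, minimum node size 3,
bootstrap on. Follow-up times are quantile-binned to ≤100 representative
values before growing the forest: the log-rank statistic depends on times
only through risk-set ranking, so binning changes held-out C-index by
~0.001–0.002 while reducing single-core fit time at n = 4,800 from hours
to ~12 s and bounding memory. The risk score is the ensemble cumulative
hazard summed over the training grid.

**Cox-loss network** ("DeepSurv-style") is a fully connected network
(default two hidden layers of 32 ReLU units with inverted dropout 0.2,
linear scalar head) trained by full-batch Adam (lr 1e-3, L2 1e-4, ≤500
epochs) on the average negative log partial likelihood, with early
stopping (patience 20) on a 20% validation slice of the training set. The
implementation is plain NumPy — the model is a few small dense layers, and
writing it out keeps the loss and its gradient (the martingale residual
δ_j − e^{η_j}Λ₀(T̃_j)) fully inspectable. With no hidden layers, no
dropout and no penalty the network reduces exactly to the Cox model, and a
test checks the recovered coefficients agree. Survival curves reuse the
Breslow baseline with e^{h(x)} as rate multiplier.

## Metrics

**Harrell's C**: fraction of permissible pairs (the shorter observed time
must be an event) ranked concordantly by risk score; tied scores credit
0.5 by default (a `strict` mode credits 0, the literal strict-inequality
reading, kept for formula-exact testing).

**IPCW Brier / IBS**: the censoring survival function Ĝ is a Kaplan–Meier
estimate with censoring as the event, fitted on the *training* split (no
test-set information leaks into the weights). Event terms are weighted by
1/Ĝ(T̃ᵢ−) (left limit), at-risk terms by 1/Ĝ(t); subjects whose required
weight is undefined (Ĝ = 0) are excluded with a warning. The evaluation
grid is the observed test event times within [0, t_max] plus endpoints,
with t_max the 95th percentile of observed test times — "all available
times" is unstable because Ĝ vanishes in the tail. IBS is the trapezoidal
average of BS(t) over [0, t_max]. Both conventions (training-split Ĝ,
95th-percentile t_max) are config-overridable; reported IBS levels depend
on them, and comparisons should only ever be made within one convention.

## Study orchestration

A scenario is one cell: N ∈ {250, 500, 2000, 6000}, survival family,
heterogeneity level, omitted features, replicate count (50 by default),
split ratio 0.8, master seed. Per-replicate child streams come from
`SeedSequence(master, spawn_key=(replicate,))`, with fixed per-model
sub-streams, so every number is reproducible end to end from the master
seed and replicates are pairable across scenarios that share one (the
feature-omission comparisons use this). The 80:20 split is simple random,
unstratified. Summaries report the mean and empirical 5%/95% quantiles
(NumPy's default, type-7) over replicates, plus per-replicate pairwise
model differences. Failed fits are recorded and skipped
(record-and-continue); a scenario with >20% failed replicates is marked
invalid.

Problem sizes used by the shipped checks: the N=250 and N=500 cells and
the observed-heterogeneity table run the full 50 replicates; the N=6,000
cell and the feature-omission comparisons run 10 replicates, which keeps a
full verification pass on one core while leaving the Monte-Carlo error of
a scenario mean near or below 0.01 in C-index.

## What the generator does and does not emulate

It reproduces marginal frequencies, a realistic censoring fraction, a
log-linear hazard with fixed COGSTAT effects, and controllable
sex-by-COGSTAT heterogeneity. It does **not** model feature correlations
(features are drawn independently), outliers, missing values,
time-varying covariates, or non-log-linear effects. Passing benchmarks
here therefore says how the predictors compare *when the Cox model's
assumptions hold and features are independent* — the forest and the
network have no structural advantage to find, which is exactly the point
of the baseline comparison; conclusions do not transfer to data with
strong nonlinearities or correlated predictors.

## Known limitations

- Separation in small cohorts is flagged, not penalised; a ridge-penalised
  Cox variant would be the next step if very small N mattered.
- The forest's time binning (≤100 bins) is invisible at the study's sizes
  but would need re-examination for cohorts with very heavy tie structure.
- The network's hyperparameters are fixed defaults, not tuned; the study
  design compares default-configured methods, not best-achievable ones.
- IBS levels are convention-dependent (t_max, Ĝ split); only within-run
  comparisons are meaningful.
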