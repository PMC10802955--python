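# mcibench

A Monte-Carlo benchmark of survival predictors for time-to-MCI
(mild cognitive impairment) cohorts.

## The problem

Clinicians want to predict *when* a cognitively normal person will convert
to MCI from routinely collected features. Such time-to-event data are
right-censored — for many subjects follow-up ends before conversion — and
the candidate predictors span three traditions: a statistical model (Cox
proportional hazards), a machine-learning model (random survival forest,
RSF) and a deep-learning model (a Cox-loss feed-forward network,
DeepSurv-style). Which one to trust, and how much training data each
needs, is an empirical question. `mcibench` answers it by simulation: it
generates synthetic cohorts from a fully known mechanism and scores the
three predictors head-to-head across sample sizes, survival
distributions, and heterogeneity regimes.

## The model

Cohorts carry ten independent clinical features (sex, age, education, and
seven impairment indicators including the three-level cognitive status
COGSTAT) with fixed marginals. Event times follow

T = −log(U) / λ,  λ = exp(x·β)   (exponential; Weibull and log-logistic variants)

and censoring times follow max{0, N(μ=2, σ=3.611)}. The observed pair is
(min(T, C), δ). The COGSTAT log-hazard weights are fixed at β₁ = 0.57,
β₉ = −0.44; the remaining weights are scaled once by `calibrate_base_scale`
so that the correctly specified Cox model reaches a held-out C-index of
0.73 at N = 6,000. Sex-specific COGSTAT effects ("observed heterogeneity")
enter through dummy features SEX·I{COGSTAT=k}; "unobserved heterogeneity"
is realised by hiding features that shaped the outcomes. Models are scored
on a held-out 20% split with Harrell's C-index and the IPCW-weighted
integrated Brier score. See `docs/methods.md` for every convention.

## Worked example

`python examples/fit_and_score.py` — one replicate at N = 2,000:

```
model       C-index      IBS
coxph         0.710    0.147
rsf           0.689    0.154
deepsurv      0.709    0.143
```

A C-index of 0.5 is a random ranking and 1.0 a perfect one, so all three
models rank held-out subjects far better than chance; lower IBS means
better-calibrated survival curves. The Cox model is the correctly
specified reference here, and at this sample size the network has
essentially caught up with it while the forest trails slightly — run
`examples/sample_size_sweep.py` to watch the gap open up at N = 250.

Other examples: `simulate_cohort.py` (inspect a generated cohort),
`heterogeneity_weights.py` (the sex-by-COGSTAT weight schemes),
`calibrate_weights.py` (re-run the weight calibration).

A thin CLI wraps the same functions:

```
mcibench simulate --n 2000 --seed 1 --out cohort.csv
mcibench run-study --family sample_size --replicates 10 --outdir results/
```

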