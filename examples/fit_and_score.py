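"""Fit the three predictors on one simulated cohort and score the held-out set.

One replicate of the benchmark: simulate 2,000 subjects, split 80:20,
fit the Cox model, the random survival forest and the Cox-loss network on
the training set, then report Harrell's C-index (0.5 = random ranking,
1 = perfect) and the IPCW integrated Brier score (lower = better-calibrated
survival curves) on the 400 held-out subjects.
"""

from mcibench import ScenarioConfig, run_replicate

config = ScenarioConfig(n_subjects=2000, seed=7, models=("coxph", "rsf", "deepsurv"))
records = run_replicate(config, replicate_index=0)

print(f"{'model':<10} {'C-index':>8} {'IBS':>8}")
for rec in records:
    print(f"{rec.model:<10} {rec.cindex:8.3f} {rec.ibs:8.3f}")
print()
print("Higher C-index = better risk ranking; lower IBS = better survival-curve")
print("calibration. On this linear generating mechanism the Cox model is the")
print("correctly specified reference the other two are judged against.")
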