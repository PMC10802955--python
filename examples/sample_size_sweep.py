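"""A miniature sample-size sweep.

Runs the Cox model and the random survival forest at N = 250 and N = 1,000
with 8 replicates each (the full study uses 50) and prints mean held-out
C-index with the empirical 5%/95% interval.  The statistical model keeps
its accuracy at small N while the forest needs more data — the study's
central sample-size effect.
"""

from mcibench import ScenarioConfig, run_scenario

for n in (250, 1000):
    cfg = ScenarioConfig(
        name=f"n{n}", n_subjects=n, replicates=8, seed=1,
        models=("coxph", "rsf"),
    )
    summary = run_scenario(cfg)
    print(f"N = {n}:")
    for model in cfg.models:
        mean = summary.mean(model, "cindex")
        lo, hi = summary.interval(model, "cindex")
        print(f"  {model:<6} C-index {mean:.3f}  (90% interval {lo:.3f} - {hi:.3f})")
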