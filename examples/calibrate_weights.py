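"""Re-run the one-time calibration of the generating weights.

The ten-feature generator fixes the COGSTAT coefficients at their
estimated values (0.57, -0.44) but the remaining coefficients are only
known up to plausible signs and magnitudes.  The calibration scales them
by a single factor until the correctly specified Cox model reaches a
held-out C-index of 0.73 at N = 6,000 — the study's reference accuracy —
and that factor ships as `DEFAULT_BASE_SCALE`.
"""

from mcibench import DEFAULT_BASE_SCALE, calibrate_base_scale

scale = calibrate_base_scale(target=0.73, n=6000, seed=0, replicates=3)
print(f"calibrated scale for this seed : {scale:.3f}")
print(f"packaged default               : {DEFAULT_BASE_SCALE:.3f}")
print("Small differences are Monte-Carlo noise; the packaged value was fixed")
print("with a 10-replicate run of this same routine.")
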