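"""Per-intensity Euclidean distance between lick and reflex responses.

For each intensity within a session the two 20-trial binary response
vectors are compared; distance = sqrt(number of disagreeing trials).
Reference lines mark 95% agreement (distance 1) and 50% agreement
(sqrt(10) ~ 3.16).  Channels decouple near the perceptual threshold.
"""

import lickreport as lr

cohort = lr.simulate_cohort([lr.DEFAULT_OBSERVER] * 5, sessions_per_mouse=8, seed=1)
profile = lr.profile_across_sessions(
    [(s.session_id, t) for s, t in cohort], n_bootstrap=2000, seed=1
)

print(f"reference lines: 95% agreement -> {profile.reference_95:.2f}, "
      f"50% -> {profile.reference_50:.2f}")
print(f"{'intensity':>10} {'mean dist':>10} {'95% CI':>18}")
for row in profile.summary.itertuples(index=False):
    print(f"{row.intensity_mw_mm2:10.3f} {row.mean:10.3f}   "
          f"[{row.ci_low:6.3f}, {row.ci_high:6.3f}]")
print("distances peak at near-threshold intensities: perceptually ambiguous "
      "stimuli drive the two behaviors apart")
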