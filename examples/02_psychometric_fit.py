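"""Fit a cumulative-Gaussian psychometric function to pooled hit counts.

Detection probability is gamma + (1 - gamma - lambda) * Phi((log10 I - mu)/sigma);
the threshold is the intensity at the curve midpoint, 10**mu.
"""

import numpy as np

import lickreport as lr

cohort = lr.simulate_cohort([lr.DEFAULT_OBSERVER] * 5, sessions_per_mouse=8, seed=1)

counts = {}
fa_rates = []
for _, trials in cohort:
    fa_rates.append(lr.rates(trials, "lick")[1])
    for t in trials:
        if t.stimulus.is_catch:
            continue
        n, k = counts.get(t.stimulus.intensity_mw_mm2, (0, 0))
        counts[t.stimulus.intensity_mw_mm2] = (n + 1, k + int(t.licked))

rows = [(I, n, k) for I, (n, k) in sorted(counts.items())]
fit = lr.fit_psychometric(rows, fa_rate=float(np.mean(fa_rates)))

print(f"pooled fit over {len(cohort)} sessions:")
print(f"  location mu = {fit.location_mu:.3f} log10 mW/mm^2, spread sigma = {fit.spread_sigma:.3f}")
print(f"  guess rate gamma = {fit.guess_gamma:.3f}, lapse rate lambda = {fit.lapse_lambda:.3f}")
print(f"  detection threshold = {lr.extract_threshold(fit):.3f} mW/mm^2 (midpoint intensity)")
print(f"  catch-trial reference line (not fitted): FA = {fit.fa_reference:.3f}")

band = lr.near_threshold_band(fit)
print(f"near-threshold intensities (normalized detection in [0.25, 0.75]): "
      f"{[round(v, 3) for v in band.member_intensities]} mW/mm^2")
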