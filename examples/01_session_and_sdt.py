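"""Build a testing session, simulate a mouse, and compute SDT metrics.

A testing session presents 20 repetitions of each of 17 optogenetic
irradiances (0.14-5.45 mW/mm^2) plus 20 tactile catch trials in seeded
random order.  The synthetic observer licks when its noisy evidence
exceeds a criterion that drifts upward within the session.
"""

from dataclasses import replace

import lickreport as lr

schedule = lr.build_schedule("testing", seed=7)
observer = replace(lr.DEFAULT_OBSERVER, rng_seed=101)
trials = lr.simulate_session(observer, schedule)

hit, fa = lr.rates(trials, "lick")
print(f"session: {len(trials)} trials, lick hit rate {hit:.3f}, false-alarm rate {fa:.3f}")
print(f"session d' = {lr.dprime(hit, fa):.3f}  (sensitivity: separation of signal vs noise)")
print(f"session criterion = {lr.criterion(hit, fa):.3f}  (positive = conservative)")

series = lr.sliding_series(trials)
first, last = series.records[0], series.records[-1]
print(
    f"50-trial sliding window: criterion {first.criterion:.2f} (early) -> "
    f"{last.criterion:.2f} (late); the rise reflects within-session response-bias drift"
)
print(f"passes the d' > 1.0 inclusion rule (first 250 trials and overall): "
      f"{lr.passes_inclusion(trials)}")
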