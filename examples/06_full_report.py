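"""End-to-end driver: simulate a cohort to disk, analyze, print the panels.

Equivalent to `lickreport simulate` followed by `lickreport analyze` on
the command line; everything is seeded through the config, so reruns
are byte-identical.
"""

import tempfile
from pathlib import Path

import lickreport as lr
from lickreport.io import RunConfig
from lickreport.reporting import analyze_files, simulate_to_files

config = RunConfig(seed=1, n_mice=5, sessions_per_mouse=8, bootstrap_resamples=2000)
with tempfile.TemporaryDirectory() as tmp:
    out = simulate_to_files(config, Path(tmp) / "cohort")
    logs = sorted(out.glob("*.csv"))
    print(f"simulated {len(logs)} session logs in {out.name}/ (+ manifest.json)")
    report = analyze_files(logs, config)

print(f"sessions passing the d' > 1.0 inclusion rule: {report['n_sessions_included']}"
      f" (excluded: {report['excluded_sessions'] or 'none'})")
m = report["mean_rates"]
print(f"mean rates: lick hit {m['lick_hit_rate']:.3f} / FA {m['lick_fa_rate']:.3f}; "
      f"reflex hit {m['reflex_hit_rate']:.3f} / FA {m['reflex_fa_rate']:.3f}")
drift = report["criterion_drift_slope_mean"]
print(f"windowed criterion slope per trial: lick {drift['lick']:+.4f}, "
      f"reflex {drift['reflex']:+.4f} (the report channel grows conservative; the reflex does not)")
for c in report["comparisons"]:
    print(f"  {c['comparison_id']}: p = {c['p_value']:.2e}, significant = {c['significant']}")
print(f"lick threshold: {report['psychometric']['lick']['threshold_mw_mm2']:.3f} mW/mm^2; "
      f"near-threshold band: {[round(v, 3) for v in report['near_threshold_band']]}")
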