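# lickreport

Simulation and analysis of **operant lick-report nociceptive detection**
sessions in head-fixed mice.

In this go/no-go assay, transgenic mice expressing channelrhodopsin-2 in
TRPV1-lineage nociceptors learn to lick a water spout when a brief 470 nm
light pulse activates nociceptive afferents in the hind paw (*target*
trials, 17 irradiances spanning 0.14–5.45 mW/mm²), and to withhold licking
after a tactile *catch* stimulus. Licking within the response window is a
**hit** on target trials and a **false alarm** on catch trials. Because
a concurrent video-scored hind-quarter withdrawal reflex is available on
every trial, the assay supports trial-by-trial comparison of a learned,
brain-mediated self-report against a spinally mediated reflex.

`lickreport` packages the complete analysis pipeline around this task,
plus a generative observer that stands in for the animals so every stage
can be validated by parameter recovery:

- **session engine** — seeded 360-trial schedules (20 × 17 targets + 20
  catch), outcome classification, reward taper, task consequences;
- **synthetic observer** — an equal-variance Gaussian signal-detection
  model with two coupled response channels (lick and reflex), a
  saturating sensitivity map `δ(I) = clip(a·(log₁₀ I − x₀), 0, δmax)`,
  a within-session lick criterion drift `c(t) = c₀ + β·t`, and shared
  attentional lapses;
- **SDT metrics** — `d′ = Z(hit − offset) − Z(FA + offset)` and
  `criterion = −(Z(hit − offset) + Z(FA + offset))/2` with offset 0.001,
  session-level and in a 50-trial sliding window, plus the session
  inclusion rule (d′ > 1.0 over the first 250 trials and overall);
- **psychometric fits** — maximum-likelihood cumulative Gaussians
  `p(I) = γ + (1 − γ − λ)·Φ((log₁₀ I − μ)/σ)` on target trials with the
  catch FA rate as a fixed reference, thresholds (`10^μ`) and the
  near-threshold intensity band;
- **similarity** — per-intensity Euclidean distance
  `√Σᵢ(lickᵢ − reflexᵢ)²` between the 20-trial binary response vectors,
  with the 95% (distance 1) and 50% (√10) agreement reference lines;
- **group statistics** — KS normality screen, two-sided Wilcoxon
  signed-rank tests at α = 0.025 with Bonferroni correction, one-sided
  Mann–Whitney U for 595 nm control sessions;
- **CAP pipeline** — stimulus-locked compound action potential analysis
  (0.1–100 Hz band-pass, mains notch, 8.3 kHz downsample, epoch
  averaging, normalization, A-delta/C peak detection, conduction
  velocities), with a synthetic two-volley recording generator.

## Worked example

`examples/01_session_and_sdt.py` builds a testing schedule, simulates a
session and computes the SDT metrics:

```
session: 360 trials, lick hit rate 0.868, false-alarm rate 0.300
session d' = 1.632  (sensitivity: separation of signal vs noise)
session criterion = -0.295  (positive = conservative)
50-trial sliding window: criterion -0.75 (early) -> 1.11 (late); the rise reflects within-session response-bias drift
passes the d' > 1.0 inclusion rule (first 250 trials and overall): True
```

The hit rate counts licks on target trials; d′ ≈ 1.6 means the session
clears the engagement threshold, and the rising windowed criterion shows
the animal growing more conservative (licking less readily) as it sates.
`examples/05_cap_pipeline.py` runs the evoked-potential stage on a
synthetic dorsal-horn recording:

```
preprocessed: 12000 Hz -> 8300 Hz, 100 epochs averaged, waveform normalized to |max| = 1
  A_delta: latency 20.0 ms, normalized amplitude +1.00, conduction velocity 2.00 m/s (fast myelinated afferents)
  C: latency 200.0 ms, normalized amplitude +0.53, conduction velocity 0.20 m/s (slow unmyelinated afferents)
```

The two latencies are the early (A-delta) and late (C-fiber) afferent
volleys; dividing the 4 cm paw-to-electrode distance by each latency
gives conduction velocities in the myelinated and unmyelinated ranges.
The other scripts in `examples/` cover psychometric fitting, the
similarity profile, the group statistics and the end-to-end report; a
thin CLI (`lickreport simulate|analyze|fit|similarity|cap|report`)
exposes the same pipeline from the shell.

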