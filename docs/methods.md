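# Methods

## The task and its observables

Each session presents 360 trials in seeded random order: 20 repetitions
of each of 17 optogenetic target irradiances plus 20 tactile catch
trials. Target irradiances are log₁₀-spaced across 0.14–5.45 mW/mm²
(the range spans ~1.6 decades; log spacing is the psychophysical
convention and concentrates sampling near threshold — the exact spacing
of the original apparatus is not published, so it is configurable).
Inter-stimulus intervals are drawn uniformly from 3–6 s per trial. The
response window is 1 s in testing sessions and a single per-session draw
from 0.8–1.5 s in training sessions. Reward probability on hits starts
at 1.0 and tapers by a configurable 5–10% per training day (default
0.05) to a floor of 0.80, which is also the testing-session value.
Outcomes follow the standard go/no-go cross: hit/miss on target (and
595 nm control) trials, false alarm/correct rejection on catch trials.
Consequences: misses draw up to 10 extra stimuli, false alarms up to 10
warning pulses at maximal irradiance, and pre-stimulus licks a timeout
equal to the trial's ISI.

## Generative observer

The observer is an equal-variance Gaussian SDT model with two response
channels driven by partially shared noise:

```
lick evidence   = δ(I)      + √ρ·shared + √(1−ρ)·ε_lick
reflex evidence = δ(I) + b  + √ρ·shared + √(1−ρ)·ε_reflex   (targets, δ>0)
licked  ⇔ lick evidence   > c₀ + β·t
reflex  ⇔ reflex evidence > c_r
```

with δ(I) = clip(a·(log₁₀ I − x₀), 0, δmax) and δ = 0 on catch and
595 nm control trials. An attentional lapse (probability λ, target
trials only) forces no response on *both* channels: lapses model the
animal disengaging, not one effector failing, and a channel-specific
lapse would introduce a spurious constant hit-rate gap between
channels. The marginal lick probability is (1 − λ)·Φ(δ(I) − c(t)),
which the test suite checks against the normal-CDF closed form by Monte
Carlo.

Default parameters (the simulated study conditions; all are
`ObserverParams` fields):

| parameter | default | units / meaning |
|---|---|---|
| a (`sensitivity_gain`) | 3.5 | d′ per decade of irradiance |
| x₀ (`sensitivity_origin`) | −0.97 | log₁₀ mW/mm² where δ leaves 0 |
| δmax (`sensitivity_max`) | 3.0 | saturation sensitivity |
| c₀, β (cohort default) | 0.1, 0.8/360 | lick criterion start and per-trial drift |
| c_r (`reflex_criterion`) | 1.028 | static reflex criterion |
| b (`reflex_sensitivity_boost`) | 0.528 | extra reflex d′ on targets |
| ρ (`channel_correlation`) | 0.6 | shared-noise weight |
| λ (`lapse_rate`) | 0.02 | shared attentional lapse |

The criteria are anchored to observed session-mean false-alarm rates:
P(respond | catch) = Φ(−c), so c_r = −Φ⁻¹(0.152) ≈ 1.028 pins the
reflex channel at its ~15% FA mean, and the drifting lick criterion is
placed so its mid-session value is 0.5, giving a session-mean lick FA
of Φ(−0.5) ≈ 31%. The drift amplitude (+0.8 over a session) makes the
windowed criterion rise clearly against estimator noise while keeping
the top-intensity hit rate above 90% at session end.

The reflex boost `b` deserves emphasis. With a single shared δ and
different criteria, hit rates would *have* to differ between channels at
intermediate intensities — large, systematic gaps near threshold — while
behaving cohorts show matched hit rates with lower reflex FA, i.e. a
*more sensitive* reflex channel, not merely a more conservative one.
Setting b equal to the criterion gap (c_r − mean lick criterion = 0.528)
makes the two channels' expected hit rates identical at every intensity
while preserving the FA and d′ differences. This is the one place where
the generator is deliberately not "equal sensitivity": the data pattern
it must reproduce is incompatible with that assumption.

The sensitivity map (a = 3.5, x₀ = −0.97) places the lick threshold near
the bottom of the irradiance grid. That choice is forced by the session
inclusion rule: with only 20 catch trials a session's d′ estimate has an
SD of ≈0.3, so an inclusion pass rate above 90% requires a mean session
d′ ≈ 1.6–1.8, i.e. most intensities comfortably supra-threshold — which
is also what the steep published psychometric curves and the >90%
asymptote imply. The resulting near-threshold band ([0.25, 0.75] on the
normalized detection term) covers 3 contiguous intensities at the bottom
of the grid.

`simulate_training_curve` relaxes the gain and criterion exponentially
toward their trained values (`rate = 0` freezes day-1 performance);
`apply_manipulation("lidocaine")` zeroes δ(I) everywhere, collapsing
target responding to the false-alarm floor, and `"saline_control"` is
the identity.

## SDT metrics

d′ and criterion use the offset form with offset 0.001. The printed
formulas subtract/add the offset unconditionally, which still diverges
when a rate sits at the *wrong* corner (e.g. hit rate exactly 0), so
both adjusted rates are clamped into [offset, 1 − offset] before the
quantile; at the saturating corners this reproduces the intended
behavior exactly (d′(1, 0) = 2·Z(0.999) ≈ 6.1805). A consequence of the
one-sided offsets is that exact antisymmetry under rate exchange holds
only as the offset vanishes; the tests check it at offset 1e−9.

The sliding series uses trailing 50-trial windows ending at each trial
(series length n − 49). Hit rate comes from the targets inside the
window. With 20 catches in 360 trials a window holds 2.8 catches on
average and sometimes none; catch-free windows fall back to the running
session FA up to the current trial (full-session FA if no catch has
occurred yet), and each record's `fa_source` flags which convention fed
it so both can be compared. **Known estimator artifact:** windowed FA
estimates from 0–4 catch trials are coarse, and Z of a clamped coarse
rate is biased; because the running-FA fallback's denominator grows
within the session, a drift-free channel still shows a small spurious
criterion trend (measured ≈ −0.4 ± 0.18 per session at β = 0). The
default lick drift signal (+1.0 per session) is several times larger,
and the qualitative lick-vs-reflex drift contrast is unaffected, but
single-session windowed criterion values should be read with this bias
in mind.

## Psychometric fitting

Binomial maximum likelihood of p(I) = γ + (1 − γ − λ)Φ((log₁₀ I − μ)/σ)
over (μ, σ, γ, λ) with box constraints σ ∈ [0.01, 5], γ ∈ [0, 0.5],
λ ∈ [0, 0.1], via L-BFGS-B from a deterministic 30-point multi-start
grid (5 locations × 3 spreads × 2 guess rates). A Bayesian toolbox fit
was deliberately not emulated: the package's validation surface is
parameter recovery, for which a deterministic ML fit is sufficient and
dependency-free. γ is free rather than pinned to the catch FA rate,
since the catch rate is displayed as a separate reference line, not an
asymptote constraint. Flat data (observed-rate range < 1%, e.g. all
hit rates at γ) are flagged degenerate and carry no threshold.
Threshold = 10^μ, the intensity at the midpoint of the fitted range;
the near-threshold band collects intensities whose normalized term
Φ((log₁₀ I − μ)/σ) lies in [0.25, 0.75] (configurable), which is
contiguous in intensity rank by monotonicity.

## Similarity

Distance per intensity per session is the Euclidean norm of the
difference of the two 20-trial binary vectors, ordered by trial
occurrence (the metric is order-invariant; the ordering just fixes the
contract). distance² equals the Hamming mismatch count. Reference
lines: √(n − round(f·n)) for f = 0.95 and 0.50. Cohort summaries are
means with percentile-bootstrap 95% CIs (10,000 resamples by default,
seeded), resampling sessions with replacement. Under the coupled
observer, E[distance²] = 20·P(mismatch | I) with the mismatch
probability given by a bivariate-normal orthant integral; the test
suite checks the simulation against that closed form.

## Group statistics

Normality is screened (informationally) with a one-sample KS test on
the standardized sample; the pipeline is nonparametric regardless.
Paired contrasts use the two-sided Wilcoxon signed-rank test at
α = 0.025, exact null for n ≤ 25 with no zero or tied differences,
otherwise the normal approximation with continuity correction; families
of per-intensity comparisons are Bonferroni-corrected (family size
defaults to the number of intensities). All-zero difference vectors are
reported as p = 1 with a note. The 595 nm control comparison is a
one-sided Mann–Whitney U (test > control) at α = 0.05.

## CAP pipeline

Preprocessing is strictly zero-phase (forward-backward filtering) so
peak latencies are unbiased: 4th-order Butterworth band-pass
0.1–100 Hz, IIR mains notch, then polyphase resampling at the rational
ratio to exactly 8.3 kHz. The notch is moderately damped (Q = 5,
configurable) rather than the sharper notch typical of EEG software: a
high-Q notch rings for hundreds of milliseconds, and the ringing
excited by the large early volley superimposes a sloped baseline on the
late (C-fiber) window that measurably biases its peak latency (one
8.3 kHz sample at Q = 30 in the validation fixture); at Q = 5 the
ringing dies within ~20 ms and 60 Hz attenuation still exceeds 40 dB.
Epochs (−50 to +450 ms around each stimulus, configurable) are
averaged and normalized to the absolute maximum. Peak detection takes
the largest local extremum of |waveform| within the A-delta (5–50 ms)
and C (100–400 ms) windows, requires it to exceed 3× the pre-stimulus
RMS, and breaks ties toward the earlier latency. Conduction velocity is
distance/latency; the paw-to-electrode distance is a required user
input because it is preparation-specific and cannot be inferred from
latencies.

The synthetic recording generator sums two Gabor transients (Gaussian
envelope × cosine, peaking exactly at the nominal latencies, defaults
20 and 200 ms) on Gaussian sensor noise plus 60 Hz hum. Its defaults
are chosen for validation power rather than biophysical fidelity: the
late component is sharper than a real dispersed C volley so that its
peak is localizable to one sample under noise, and the 0.83 s ISI is
deliberately non-commensurate with the mains period (0.8 s would put
exactly 48 hum cycles between stimuli, making the hum stimulus-locked
and immune to averaging).

## What the simulations do and do not show

The generator reproduces the *statistical structure* of the task —
intensity-dependent detection with saturation, criterion drift confined
to the learned channel, partially coupled channels whose agreement
collapses for perceptually ambiguous stimuli, catch-rate floors — under
exactly the session geometry of the assay. It does not model lick
kinematics, reward-state satiety dynamics, photocurrent biophysics,
inter-mouse variability (cohorts default to identical parameters with
distinct seeds), or sequential dependencies beyond the deterministic
criterion drift. Passing recovery tests therefore validates the
*analysis code* under known ground truth; it is not evidence about
mice. Problem sizes in the tests and the acceptance script (40-session
cohorts, 100-stimulus recordings, 70-trial manipulations) mirror the
published study design.

## Numerical choices

- All RNG flows through `numpy.random.Generator` seeded per session /
  observer / bootstrap; cohort seeds derive from one master seed, and
  identical configs give byte-identical trial logs and reports.
- Rate clamps: [offset, 1 − offset] before normal quantiles; fitted
  psychometric probabilities clipped to [1e−10, 1 − 1e−10] inside the
  likelihood.
- Degenerate inputs raise typed errors (`UndefinedRateError`,
  `DegenerateFitError`) rather than returning NaN, except where the
  contract calls for a flag (degenerate fits, empty bands, p = 1 on
  all-zero differences).
- Trial logs round-trip through CSV with `float_precision="round_trip"`
  so re-analysis of written logs is bit-identical to in-memory analysis.
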