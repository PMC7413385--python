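"""Evoked compound action potential analysis on a synthetic recording.

A 100-stimulus dorsal-horn recording with A-delta and C fiber volleys at
20 and 200 ms is band-passed (0.1-100 Hz), notch-filtered, downsampled
to 8.3 kHz, epoch-averaged, normalized, and peak-detected.  Conduction
velocity = paw-to-electrode distance / latency.
"""

import lickreport as lr

recording = lr.synthesize_cap_recording(n_stimuli=100, sample_rate_hz=12_000.0, seed=1)
clean = lr.preprocess(recording)
average = lr.epoch_average(clean)
result = lr.detect_peaks(average, conduction_distance_m=0.040)

print(f"preprocessed: {recording.sample_rate_hz:.0f} Hz -> {clean.sample_rate_hz:.0f} Hz, "
      f"{result.n_epochs} epochs averaged, waveform normalized to |max| = 1")
for peak in result.peaks:
    v = result.velocities_m_s[peak.label]
    fiber = "fast myelinated" if peak.label == "A_delta" else "slow unmyelinated"
    print(f"  {peak.label}: latency {peak.latency_s * 1e3:.1f} ms, "
          f"normalized amplitude {peak.amplitude_normalized:+.2f}, "
          f"conduction velocity {v:.2f} m/s ({fiber} afferents)")
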