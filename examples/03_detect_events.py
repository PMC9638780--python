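"""Detect sleep spindles and spike-and-wave discharges, scored against
the generator's planted ground truth.

Spindles: 12-17 Hz band-pass, analytic envelope, thresholds in SDs of
the NREM envelope, duration 0.2-3 s, amplitude 25-750 uV.
SWDs: sliding-window PSD, 5-10 Hz fundamental with harmonic peaks above
the local spectral floor.
"""

import numpy as np

import eegconn as e

params = e.SimParams(duration_s=600.0, seed=6)
rng = np.random.default_rng(6)
array = e.load_array()
hyp, _ = e.sample_state_sequence(params, e.MUTANT, rng)
rec, truth = e.synth_recording(hyp, array, params, e.MUTANT, rng)

channel = 18  # right somatosensory analysis channel
nrem = hyp.sample_mask("NREM", rec.fs, rec.n_samples)

spindles = (e.detect_spindles(rec.channel(channel), rec.fs, nrem,
                              channel=channel) if nrem.any() else [])
planted = [ev for ev in truth["spindle"] if ev.channel == channel]
print(f"spindles on channel {channel}: {len(spindles)} detected, "
      f"{len(planted)} planted")
if spindles:
    d = [ev.duration_s for ev in spindles]
    f = [ev.properties["peak_freq_hz"] for ev in spindles]
    print(f"  duration {np.mean(d):.2f} +/- {np.std(d):.2f} s, "
          f"peak frequency {np.mean(f):.1f} Hz")

swds = e.detect_swd(rec.channel(channel), rec.fs)
print(f"SWDs: {len(swds)} detected, {len(truth['swd'])} planted")
for ev in swds[:5]:
    print(f"  {ev.start_s:7.1f}-{ev.end_s:7.1f} s, fundamental "
          f"{ev.properties['fundamental_hz']:.1f} Hz")

print("\nDetected event times feed the exclusion step (SWDs) and the "
      "coherogram alignment (spindle starts).")
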