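"""Spindle-locked dynamic connectivity and the high-connectivity bin count.

Aligns complex Morlet coefficients (12-17 Hz, 7 cycles) on detected
spindle starts, averages trial-wise imaginary coherence over the
short-distance pair set, and counts the time-frequency bins exceeding
70% of the coherogram maximum.
"""

import numpy as np

import eegconn as e
from eegconn.hypnogram import Hypnogram

array = e.load_array()
hyp = Hypnogram(("NREM",) * 36, 5.0)  # 3 minutes of NREM
short = e.pairs_by_threshold(array, 2.0, "short")
chans = sorted({c for p in short.pairs for c in p})

for preset in (e.CONTROL, e.MUTANT):
    params = e.SimParams(duration_s=180.0, seed=3)
    rng = np.random.default_rng(3)
    rec, _ = e.synth_recording(hyp, array, params, preset, rng)
    nrem = hyp.sample_mask("NREM", rec.fs, rec.n_samples)
    anchor = e.detect_spindles(rec.channel(18), rec.fs, nrem, channel=18)
    starts = np.array([ev.start_s for ev in anchor])
    tfrs = {c: e.morlet_tfr(rec.channel(c), rec.fs, starts) for c in chans}
    cohs = [e.event_coherogram(tfrs[a], tfrs[b])
            for a, b in sorted(short.pairs)
            if len(tfrs[a]) >= 2 and tfrs[a].shape == tfrs[b].shape]
    stat = e.high_connectivity(e.average_coherograms(cohs))
    print(f"{preset.name}: {len(starts)} spindle trials, "
          f"max |Im coherence| = {stat.maximum:.2f}, "
          f"{stat.n_supra_bins} of 22000 bins above 70% of max, "
          f"mean frequency {stat.mean_freq_hz:.1f} Hz")

print("\nA broad high-connectivity region around spindle onset yields "
      "many supra-threshold bins; weakened coupling fragments it.")
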