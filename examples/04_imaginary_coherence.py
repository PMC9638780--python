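"""Distance-resolved NREM functional connectivity.

Computes the Fisher-averaged imaginary-coherency (Z^-1) spectrum for
electrode pairs closer than 2 mm and farther than 2 mm, for a control
and a mutant animal.  Imaginary coherency ignores zero-lag (volume
conducted) mixing, so the short-distance sigma-band elevation reflects
genuinely lagged local coupling.
"""

import numpy as np

import eegconn as e
from eegconn.hypnogram import Hypnogram

array = e.load_array()
grid = e.coherence_grid()
sigma = (grid >= 12) & (grid <= 17)
hyp = Hypnogram(("NREM",) * 24, 5.0)  # 2 minutes of NREM
short = e.pairs_by_threshold(array, 2.0, "short")
long_ = e.pairs_by_threshold(array, 2.0, "long")

for preset in (e.CONTROL, e.MUTANT):
    params = e.SimParams(duration_s=120.0, seed=8)
    rng = np.random.default_rng(8)
    rec, _ = e.synth_recording(hyp, array, params, preset, rng)
    rec125 = e.decimate8(rec)  # 1 kHz -> 125 Hz
    spectra = e.state_all_pairs(rec125, hyp, "NREM",
                                sorted(short.pairs | long_.pairs))
    vals = list(spectra.values())
    g_short = e.group_average(vals, short)
    g_long = e.group_average(vals, long_)
    print(f"{preset.name}: sigma-band (12-17 Hz) mean Z^-1 "
          f"short(<2mm) = {g_short.values[sigma].mean():.3f}, "
          f"long(>2mm) = {g_long.values[sigma].mean():.3f}")

print("\nShort-distance pairs carry the lagged spindle-band coupling; "
      "the mutant preset halves the shared fraction, which shows up as "
      "a lower short-pair sigma value.")
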