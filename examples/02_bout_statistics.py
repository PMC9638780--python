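"""Brain-state bout statistics: control vs mutant preset.

Samples 2 h hypnograms for both genotype presets and prints percent
time, bout counts and mean bout durations.  The mutant preset has the
same per-state percent time in expectation but fewer, longer wake and
NREM bouts (its dwell-time means are scaled up).
"""

import eegconn as e
from eegconn.hypnogram import NREM, REM, WAKE

for preset in (e.CONTROL, e.MUTANT):
    params = e.SimParams(duration_s=2 * 3600, seed=4)
    hyp, _ = e.sample_state_sequence(params, preset)
    s = e.bout_statistics(hyp)
    print(f"\n{preset.name}:")
    for state in (WAKE, NREM, REM):
        print(f"  {state:4s}: {s.percent_time[state]:5.1f}% of time, "
              f"{s.n_bouts[state]:3d} bouts, "
              f"mean {s.mean_bout_duration_s[state]:6.1f} s")

print("\nFewer bouts at higher mean duration = a more consolidated, "
      "less fragmented sleep architecture.")
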