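"""Simulate a 5-minute 32-channel EEG recording and save it to disk.

Generates a semi-Markov wake/NREM/REM hypnogram, renders the voltage
traces (1/f background, state oscillations, planted spindles, SWDs,
artifacts, lagged coupling), and writes EDF + CSV + a YAML provenance
config.
"""

from pathlib import Path

import numpy as np

import eegconn as e
from eegconn.events import write_events_csv
from eegconn.hypnogram import write_hypnogram_csv
from eegconn.io import write_edf, write_sim_config

out = Path("scratch/example_recording")
out.mkdir(parents=True, exist_ok=True)

params = e.SimParams(duration_s=300.0, seed=1)
rng = np.random.default_rng(1)
array = e.load_array()

hyp, bouts = e.sample_state_sequence(params, e.CONTROL, rng)
rec, truth = e.synth_recording(hyp, array, params, e.CONTROL, rng)

write_edf(rec, out / "recording.edf")
write_hypnogram_csv(hyp, out / "hypnogram.csv")
write_events_csv(
    [ev for evs in truth.values() for ev in evs], out / "events.csv"
)
write_sim_config(params, e.CONTROL, out / "config.yaml")

counts = {k: len(v) for k, v in truth.items()}
print(f"recording: {rec.n_channels} channels x {rec.duration_s:.0f} s "
      f"at {rec.fs:.0f} Hz")
print(f"hypnogram: {len(hyp)} x {hyp.epoch_s:.0f} s epochs, "
      f"{len(bouts)} bouts")
print(f"planted ground truth: {counts}")
print("-> files in", out)
print("Each planted event list is the reference the detectors are "
      "scored against.")
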