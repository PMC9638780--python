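"""File I/O: EDF recordings, hypnogram/event CSV, simulation configs.

EDF (European Data Format) is the interchange format for the raw
recordings.  Reading goes through ``mne`` when it is installed; writing
uses a small built-in EDF+-free writer (16-bit, 1 s data records)
because no pre-installed library exposes an EDF encoder.  The writer is
validated against mne's independent reader in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .recording import Recording
from .synth import SimParams, GenotypePreset

_HDR = 256


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path, labels: list[str] | None = None) -> None:
    """Write a recording as 16-bit EDF with 1 s data records.

    The last partial second, if any, is zero-padded.  The accelerometer
    trace, when present, is stored as an extra signal labelled ``Accel``.
    """
    if rec.fs != int(rec.fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(rec.fs)
    signals = [rec.data[i] for i in range(rec.n_channels)]
    if labels is None:
        labels = [f"EEG ch{int(c)}" for c in rec.channel_ids]
    labels = list(labels)
    dims = ["uV"] * rec.n_channels
    if rec.accel is not None:
        signals.append(rec.accel)
        labels.append("Accel")
        dims.append("g")
    ns = len(signals)
    n_records = int(np.ceil(rec.n_samples / fs))

    pmaxs = []
    for sig in signals:
        m = float(np.max(np.abs(sig)))
        pmaxs.append(m if m > 0 else 1.0)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("synthetic", 80))
        fh.write(_field("eegconn", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(_HDR * (1 + ns), 8))
        fh.write(_field("", 44))
        fh.write(_field(n_records, 8))
        fh.write(_field(1, 8))
        fh.write(_field(ns, 4))
        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in range(ns):
            fh.write(_field("", 80))
        for d in dims:
            fh.write(_field(d, 8))
        for m in pmaxs:
            fh.write(_field(f"{-m:.6g}"[:8], 8))
        for m in pmaxs:
            fh.write(_field(f"{m:.6g}"[:8], 8))
        for _ in range(ns):
            fh.write(_field(-32768, 8))
        for _ in range(ns):
            fh.write(_field(32767, 8))
        for _ in range(ns):
            fh.write(_field("", 80))
        for _ in range(ns):
            fh.write(_field(fs, 8))
        for _ in range(ns):
            fh.write(_field("", 32))

        for r in range(n_records):
            for sig, m in zip(signals, pmaxs):
                seg = sig[r * fs:(r + 1) * fs]
                if len(seg) < fs:
                    seg = np.pad(seg, (0, fs - len(seg)))
                # physical -m..m maps onto digital -32768..32767
                dig = np.round(
                    (seg + m) / (2 * m) * 65535.0 - 32768.0
                ).astype("<i2")
                fh.write(dig.tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file into a Recording (requires mne)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    names = raw.ch_names
    accel = None
    eeg_rows = []
    ids = []
    for i, name in enumerate(names):
        if name.strip() == "Accel":
            accel = data[i]
        else:
            eeg_rows.append(data[i] * 1e6)  # mne returns volts
            tok = name.split("ch")[-1]
            ids.append(int(tok) if tok.strip().isdigit() else len(ids))
    return Recording(np.array(eeg_rows), raw.info["sfreq"],
                     channel_ids=np.array(ids), accel=accel)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_sim_config(params: SimParams, preset: GenotypePreset, path) -> None:
    """Persist the full generator configuration (YAML) for provenance."""
    doc = {"sim_params": _to_plain(params), "preset": _to_plain(preset)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_sim_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_to_plain(obj), indent=2, default=str))
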