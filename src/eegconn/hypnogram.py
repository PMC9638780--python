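"""Hypnograms: epoch-level brain-state labels and bout statistics.

A hypnogram is a sequence of 5 s epoch labels over WAKE / NREM / REM, with
EXCLUDED marking epochs dropped from analysis (movement artifacts, seizure
times).  A *bout* is a maximal run of identical non-excluded labels;
excluded epochs terminate bouts and are removed from the percent-time
denominator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .events import IntervalEvent
from .recording import Recording

WAKE, NREM, REM, EXCLUDED = "WAKE", "NREM", "REM", "EXCLUDED"
STATES = (WAKE, NREM, REM)
ALL_LABELS = STATES + (EXCLUDED,)


@dataclass(frozen=True)
class Hypnogram:
    labels: tuple[str, ...]
    epoch_s: float = 5.0

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("hypnogram must be non-empty")
        if self.epoch_s <= 0:
            raise ValueError("epoch length must be positive")
        bad = set(self.labels) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown labels: {bad}")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_s

    def state_mask(self, state: str) -> np.ndarray:
        """Boolean per-epoch mask for one state."""
        return np.asarray([lab == state for lab in self.labels])

    def sample_mask(self, state: str, fs: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask for one state at sampling rate ``fs``."""
        spe = int(round(self.epoch_s * fs))
        mask = np.zeros(n_samples, dtype=bool)
        for i, lab in enumerate(self.labels):
            if lab == state:
                mask[i * spe: min((i + 1) * spe, n_samples)] = True
        return mask


@dataclass(frozen=True)
class BoutSummary:
    """Per-state percent time, bout count and mean bout duration.

    ``percent_time`` is relative to non-excluded time; if every epoch is
    excluded all percents are NaN and ``defined`` is False.
    """

    percent_time: dict[str, float]
    n_bouts: dict[str, int]
    mean_bout_duration_s: dict[str, float]
    defined: bool = True


def _runs(labels) -> list[tuple[str, int]]:
    """Run-length encoding of a label sequence as (label, length)."""
    out: list[tuple[str, int]] = []
    for lab in labels:
        if out and out[-1][0] == lab:
            out[-1] = (lab, out[-1][1] + 1)
        else:
            out.append((lab, 1))
    return out


def bout_statistics(h: Hypnogram) -> BoutSummary:
    """Percent time, number of bouts and mean bout duration per state.

    EXCLUDED epochs split bouts and do not count toward any denominator.
    """
    epoch_counts = {s: 0 for s in STATES}
    bout_lengths: dict[str, list[int]] = {s: [] for s in STATES}
    for lab, length in _runs(h.labels):
        if lab == EXCLUDED:
            continue
        epoch_counts[lab] += length
        bout_lengths[lab].append(length)
    total = sum(epoch_counts.values())
    if total == 0:
        nan = {s: float("nan") for s in STATES}
        return BoutSummary(nan, {s: 0 for s in STATES}, dict(nan), defined=False)
    percent = {s: 100.0 * epoch_counts[s] / total for s in STATES}
    n_bouts = {s: len(bout_lengths[s]) for s in STATES}
    mean_dur = {
        s: (np.mean(bout_lengths[s]) * h.epoch_s if bout_lengths[s] else float("nan"))
        for s in STATES
    }
    return BoutSummary(percent, n_bouts, mean_dur)


def exclude_event_times(h: Hypnogram, events: list[IntervalEvent]) -> Hypnogram:
    """Mark every epoch overlapping any event interval as EXCLUDED.

    Epochs are half-open intervals [i*epoch_s, (i+1)*epoch_s); an epoch is
    excluded whole on any positive overlap.  Idempotent.
    """
    labels = list(h.labels)
    for ev in events:
        if ev.start_s < 0:
            raise ValueError("event starts before the recording")
        first = int(np.floor(ev.start_s / h.epoch_s))
        last = int(np.ceil(ev.end_s / h.epoch_s))  # exclusive
        for i in range(max(first, 0), min(last, len(labels))):
            labels[i] = EXCLUDED
    return replace(h, labels=tuple(labels))


def artifact_mask(
    rec: Recording,
    h: Hypnogram,
    threshold_uv: float = 750.0,
    channels: list[int] | None = None,
) -> Hypnogram:
    """Exclude epochs containing any sample with |v| > threshold.

    The rule is applied per-sample on the analysed channels (all channels
    by default); a contaminated epoch is dropped whole.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    data = rec.data if channels is None else np.stack(
        [rec.channel(c) for c in channels]
    )
    spe = int(round(h.epoch_s * rec.fs))
    labels = list(h.labels)
    hot = np.abs(data).max(axis=0) > threshold_uv
    for i in range(len(labels)):
        seg = hot[i * spe: (i + 1) * spe]
        if seg.size and seg.any():
            labels[i] = EXCLUDED
    return replace(h, labels=tuple(labels))


def auto_score(
    rec: Recording,
    channel: int | None = None,
    delta_fraction_min: float = 0.4,
    theta_delta_ratio_min: float = 1.0,
    quiet_accel_sd: float = 0.08,
    epoch_s: float = 5.0,
) -> Hypnogram:
    """Rule-based epoch scorer from one EEG channel plus accelerometer.

    Per epoch: low accelerometer variance marks sleep; within sleep, a
    theta(5-10 Hz)/delta(1-4 Hz) power ratio above
    ``theta_delta_ratio_min`` marks REM, a delta fraction of 1-48 Hz power
    above ``delta_fraction_min`` marks NREM; everything else is WAKE.
    This is a convenience surrogate for visual scoring, validated against
    synthetic ground truth only.
    """
    if rec.accel is None:
        raise ValueError("auto_score requires an accelerometer trace")
    x = rec.data[0] if channel is None else rec.channel(channel)
    spe = int(round(epoch_s * rec.fs))
    n_epochs = len(x) // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    labels = []
    for i in range(n_epochs):
        seg = x[i * spe: (i + 1) * spe]
        acc = rec.accel[i * spe: (i + 1) * spe]
        f, p = sps.welch(seg, fs=rec.fs, nperseg=min(len(seg), int(2 * rec.fs)))
        band = lambda lo, hi: p[(f >= lo) & (f <= hi)].sum()
        delta, theta, total = band(1, 4), band(5, 10), band(1, 48)
        quiet = np.std(acc) < quiet_accel_sd
        if quiet and total > 0:
            if theta > theta_delta_ratio_min * delta and delta / total < delta_fraction_min:
                labels.append(REM)
            elif delta / total >= delta_fraction_min:
                labels.append(NREM)
            else:
                labels.append(WAKE)
        else:
            labels.append(WAKE)
    return Hypnogram(tuple(labels), epoch_s)


def write_hypnogram_csv(h: Hypnogram, path) -> None:
    frame = pd.DataFrame(
        {"epoch_index": np.arange(len(h)), "state": list(h.labels)}
    )
    header = f"# epoch_s={h.epoch_s}\n"
    if hasattr(path, "write"):
        path.write(header)
        frame.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)


def read_hypnogram_csv(path) -> Hypnogram:
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    epoch_s = 5.0
    lines = text.splitlines()
    if lines and lines[0].startswith("#"):
        if "epoch_s=" in lines[0]:
            epoch_s = float(lines[0].split("epoch_s=")[1])
        lines = lines[1:]
    frame = pd.read_csv(io.StringIO("\n".join(lines)))
    return Hypnogram(tuple(frame["state"]), epoch_s)
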