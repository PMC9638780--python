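"""Spike-and-wave discharge (SWD) detection.

SWDs — the EEG correlate of absence seizures — are periodic
high-amplitude discharges with a 5-10 Hz fundamental whose power
spectral density shows peaks at the harmonics of the fundamental.  The
detector slides a short PSD window along a single channel, scores the
harmonic structure relative to the local spectral floor, gates on
amplitude, and merges qualifying windows into events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .events import IntervalEvent


@dataclass
class SwdParams:
    window_s: float = 1.0
    step_s: float = 0.5
    band_lo_hz: float = 5.0
    band_hi_hz: float = 10.0
    n_harmonics: int = 2
    prominence_factor: float = 3.0   # harmonic peak vs local median power
    amplitude_floor_uv: float = 300.0
    # > window_s, so an event needs two overlapping marked windows; a
    # single spectrally-unlucky noise window cannot become an event
    min_duration_s: float = 1.25
    merge_gap_s: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window and step must be positive")
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise ValueError("invalid fundamental band")


def _peak_ratio(freqs, psd, target, df):
    """PSD peak within one bin of ``target`` over the local median in a
    +/-3 Hz neighbourhood (peak bins excluded)."""
    peak_sel = np.abs(freqs - target) <= df * 1.001
    hood = (np.abs(freqs - target) <= 3.0) & ~peak_sel
    if not peak_sel.any() or not hood.any():
        return 0.0
    floor = np.median(psd[hood])
    peak = psd[peak_sel].max()
    return float(peak / floor) if floor > 0 else np.inf


def harmonic_score(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float] = (5.0, 10.0),
    n_harmonics: int = 2,
) -> tuple[float, float]:
    """Locate the fundamental and score its harmonic structure.

    The fundamental is the maximal PSD peak inside ``band``.  The score is
    the minimum, over harmonics k = 2..n_harmonics+1, of the peak power
    near k*f0 (within one PSD bin) divided by the local median power in a
    +/-3 Hz neighbourhood excluding the peak bins.  A periodic discharge
    yields a large score; a pure sinusoid or broadband noise does not.
    """
    freqs = np.asarray(freqs)
    psd = np.asarray(psd)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("PSD grid does not cover the fundamental band")
    if freqs[-1] < (n_harmonics + 1) * band[1]:
        raise ValueError("PSD grid does not cover the requested harmonics")
    band_idx = np.flatnonzero(in_band)
    f0_idx = band_idx[np.argmax(psd[band_idx])]
    f0 = float(freqs[f0_idx])
    df = freqs[1] - freqs[0]
    score = min(
        _peak_ratio(freqs, psd, k * f0, df)
        for k in range(2, n_harmonics + 2)
    )
    return f0, float(score)


def detect_swd(
    x: np.ndarray, fs: float, params: SwdParams | None = None
) -> list[IntervalEvent]:
    """Detect SWDs on a single channel.

    Windows passing both the amplitude floor and the harmonic-score
    criterion are marked; marked windows closer than ``merge_gap_s``
    merge; events shorter than ``min_duration_s`` are dropped.  Scores
    are power *ratios*, so detection above the floor is invariant to
    amplitude scaling.
    """
    if params is None:
        params = SwdParams()
    x = np.asarray(x, dtype=float)
    nper = int(round(params.window_s * fs))
    step = int(round(params.step_s * fs))
    if len(x) < nper:
        raise ValueError("signal shorter than one analysis window")
    if fs / 2 <= (params.n_harmonics + 1) * params.band_hi_hz:
        raise ValueError("sampling rate too low for the requested harmonics")

    marked: list[tuple[float, float, float]] = []  # (start, end, f0)
    for i0 in range(0, len(x) - nper + 1, step):
        seg = x[i0:i0 + nper]
        if np.ptp(seg) < params.amplitude_floor_uv:
            continue
        freqs, psd = sps.periodogram(seg, fs=fs, window="hann")
        f0, score = harmonic_score(
            freqs, psd, (params.band_lo_hz, params.band_hi_hz),
            params.n_harmonics,
        )
        # the fundamental itself must stand out of the local floor too
        fund_ratio = _peak_ratio(freqs, psd, f0, freqs[1] - freqs[0])
        if score >= params.prominence_factor and \
                fund_ratio >= params.prominence_factor:
            marked.append((i0 / fs, (i0 + nper) / fs, f0))

    events: list[IntervalEvent] = []
    for start, end, f0 in marked:
        if events and start - events[-1].end_s <= params.merge_gap_s:
            prev = events[-1]
            prev.end_s = max(prev.end_s, end)
            prev.properties["fundamentals"].append(f0)
        else:
            events.append(IntervalEvent(
                "swd", None, start, end, {"fundamentals": [f0]}
            ))

    out = []
    for ev in events:
        if ev.duration_s < params.min_duration_s:
            continue
        fund = float(np.median(ev.properties.pop("fundamentals")))
        ev.properties.update(
            {"fundamental_hz": fund, "duration_s": ev.duration_s}
        )
        out.append(ev)
    return out
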