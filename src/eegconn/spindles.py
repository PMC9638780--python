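"""Sleep-spindle detection and multi-electrode spindle grouping.

Spindles are brief 12-17 Hz bursts during NREM.  Detection follows the
envelope-threshold scheme common to rodent toolboxes: band-pass, analytic
envelope, thresholds expressed in SDs of the envelope over all NREM
samples of the channel above its mean (detection at mean + 3 SD,
boundaries extended to the mean + 1.5 SD crossings, noise exclusion at
mean + 35 SD), duration limits 0.2-3 s,
minimum inter-event gap 0.2 s, and an absolute peak-to-trough amplitude
window of 25-750 uV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .events import IntervalEvent
from .geometry import ElectrodeArray, pairwise_distances


@dataclass
class SpindleParams:
    band_lo_hz: float = 12.0
    band_hi_hz: float = 17.0
    min_dur_s: float = 0.2
    max_dur_s: float = 3.0
    min_gap_s: float = 0.2
    amp_min_uv: float = 25.0
    amp_max_uv: float = 750.0
    boundary_sd: float = 1.5
    detect_sd: float = 3.0
    noise_sd: float = 35.0
    smooth_ms: float = 50.0          # moving-average span for the envelope
    transition_hz: float = 1.0       # FIR band edge width

    def __post_init__(self) -> None:
        if not 0 < self.min_dur_s < self.max_dur_s:
            raise ValueError("need 0 < min_dur < max_dur")
        if not self.boundary_sd < self.detect_sd < self.noise_sd:
            raise ValueError("need boundary_sd < detect_sd < noise_sd")
        if not self.amp_min_uv < self.amp_max_uv:
            raise ValueError("need amp_min < amp_max")


def bandpass_sigma(x: np.ndarray, fs: float, params: SpindleParams) -> np.ndarray:
    """Zero-phase FIR band-pass to the spindle band.

    The FIR is symmetric (linear phase), so a single centred FFT
    convolution applies it with zero group delay and preserves event
    timing for coherogram alignment.
    """
    numtaps = int(3 * fs / params.transition_hz) | 1
    numtaps = min(numtaps, 2 * (len(x) // 3) - 1)
    if numtaps < 11:
        raise ValueError("signal too short for the band-pass filter")
    taps = sps.firwin(
        numtaps, [params.band_lo_hz, params.band_hi_hz],
        pass_zero=False, fs=fs,
    )
    return sps.fftconvolve(x, taps, mode="same")


def _envelope(xf: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    env = np.abs(sps.hilbert(xf))
    span = max(int(round(smooth_ms * fs / 1000.0)), 1)
    kernel = np.ones(span) / span
    return np.convolve(env, kernel, mode="same")


def detect_spindles(
    x: np.ndarray,
    fs: float,
    nrem_mask: np.ndarray,
    params: SpindleParams | None = None,
    channel: int | None = None,
) -> list[IntervalEvent]:
    """Detect spindles on one channel within NREM time.

    ``nrem_mask`` is a per-sample boolean mask of scored NREM.  The SD
    baseline is the envelope SD over all NREM samples of this channel.
    Each event carries duration, peak-to-trough amplitude of the
    band-passed trace, peak frequency, and 12-17 Hz band power.
    """
    if params is None:
        params = SpindleParams()
    x = np.asarray(x, dtype=float)
    nrem_mask = np.asarray(nrem_mask, dtype=bool)
    if nrem_mask.shape != x.shape:
        raise ValueError("nrem_mask must match the signal sample-for-sample")
    if not nrem_mask.any():
        raise ValueError("empty NREM mask")
    if fs < 2 * params.band_hi_hz:
        raise ValueError("sampling rate below twice the band top")

    xf = bandpass_sigma(x, fs, params)
    env = _envelope(xf, fs, params.smooth_ms)
    sd = env[nrem_mask].std()
    if sd == 0:
        return []

    # thresholds in SDs of the NREM envelope above its mean (the
    # standard form of envelope-threshold spindle detectors)
    mu = env[nrem_mask].mean()
    detect_th = mu + params.detect_sd * sd
    bound_th = mu + params.boundary_sd * sd
    noise_th = mu + params.noise_sd * sd

    above_bound = env >= bound_th
    # candidate cores: NREM samples at/above the detection threshold
    core = (env >= detect_th) & nrem_mask
    if not core.any():
        return []

    # extend each core run to the surrounding boundary-threshold crossings
    starts = list(np.flatnonzero(np.diff(np.r_[0, core.astype(np.int8)]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[core.astype(np.int8), 0]) == -1))
    intervals = []
    for s, e in zip(starts, ends):
        while s > 0 and above_bound[s - 1] and nrem_mask[s - 1]:
            s -= 1
        while e + 1 < len(env) and above_bound[e + 1] and nrem_mask[e + 1]:
            e += 1
        intervals.append([s, e + 1])  # half-open

    # merge candidates separated by less than the minimum gap
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if (s - merged[-1][1]) / fs < params.min_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    events: list[IntervalEvent] = []
    for s, e in merged:
        dur = (e - s) / fs
        if not params.min_dur_s <= dur <= params.max_dur_s:
            continue
        seg = xf[s:e]
        p2t = float(seg.max() - seg.min())
        if not params.amp_min_uv <= p2t <= params.amp_max_uv:
            continue
        if env[s:e].max() >= noise_th:
            continue
        freqs, psd = sps.periodogram(seg, fs=fs)
        sel = (freqs >= params.band_lo_hz) & (freqs <= params.band_hi_hz)
        peak_f = float(freqs[sel][np.argmax(psd[sel])]) if sel.any() else np.nan
        band_power = float(psd[sel].sum() * (freqs[1] - freqs[0])) if sel.any() else np.nan
        events.append(IntervalEvent(
            "spindle", channel, s / fs, e / fs,
            {"duration_s": dur, "amplitude_uv": p2t,
             "peak_freq_hz": peak_f, "band_power": band_power},
        ))
    return events


def multisite_spindles(
    per_channel_events: dict[int, list[IntervalEvent]],
    array: ElectrodeArray,
    radius_mm: float = 2.0,
) -> tuple[int, float]:
    """Group co-occurring spindles on nearby electrodes.

    Spindles on different channels whose electrodes are within
    ``radius_mm`` of each other and whose intervals overlap in time are
    merged by transitive closure into one multi-electrode spindle.
    Returns the number of groups spanning >= 2 electrodes and the mean
    number of distinct electrodes per such group (NaN when there are
    none).
    """
    dmat = pairwise_distances(array)
    id_to_idx = {int(cid): i for i, cid in enumerate(array.channel_ids)}
    nodes: list[tuple[int, IntervalEvent]] = []
    for ch, evs in per_channel_events.items():
        if ch not in id_to_idx:
            raise KeyError(f"unknown channel id {ch}")
        nodes.extend((ch, ev) for ev in evs)

    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(len(nodes)):
        ch_i, ev_i = nodes[i]
        for j in range(i + 1, len(nodes)):
            ch_j, ev_j = nodes[j]
            if ch_i == ch_j:
                continue
            if dmat[id_to_idx[ch_i], id_to_idx[ch_j]] > radius_mm:
                continue
            if ev_i.overlaps(ev_j):
                union(i, j)

    groups: dict[int, set[int]] = {}
    for i, (ch, _) in enumerate(nodes):
        groups.setdefault(find(i), set()).add(ch)
    sizes = [len(chs) for chs in groups.values() if len(chs) >= 2]
    n_multi = len(sizes)
    mean_sites = float(np.mean(sizes)) if sizes else float("nan")
    return n_multi, mean_sites
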