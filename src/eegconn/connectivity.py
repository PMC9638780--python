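"""Static functional connectivity via the imaginary part of coherency.

The imaginary part of complex coherency,
Im( Sxy / sqrt(Sxx * Syy) ), is insensitive to instantaneous
(volume-conducted) mixing: any zero-lag linear combination of sources
contributes only to the real part.  Nonzero values therefore indicate
genuinely time-lagged coupling.

Pipeline, per electrode pair and brain state: decimate the 1 kHz
recording by 8 (order-8 Chebyshev-I anti-aliasing, as in
``scipy.signal.decimate``), estimate the coherency per 5 s epoch from
Welch cross/auto spectra on the 99-bin grid (1-50 Hz, 0.5 Hz steps),
Fisher-z each epoch's imaginary coherency, average the z-scores across
epochs, and inverse-transform to the Z^-1 value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal as sps

from .geometry import ElectrodeArray, PairSet
from .hypnogram import Hypnogram
from .recording import Recording

GRID_LO_HZ = 1.0
GRID_HI_HZ = 50.0
GRID_STEP_HZ = 0.5
N_BINS = 99

WELCH_SEGMENT_S = 2.0  # 2 s Hann segments, 50% overlap -> 0.5 Hz native bins


def coherence_grid() -> np.ndarray:
    """The 99-bin frequency grid: 1-50 Hz in 0.5 Hz steps."""
    return GRID_LO_HZ + GRID_STEP_HZ * np.arange(N_BINS)


@dataclass(frozen=True)
class CoherencePair:
    """Fisher-inverse averaged imaginary coherency for one channel pair.

    Canonical orientation is lower id -> higher id; swapping the
    orientation negates every bin value.
    """

    pair: tuple[int, int]
    z_inv_values: np.ndarray
    n_epochs: int
    freqs: np.ndarray = field(default_factory=coherence_grid)

    def __post_init__(self) -> None:
        v = np.asarray(self.z_inv_values, dtype=float)
        if v.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {v.shape}")
        if np.any(np.abs(v) >= 1):
            raise ValueError("Z^-1 values must lie in (-1, 1)")
        if self.n_epochs < 1:
            raise ValueError("need at least one epoch")
        object.__setattr__(self, "z_inv_values", v)


@dataclass(frozen=True)
class GroupSpectrum:
    """Mean Z^-1 spectrum for a pair selection or region pair."""

    descriptor: str
    values: np.ndarray
    freqs: np.ndarray = field(default_factory=coherence_grid)
    animal_id: str | None = None


def decimate8(rec: Recording) -> Recording:
    """Downsample by 8 after order-8 Chebyshev-I anti-alias filtering."""
    if rec.fs % 8 != 0:
        raise ValueError(f"sampling rate {rec.fs} not divisible by 8")
    data = sps.decimate(rec.data, 8, ftype="iir", axis=-1, zero_phase=True)
    accel = (
        sps.decimate(rec.accel, 8, ftype="iir", zero_phase=True)
        if rec.accel is not None else None
    )
    return Recording(data, rec.fs / 8, channel_ids=rec.channel_ids.copy(),
                     accel=accel)


def _segment_ffts(x: np.ndarray, fs: float) -> np.ndarray:
    """rFFTs of overlapping detrended Hann-windowed Welch segments."""
    nperseg = int(round(WELCH_SEGMENT_S * fs))
    if len(x) < nperseg:
        raise ValueError("trace shorter than one Welch segment")
    step = nperseg // 2
    win = sps.get_window("hann", nperseg)
    n_segs = (len(x) - nperseg) // step + 1
    segs = np.stack([x[i * step:i * step + nperseg] for i in range(n_segs)])
    segs = (segs - segs.mean(axis=1, keepdims=True)) * win
    return np.fft.rfft(segs, axis=1)


def _grid_indices(fs: float) -> np.ndarray:
    nperseg = int(round(WELCH_SEGMENT_S * fs))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    grid = coherence_grid()
    df = freqs[1] - freqs[0]
    idx = np.round((grid - freqs[0]) / df).astype(int)
    if idx[-1] >= len(freqs) or not np.allclose(freqs[idx], grid):
        raise ValueError(
            "Welch grid does not contain the 0.5 Hz bins "
            "(sampling rate must make 2 s segments hold whole cycles)"
        )
    return idx


def _imcoh_from_ffts(fx: np.ndarray, fy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sxy = (fx * np.conj(fy)).mean(axis=0)[idx]
    sxx = (np.abs(fx) ** 2).mean(axis=0)[idx]
    syy = (np.abs(fy) ** 2).mean(axis=0)[idx]
    denom = np.sqrt(sxx * syy)
    out = np.full(len(idx), np.nan)
    ok = denom > 0
    if not ok.all():
        warnings.warn("zero-power bins excluded from coherency")
    out[ok] = np.imag(sxy[ok] / denom[ok])
    return np.clip(out, -1.0, 1.0)


def imaginary_coherency(x: np.ndarray, y: np.ndarray, fs: float) -> np.ndarray:
    """Imaginary part of Welch coherency on the 99-bin grid.

    Uses 2 s Hann segments with 50% overlap so the native resolution is
    exactly 0.5 Hz.  Bins where either channel has zero power are NaN
    (excluded from averaging) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    return _imcoh_from_ffts(
        _segment_ffts(x, fs), _segment_ffts(y, fs), _grid_indices(fs)
    )


def fisher_mean(values: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """tanh(mean(atanh(v))): Fisher-z average of correlation-like values.

    atanh is odd, so signed imaginary-coherency values keep their sign.
    Values at |v| >= 1 are clipped to 1-1e-12 with a warning; NaNs are
    ignored.
    """
    v = np.asarray(values, dtype=float)
    if np.any(np.abs(v) >= 1):
        warnings.warn("coherency values at |v| >= 1 clipped for Fisher z")
        v = np.clip(v, -1 + 1e-12, 1 - 1e-12)
    with np.errstate(invalid="ignore"):
        return np.tanh(np.nanmean(np.arctanh(v), axis=axis))


def _state_epoch_slices(h: Hypnogram, state: str, fs: float,
                        n_samples: int) -> list[slice]:
    spe = int(round(h.epoch_s * fs))
    nper = int(round(WELCH_SEGMENT_S * fs))
    out = []
    for i, lab in enumerate(h.labels):
        if lab != state:
            continue
        stop = min((i + 1) * spe, n_samples)
        if stop - i * spe >= nper:  # epochs shorter than a segment skipped
            out.append(slice(i * spe, stop))
    return out


def state_pair_spectrum(
    rec: Recording, h: Hypnogram, state: str, pair: tuple[int, int]
) -> CoherencePair:
    """Z^-1 imaginary-coherency spectrum for one pair in one state."""
    return state_all_pairs(rec, h, state, [tuple(sorted(pair))])[
        tuple(sorted(pair))
    ]


def state_all_pairs(
    rec: Recording,
    h: Hypnogram,
    state: str,
    pairs: list[tuple[int, int]],
) -> dict[tuple[int, int], CoherencePair]:
    """Z^-1 spectra for many pairs, sharing per-channel segment FFTs."""
    slices = _state_epoch_slices(h, state, rec.fs, rec.n_samples)
    if not slices:
        raise ValueError(f"no usable epochs of state {state}")
    idx = _grid_indices(rec.fs)
    channels = sorted({c for p in pairs for c in p})
    # per channel: list of per-epoch segment-FFT stacks
    ffts = {
        c: [_segment_ffts(rec.channel(c)[sl], rec.fs) for sl in slices]
        for c in channels
    }
    out = {}
    for pair in pairs:
        lo, hi = sorted(pair)
        per_epoch = np.stack([
            _imcoh_from_ffts(fx, fy, idx)
            for fx, fy in zip(ffts[lo], ffts[hi])
        ])
        z = np.clip(fisher_mean(per_epoch, axis=0), -1 + 1e-12, 1 - 1e-12)
        out[(lo, hi)] = CoherencePair((lo, hi), z, len(slices))
    return out


def group_average(
    pairs: list[CoherencePair], sel: PairSet, animal_id: str | None = None
) -> GroupSpectrum:
    """Arithmetic mean of Z^-1 spectra across the selected pairs."""
    wanted = set(sel.pairs)
    chosen = [p for p in pairs if p.pair in wanted]
    if not chosen:
        raise ValueError("empty pair selection")
    values = np.mean([p.z_inv_values for p in chosen], axis=0)
    return GroupSpectrum(
        f"{sel.side}@{sel.threshold_mm}mm", values, animal_id=animal_id
    )


def region_coherence(
    rec: Recording,
    h: Hypnogram,
    state: str,
    array: ElectrodeArray,
    region_a: tuple[str, str],
    region_b: tuple[str, str],
    animal_id: str | None = None,
) -> GroupSpectrum:
    """Regional coherency: member-channel voltages are averaged *first*,
    then one Z^-1 spectrum is computed between the two regional signals."""
    groups = array.region_groups()
    for r in (region_a, region_b):
        if not groups.get(r):
            raise ValueError(f"empty region group {r}")
    xa = np.mean([rec.channel(c) for c in groups[region_a]], axis=0)
    xb = np.mean([rec.channel(c) for c in groups[region_b]], axis=0)
    slices = _state_epoch_slices(h, state, rec.fs, rec.n_samples)
    if not slices:
        raise ValueError(f"no usable epochs of state {state}")
    idx = _grid_indices(rec.fs)
    per_epoch = np.stack([
        _imcoh_from_ffts(_segment_ffts(xa[sl], rec.fs),
                         _segment_ffts(xb[sl], rec.fs), idx)
        for sl in slices
    ])
    values = np.clip(fisher_mean(per_epoch, axis=0), -1 + 1e-12, 1 - 1e-12)
    name = f"{region_a[0]} {region_a[1]} - {region_b[0]} {region_b[1]}"
    return GroupSpectrum(name, values, animal_id=animal_id)
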