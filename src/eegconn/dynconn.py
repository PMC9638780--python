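"""Spindle-locked dynamic connectivity: Morlet coherograms.

For each detected spindle, complex Morlet coefficients (7 cycles,
kernel truncated at 3 SD of the Gaussian envelope) are extracted for the
11 frequency components 12-17 Hz (0.5 Hz steps) over a window from
500 ms before to 1500 ms after spindle start (2000 time points at 1 ms).
Trial-averaged imaginary coherence between two channels is

    value(f, t) = Im( sum_trials Wx conj(Wy)
                      / sqrt(sum |Wx|^2 * sum |Wy|^2) )

The summary statistic counts time-frequency bins whose magnitude
exceeds 70% of the per-animal coherogram maximum, and the mean frequency
of those bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

TF_LO_HZ = 12.0
TF_HI_HZ = 17.0
TF_STEP_HZ = 0.5
N_FREQS = 11

WINDOW_MS = (-500, 1500)
N_TIMES = 2000

MORLET_CYCLES = 7.0
KERNEL_SD_TRUNC = 3.0


def tf_freqs() -> np.ndarray:
    """The 11-component grid: 12-17 Hz in 0.5 Hz steps."""
    return TF_LO_HZ + TF_STEP_HZ * np.arange(N_FREQS)


def tf_times_ms() -> np.ndarray:
    """The 2000-point time grid in ms relative to spindle start."""
    return np.arange(WINDOW_MS[0], WINDOW_MS[1])


@dataclass(frozen=True)
class Coherogram:
    """Imaginary coherence on the 11 x 2000 time-frequency grid."""

    values: np.ndarray
    n_trials: int
    freqs: np.ndarray = field(default_factory=tf_freqs)
    times_ms: np.ndarray = field(default_factory=tf_times_ms)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FREQS, N_TIMES):
            raise ValueError(f"expected ({N_FREQS}, {N_TIMES}), got {v.shape}")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("|imaginary coherence| must be <= 1")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class HighConnStat:
    """70%-of-maximum high-connectivity summary."""

    maximum: float
    n_supra_bins: int
    mean_freq_hz: float      # NaN when the coherogram is degenerate
    fraction: float = 0.70


def morlet_kernel(f0: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet: 7 cycles, truncated at +/-3 SD."""
    sigma_t = MORLET_CYCLES / (2.0 * np.pi * f0)
    half = int(np.ceil(KERNEL_SD_TRUNC * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-t**2 / (2 * sigma_t**2)) * np.exp(2j * np.pi * f0 * t)
    # unit-energy normalisation keeps coefficient scale comparable across f
    return kernel / np.sqrt(np.sum(np.abs(kernel) ** 2))


def morlet_tfr(
    x: np.ndarray,
    fs: float,
    event_starts_s: np.ndarray,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Event-locked complex Morlet coefficients.

    Returns an array of shape (n_kept_trials, n_freqs, 2000): the
    convolution of the signal with each wavelet, sampled on the 1 ms grid
    from -500 to +1500 ms around each event start.  Trials whose window
    (including the wavelet support) exceeds the record bounds are
    dropped.
    """
    if freqs is None:
        freqs = tf_freqs()
    x = np.asarray(x, dtype=float)
    if fs < 2 * max(freqs):
        raise ValueError("sampling rate below twice the top frequency")
    kernels = [morlet_kernel(float(f0), fs) for f0 in freqs]
    pad = max(len(k) for k in kernels) // 2
    rel_s = tf_times_ms() / 1000.0  # time grid relative to event start
    trials = []
    for t0 in np.asarray(event_starts_s, dtype=float):
        idx = np.round((t0 + rel_s) * fs).astype(int)
        if idx[0] < 0 or idx[-1] >= len(x):
            continue  # window outside the record: trial dropped
        # convolve only a padded neighbourhood of the window; samples
        # whose wavelet support leaves the record use zero padding
        lo = idx[0] - pad
        hi = idx[-1] + pad + 1
        seg = x[max(lo, 0):min(hi, len(x))]
        seg = np.pad(seg, (max(-lo, 0), max(hi - len(x), 0)))
        coeffs = np.stack([
            sps.fftconvolve(seg, k, mode="same") for k in kernels
        ])
        trials.append(coeffs[:, idx - lo])
    return np.array(trials)


def event_coherogram(tfr_x: np.ndarray, tfr_y: np.ndarray) -> Coherogram:
    """Trial-averaged imaginary coherence of two coefficient stacks."""
    tfr_x = np.asarray(tfr_x)
    tfr_y = np.asarray(tfr_y)
    if tfr_x.shape != tfr_y.shape:
        raise ValueError("coefficient stacks must have equal shape")
    n_trials = tfr_x.shape[0]
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    cross = np.sum(tfr_x * np.conj(tfr_y), axis=0)
    denom = np.sqrt(
        np.sum(np.abs(tfr_x) ** 2, axis=0) * np.sum(np.abs(tfr_y) ** 2, axis=0)
    )
    values = np.zeros(cross.shape)
    ok = denom > 0
    values[ok] = np.imag(cross[ok] / denom[ok])
    return Coherogram(values, n_trials)


def average_coherograms(cohs: list[Coherogram]) -> Coherogram:
    """Mean over pairs (same grid); n_trials is the minimum across pairs."""
    if not cohs:
        raise ValueError("no coherograms to average")
    values = np.mean([c.values for c in cohs], axis=0)
    return Coherogram(values, min(c.n_trials for c in cohs))


def high_connectivity(coh: Coherogram, fraction: float = 0.70) -> HighConnStat:
    """Count bins whose |value| exceeds ``fraction`` of the maximum.

    The threshold is relative, so the count is invariant under global
    scaling of the coherogram.  A flat-zero coherogram yields count 0
    and undefined (NaN) mean frequency.
    """
    mag = np.abs(coh.values)
    m = float(mag.max())
    if m == 0:
        return HighConnStat(0.0, 0, float("nan"), fraction)
    supra = mag > fraction * m
    n = int(supra.sum())
    freq_map = np.broadcast_to(coh.freqs[:, None], mag.shape)
    mean_f = float(freq_map[supra].mean()) if n else float("nan")
    return HighConnStat(m, n, mean_f, fraction)
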