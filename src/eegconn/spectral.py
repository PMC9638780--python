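"""Per-epoch multitaper log-power spectra and band summaries.

Power for each 5 s epoch is estimated with DPSS multitapers (NW = 4,
7 tapers, i.e. ~0.8 Hz smoothing on a 5 s window), interpolated onto the
fixed 0.2-48 Hz grid in 0.2 Hz steps (240 bins), and expressed as log10
power per bin.  State averages are arithmetic means of the log spectra
over that state's non-excluded epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .hypnogram import Hypnogram

GRID_LO_HZ = 0.2
GRID_HI_HZ = 48.0
GRID_STEP_HZ = 0.2
N_BINS = 240

NW = 4.0
N_TAPERS = 7


def psd_grid() -> np.ndarray:
    """The mandated 0.2-48 Hz grid (240 bins, 0.2 Hz steps)."""
    return GRID_LO_HZ + GRID_STEP_HZ * np.arange(N_BINS)


@dataclass(frozen=True)
class PSD:
    """Log10 power on the fixed 240-bin grid."""

    values: np.ndarray
    freqs: np.ndarray = field(default_factory=psd_grid)
    n_tapers: int = N_TAPERS
    epoch_s: float = 5.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite PSD values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands (inclusive edges)."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (1.0, 4.0),
            "theta": (5.0, 10.0),
            "sigma": (12.0, 17.0),
            "beta": (17.0, 30.0),
            "gamma": (30.0, 48.0),
        }
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band scheme must be non-empty")
        grid = psd_grid()
        for name, (lo, hi) in self.bands.items():
            if lo >= hi or lo < grid[0] or hi > grid[-1]:
                raise ValueError(f"band {name} outside the PSD grid")


def epoch_psd(segment: np.ndarray, fs: float, epoch_s: float = 5.0) -> PSD:
    """Multitaper log10 power of one epoch on the fixed grid."""
    segment = np.asarray(segment, dtype=float)
    expected = int(round(epoch_s * fs))
    if len(segment) != expected:
        raise ValueError(
            f"segment length {len(segment)} != epoch_s*fs = {expected}"
        )
    if not np.all(np.isfinite(segment)):
        raise ValueError("non-finite samples")
    tapers = dpss(len(segment), NW, N_TAPERS)
    n = len(segment)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros(len(freqs))
    for w in tapers:
        ft = np.fft.rfft(w * segment)
        spec += (np.abs(ft) ** 2)
    spec /= N_TAPERS * fs
    power = np.interp(psd_grid(), freqs, spec)
    # floor avoids -inf for identically-zero segments
    return PSD(np.log10(np.maximum(power, 1e-300)), epoch_s=epoch_s)


def state_average_psd(
    psds: list[PSD], h: Hypnogram, state: str
) -> PSD:
    """Mean log10 spectrum over the state's (non-excluded) epochs."""
    sel = [p for p, lab in zip(psds, h.labels) if lab == state]
    if not sel:
        raise ValueError(f"no epochs of state {state}")
    return PSD(np.mean([p.values for p in sel], axis=0),
               epoch_s=sel[0].epoch_s)


def band_average(psd: PSD, scheme: BandScheme | None = None) -> dict[str, float]:
    """Mean value over the bins whose centres fall inside each band."""
    if scheme is None:
        scheme = BandScheme()
    out = {}
    for name, (lo, hi) in scheme.bands.items():
        sel = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
        out[name] = float(psd.values[sel].mean())
    return out


def recording_psds(
    x: np.ndarray, fs: float, h: Hypnogram
) -> list[PSD]:
    """Per-epoch PSDs for one channel, aligned with the hypnogram."""
    spe = int(round(h.epoch_s * fs))
    return [
        epoch_psd(x[i * spe:(i + 1) * spe], fs, h.epoch_s)
        for i in range(min(len(h), len(x) // spe))
    ]
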