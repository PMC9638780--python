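"""Synthetic multi-channel EEG with known ground truth.

Generates recordings that mimic the statistical structure rodent
skull-surface EEG analyses assume: a 1/f background, state-dependent
oscillations (NREM delta, REM theta, desynchronized wake), planted sleep
spindles and spike-and-wave discharges, movement artifacts, accelerometer
traces, and distance-dependent *lagged* coupling between nearby channels
(a shared band-limited source injected with a propagation delay, so that
imaginary coherency is nonzero by construction while zero-lag mixing
alone would leave it at zero).

The generator's defaults define the study conditions for every
synthetic-ground-truth test in this package; two genotype presets encode
the qualitative effect directions under test (mutant: fewer but longer
wake/NREM bouts, more SWDs, attenuated short-range spindle-band
coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .events import IntervalEvent
from .geometry import ElectrodeArray, pairwise_distances
from .hypnogram import Hypnogram, WAKE, NREM, REM
from .recording import Recording


@dataclass
class OscillatorSpec:
    """Band-limited Gaussian oscillation added during one state."""

    lo_hz: float
    hi_hz: float
    rms_uv: float


@dataclass
class SpindleSpec:
    # array-wide focus-event rate; with ~3-channel patches this puts
    # ~2-3 spindles/min on each channel, in the range reported for
    # rodent somatosensory NREM, and keeps the sigma-band envelope SD
    # dominated by spindles rather than background (as on real data)
    rate_per_nrem_min: float = 24.0
    min_dur_s: float = 0.4
    max_dur_s: float = 1.2
    lo_hz: float = 12.0
    hi_hz: float = 17.0
    amplitude_uv: float = 120.0      # carrier peak amplitude
    spread_mm: float = 1.5           # co-occurrence radius around the focus


@dataclass
class SwdSpec:
    rate_per_wake_min: float = 0.5
    lo_hz: float = 6.0
    hi_hz: float = 9.0
    n_harmonics: int = 3
    amplitude_uv: float = 250.0
    min_dur_s: float = 2.0
    max_dur_s: float = 5.0
    harmonic_decay: float = 0.5      # amplitude ratio between harmonics


@dataclass
class CouplingSpec:
    """Lagged coupling between nearby channels (NREM only).

    Two mechanisms, both with a propagation delay so imaginary coherency
    is nonzero by construction (zero-lag mixing alone would leave it at
    zero, which doubles as the volume-conduction control):

    * spindle events: each patch channel receives a fraction ``gain`` of
      the focus waveform, time-shifted by ``lag_ms_per_mm`` times the
      *signed rostro-caudal* (anterior-posterior) offset from the focus,
      the remainder being a private burst of matched envelope;
    * a weak continuous field of band-limited latent sources (one per
      electrode) injected into neighbouring channels with the same
      signed rostro-caudal delay and a spatial decay.

    The signed delay models a caudally travelling wave: the more rostral
    channel of a pair consistently leads, so the pairwise lag does not
    cancel when sources on both sides of a pair are summed (a symmetric
    distance-based delay would cancel the signed imaginary part).
    """

    lo_hz: float = 12.0
    hi_hz: float = 17.0
    rms_uv: float = 2.0
    gain: float = 1.0
    decay_mm: float = 1.5            # spatial e-folding of source weight
    lag_ms_per_mm: float = 3.0       # propagation delay
    cutoff_mm: float = 4.0           # sources beyond this contribute nothing


@dataclass
class ArtifactSpec:
    rate_per_min: float = 0.2
    amplitude_uv: float = 900.0
    duration_s: float = 0.3


@dataclass
class SimParams:
    sample_rate_hz: float = 1000.0
    duration_s: float = 21600.0
    epoch_s: float = 5.0
    dwell_mean_s: dict = field(
        default_factory=lambda: {WAKE: 150.0, NREM: 120.0, REM: 60.0}
    )
    p_nrem_to_rem: float = 0.35
    background_exponent: float = 1.5
    background_rms_uv: float = 20.0
    oscillators: dict = field(
        default_factory=lambda: {
            NREM: OscillatorSpec(1.0, 4.0, 60.0),
            REM: OscillatorSpec(5.0, 10.0, 30.0),
        }
    )
    spindles: SpindleSpec = field(default_factory=SpindleSpec)
    swd: SwdSpec = field(default_factory=SwdSpec)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    accel_sd: dict = field(
        default_factory=lambda: {WAKE: 0.30, NREM: 0.03, REM: 0.01}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.dwell_mean_s.values()):
            raise ValueError("dwell means must be positive")
        if not 0.0 <= self.coupling.gain:
            raise ValueError("coupling gain must be non-negative")
        for spec in (self.spindles, self.swd, self.artifacts):
            for name, val in asdict(spec).items():
                if isinstance(val, (int, float)) and val < 0:
                    raise ValueError(f"{name} must be non-negative")


@dataclass
class GenotypePreset:
    """Multiplicative modifiers encoding a genotype's effect directions."""

    name: str = "control"
    wake_dwell_mult: float = 1.0
    nrem_dwell_mult: float = 1.0
    rem_dwell_mult: float = 1.0
    coupling_gain_mult: float = 1.0
    swd_rate_mult: float = 1.0

    def __post_init__(self) -> None:
        for f_ in (self.wake_dwell_mult, self.nrem_dwell_mult,
                   self.rem_dwell_mult, self.coupling_gain_mult,
                   self.swd_rate_mult):
            if f_ <= 0:
                raise ValueError("preset multipliers must be positive")


CONTROL = GenotypePreset("control")
#: longer wake/NREM dwell (hence fewer bouts over a fixed recording),
#: halved short-range spindle-band coupling, more frequent SWDs
MUTANT = GenotypePreset(
    "mutant",
    wake_dwell_mult=1.6,
    nrem_dwell_mult=1.6,
    coupling_gain_mult=0.5,
    swd_rate_mult=3.0,
)


def sample_state_sequence(
    params: SimParams,
    preset: GenotypePreset = CONTROL,
    rng: np.random.Generator | None = None,
) -> tuple[Hypnogram, list[tuple[str, int, int]]]:
    """Semi-Markov brain-state sequence at epoch resolution.

    Dwell times are geometric in epochs (memoryless per state) with the
    configured per-state means; REM is entered only from NREM.  Returns
    the hypnogram and the true bout list as (state, start_epoch,
    n_epochs) tuples.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_epochs = int(params.duration_s // params.epoch_s)
    if n_epochs < 1:
        raise ValueError("duration must cover at least one epoch")
    mult = {
        WAKE: preset.wake_dwell_mult,
        NREM: preset.nrem_dwell_mult,
        REM: preset.rem_dwell_mult,
    }
    mean_epochs = {
        s: max(params.dwell_mean_s[s] * mult[s] / params.epoch_s, 1.0)
        for s in (WAKE, NREM, REM)
    }
    labels: list[str] = []
    bouts: list[tuple[str, int, int]] = []
    state = WAKE
    while len(labels) < n_epochs:
        # geometric dwell with mean m: support {1, 2, ...}
        p = 1.0 / mean_epochs[state]
        dwell = int(rng.geometric(p))
        dwell = min(dwell, n_epochs - len(labels))
        bouts.append((state, len(labels), dwell))
        labels.extend([state] * dwell)
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if rng.random() < params.p_nrem_to_rem else WAKE
        else:
            state = WAKE
    return Hypnogram(tuple(labels), params.epoch_s), bouts


def _band_noise(rng, n, fs, lo, hi, rms):
    """Gaussian noise band-limited to [lo, hi] Hz with target RMS.

    Synthesized directly in the frequency domain (random phases on the
    in-band rFFT coefficients), which is equivalent to band-pass
    filtering white Gaussian noise.
    """
    f = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (f >= lo) & (f <= hi)
    spec = np.zeros(len(f), dtype=complex)
    k = int(sel.sum())
    if k == 0:
        return np.zeros(n)
    spec[sel] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (rms / s) if s > 0 else x


def _one_over_f(rng, n, fs, exponent, rms):
    """Power-law (1/f^exponent) background noise with target RMS."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros(len(f), dtype=complex)
    nz = f > 0
    k = int(nz.sum())
    amp = f[nz] ** (-exponent / 2.0)
    spec[nz] = amp * (rng.standard_normal(k) + 1j * rng.standard_normal(k))
    x = np.fft.irfft(spec, n)
    return x * (rms / x.std())


def _poisson_times(rng, mask_s, rate_per_min):
    """Event start times drawn uniformly within True seconds of a mask."""
    avail = np.flatnonzero(mask_s)
    if avail.size == 0 or rate_per_min <= 0:
        return np.array([])
    n_events = rng.poisson(rate_per_min * avail.size / 60.0)
    return np.sort(rng.choice(avail, size=n_events, replace=True)
                   + rng.random(n_events))


def synth_recording(
    h: Hypnogram,
    array: ElectrodeArray,
    params: SimParams,
    preset: GenotypePreset = CONTROL,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, dict[str, list[IntervalEvent]]]:
    """Render a multi-channel recording for a given hypnogram.

    Returns the recording and the ground-truth event lists
    ``{"spindle": [...], "swd": [...], "artifact": [...]}``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    fs = params.sample_rate_hz
    n = int(round(len(h) * h.epoch_s * fs))
    n_ch = len(array.channel_ids)
    data = np.empty((n_ch, n))

    # per-second state masks for event placement
    sec = np.arange(int(len(h) * h.epoch_s))
    state_of_sec = np.array(
        [h.labels[min(int(s // h.epoch_s), len(h) - 1)] for s in sec]
    )

    masks = {s: h.sample_mask(s, fs, n) for s in (WAKE, NREM, REM)}

    for ci in range(n_ch):
        x = _one_over_f(rng, n, fs, params.background_exponent,
                        params.background_rms_uv)
        for state, osc in params.oscillators.items():
            if not masks[state].any():
                continue
            burst = _band_noise(rng, n, fs, osc.lo_hz, osc.hi_hz, osc.rms_uv)
            x[masks[state]] += burst[masks[state]]
        data[ci] = x

    truth: dict[str, list[IntervalEvent]] = {
        "spindle": [], "swd": [], "artifact": []
    }
    dmat = pairwise_distances(array)
    ids = array.channel_ids

    # --- sleep spindles: Hann-enveloped carrier over a local patch.
    # Patch channels share a fraction g of the focus carrier *with a
    # propagation delay*; the remainder is a private burst of matched
    # envelope, so spindle count/amplitude are genotype-independent
    # while spindle-band coherence scales with the coupling gain.
    sp = params.spindles
    cp = params.coupling
    g = min(cp.gain * preset.coupling_gain_mult, 1.0)
    ap = array.coordinates[:, 0]  # rostro-caudal position, mm
    for t0 in _poisson_times(rng, state_of_sec == NREM, sp.rate_per_nrem_min):
        dur = rng.uniform(sp.min_dur_s, sp.max_dur_s)
        f0 = rng.uniform(sp.lo_hz, sp.hi_hz)
        i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
        if i1 >= n:
            continue
        tloc = np.arange(i1 - i0) / fs
        env = np.hanning(i1 - i0)
        phase0 = rng.uniform(0, 2 * np.pi)
        focus = int(rng.integers(n_ch))
        for ci in range(n_ch):
            d = dmat[focus, ci]
            if d > sp.spread_mm:
                continue
            # caudally travelling wave: channels caudal of the focus lag,
            # rostral ones lead (signed AP offset, not absolute distance)
            lag_s = (ap[focus] - ap[ci]) * cp.lag_ms_per_mm / 1000.0
            shared = env * np.sin(2 * np.pi * f0 * (tloc - lag_s) + phase0)
            if ci == focus or g >= 1.0:
                wave = shared
            else:
                f1 = rng.uniform(sp.lo_hz, sp.hi_hz)
                private = env * np.sin(
                    2 * np.pi * f1 * tloc + rng.uniform(0, 2 * np.pi)
                )
                wave = g * shared + np.sqrt(1 - g**2) * private
            data[ci, i0:i1] += sp.amplitude_uv * wave
            truth["spindle"].append(IntervalEvent(
                "spindle", int(ids[ci]), t0, t0 + dur,
                {"freq_hz": f0, "amplitude_uv": sp.amplitude_uv,
                 "focus": int(ids[focus])},
            ))

    # --- SWDs: harmonic train with square envelope, generalized across
    # the array (absence discharges are recording-wide events)
    sw = params.swd
    for t0 in _poisson_times(
        rng, state_of_sec == WAKE, sw.rate_per_wake_min * preset.swd_rate_mult
    ):
        dur = rng.uniform(sw.min_dur_s, sw.max_dur_s)
        f0 = rng.uniform(sw.lo_hz, sw.hi_hz)
        i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
        if i1 >= n:
            continue
        tloc = np.arange(i1 - i0) / fs
        wave = np.zeros(i1 - i0)
        for k in range(1, sw.n_harmonics + 2):
            wave += sw.harmonic_decay ** (k - 1) * np.sin(2 * np.pi * k * f0 * tloc)
        wave *= sw.amplitude_uv
        gain = 0.8 + 0.4 * rng.random(n_ch)
        data[:, i0:i1] += gain[:, None] * wave[None, :]
        truth["swd"].append(IntervalEvent(
            "swd", None, t0, t0 + dur, {"fundamental_hz": f0,
                                        "amplitude_uv": sw.amplitude_uv},
        ))

    # --- movement artifacts: biphasic pulses above the discard threshold
    ar = params.artifacts
    for t0 in _poisson_times(rng, state_of_sec == WAKE, ar.rate_per_min):
        i0 = int(t0 * fs)
        i1 = min(i0 + int(ar.duration_s * fs), n)
        if i1 <= i0 + 2:
            continue
        tloc = np.linspace(0, 1, i1 - i0)
        pulse = ar.amplitude_uv * np.sin(2 * np.pi * tloc) * np.hanning(i1 - i0) * 2
        data[:, i0:i1] += pulse[None, :]
        truth["artifact"].append(IntervalEvent(
            "artifact", None, t0, i1 / fs, {"amplitude_uv": ar.amplitude_uv}
        ))

    # --- continuous lagged source field (NREM only): each electrode
    # hosts a latent band-limited source received by every channel
    # within cutoff_mm, weighted by exp(-d/decay) and time-shifted by
    # the signed rostro-caudal offset (caudally travelling wave).
    cp = params.coupling
    eff_gain = cp.gain * preset.coupling_gain_mult
    if eff_gain > 0 and cp.rms_uv > 0:
        nrem_mask = masks[NREM]
        if nrem_mask.any():
            for k in range(n_ch):
                src = _band_noise(rng, n, fs, cp.lo_hz, cp.hi_hz, cp.rms_uv)
                src = src * nrem_mask
                for ci in range(n_ch):
                    d = dmat[k, ci]
                    if d > cp.cutoff_mm:
                        continue
                    w = eff_gain * np.exp(-d / cp.decay_mm)
                    shift = int(round(
                        (ap[k] - ap[ci]) * cp.lag_ms_per_mm * fs / 1000.0
                    ))
                    data[ci] += w * np.roll(src, shift)

    # --- accelerometer magnitude: per-state noise level
    accel = np.zeros(n)
    for state, sd in params.accel_sd.items():
        m = masks[state]
        accel[m] = sd * rng.standard_normal(int(m.sum()))

    rec = Recording(data, fs, channel_ids=ids.copy(), accel=accel)
    return rec, truth
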