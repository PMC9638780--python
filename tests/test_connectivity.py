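import numpy as np
import pytest

import eegconn as e
from eegconn.connectivity import (
    WELCH_SEGMENT_S, coherence_grid, fisher_mean, imaginary_coherency,
)
from eegconn.hypnogram import Hypnogram, NREM
from eegconn.recording import Recording

FS = 125.0


def test_grid_has_99_bins():
    g = coherence_grid()
    assert len(g) == 99
    assert g[0] == 1.0 and g[-1] == 50.0
    assert np.allclose(np.diff(g), 0.5)


def test_decimate8_rate_and_length():
    rec = Recording(np.zeros((2, 1000)), 1000.0)
    out = e.decimate8(rec)
    assert out.fs == 125.0
    assert out.n_samples == 125
    with pytest.raises(ValueError, match="divisible"):
        e.decimate8(Recording(np.zeros((1, 100)), 100.0))


def test_decimate8_passband_preserved():
    """A 4 Hz sine survives decimation within 5% amplitude."""
    fs = 1000.0
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * 4.0 * t)
    out = e.decimate8(Recording(x[None, :], fs))
    t2 = np.arange(out.n_samples) / out.fs
    # least-squares sine fit at 4 Hz
    design = np.column_stack([np.sin(2 * np.pi * 4 * t2),
                              np.cos(2 * np.pi * 4 * t2)])
    coef, *_ = np.linalg.lstsq(design, out.data[0], rcond=None)
    assert np.hypot(*coef) == pytest.approx(1.0, rel=0.05)


def test_decimate8_stopband_removed():
    """A 70 Hz sine (above the new Nyquist) is suppressed."""
    fs = 1000.0
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * 70.0 * t)
    out = e.decimate8(Recording(x[None, :], fs))
    in_rms = np.sqrt(np.mean(x**2))
    out_rms = np.sqrt(np.mean(out.data[0][10:-10] ** 2))
    assert out_rms < 0.05 * in_rms


def test_identical_signals_zero_imaginary():
    x = np.random.default_rng(0).standard_normal(int(60 * FS))
    vals = imaginary_coherency(x, x, FS)
    assert np.allclose(vals, 0.0, atol=1e-12)


def test_zero_lag_mixing_zero_imaginary():
    """Volume-conduction control: instantaneous mixing stays real."""
    rng = np.random.default_rng(1)
    n = int(200 * FS)
    s1, s2, s3 = rng.standard_normal((3, n))
    x = s1 + 0.5 * s2
    y = 2 * x + 0.7 * s3 + 0.3 * s1
    vals = imaginary_coherency(x, y, FS)
    assert np.abs(vals).max() < 0.06


def test_lagged_sine_matches_direct_dft_oracle():
    """A 25 ms delay at 10 Hz (90 deg) gives |Im coherency| >= 0.8 at the
    10 Hz bin, with the same sign as a direct-DFT cross-spectrum."""
    rng = np.random.default_rng(2)
    n = int(400 * FS)
    t = np.arange(n) / FS
    shared = np.sin(2 * np.pi * 10.0 * t)
    lag = int(round(0.025 * FS))
    x = shared + 0.3 * rng.standard_normal(n)
    y = np.roll(shared, lag) + 0.3 * rng.standard_normal(n)
    vals = imaginary_coherency(x, y, FS)
    k = np.argmin(np.abs(coherence_grid() - 10.0))
    assert abs(vals[k]) >= 0.8

    # independent oracle: single long-window DFT cross-spectrum
    fx = np.fft.rfft(x)
    fy = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(n, 1 / FS)
    sel = np.abs(freqs - 10.0) < 0.05
    cross = (fx[sel] * np.conj(fy[sel])).sum()
    denom = np.sqrt(
        (np.abs(fx[sel]) ** 2).sum() * (np.abs(fy[sel]) ** 2).sum()
    )
    oracle = np.imag(cross / denom)
    assert np.sign(oracle) == np.sign(vals[k])
    assert vals[k] == pytest.approx(oracle, abs=0.1)


def test_antisymmetry_under_pair_swap():
    rng = np.random.default_rng(3)
    n = int(60 * FS)
    x = rng.standard_normal(n)
    y = np.roll(x, 3) + 0.5 * rng.standard_normal(n)
    assert np.allclose(
        imaginary_coherency(x, y, FS), -imaginary_coherency(y, x, FS),
        atol=1e-12,
    )


def test_fisher_mean_properties():
    assert fisher_mean(np.array([0.4, 0.4, 0.4])) == pytest.approx(0.4)
    assert fisher_mean(np.array([0.3, -0.3])) == pytest.approx(0.0)
    expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
    assert fisher_mean(np.array([0.2, 0.6])) == pytest.approx(expected, abs=1e-15)


def test_fisher_round_trip_identity():
    v = np.linspace(-0.99, 0.99, 21)
    assert np.allclose(np.tanh(np.arctanh(v)), v, atol=1e-12)
    for vi in v:
        assert fisher_mean(np.array([vi])) == pytest.approx(vi, abs=1e-12)


def test_fisher_clips_out_of_range():
    with pytest.warns(UserWarning, match="clipped"):
        out = fisher_mean(np.array([1.0, 0.5]))
    assert np.isfinite(out)


def test_state_pair_spectrum_single_epoch_equals_raw(array):
    rng = np.random.default_rng(4)
    data = rng.standard_normal((32, int(5 * FS)))
    rec = Recording(data, FS)
    h = Hypnogram((NREM,), 5.0)
    cp = e.state_pair_spectrum(rec, h, NREM, (0, 1))
    raw = imaginary_coherency(data[0], data[1], FS)
    assert np.allclose(cp.z_inv_values, raw, atol=1e-9)
    assert cp.n_epochs == 1
    assert cp.pair == (0, 1)


def test_group_average_mean_and_empty(array):
    short = e.pairs_by_threshold(array, 2, "short")
    pairs = sorted(short.pairs)[:2]
    cp1 = e.CoherencePair(pairs[0], np.full(99, 0.1), 3)
    cp2 = e.CoherencePair(pairs[1], np.full(99, 0.3), 3)
    g = e.group_average([cp1, cp2], short)
    assert np.allclose(g.values, 0.2)
    far = e.pairs_by_threshold(array, 14, "long")
    with pytest.raises(ValueError, match="empty"):
        e.group_average([cp1], far)


def test_region_mode_identical_channels_zero(array):
    """Identical regional signals have no imaginary coherency."""
    rng = np.random.default_rng(5)
    base = rng.standard_normal(int(10 * FS))
    data = np.tile(base, (32, 1))
    rec = Recording(data, FS)
    h = Hypnogram((NREM, NREM), 5.0)
    g = e.region_coherence(rec, h, NREM, array,
                           ("left", "rostral"), ("right", "caudal"))
    assert np.abs(g.values).max() < 1e-9


def test_nrem_coupling_elevates_sigma_not_wake(array, nrem_recording):
    """Short pairs show sigma-band Z^-1 above an uncoupled control."""
    rec, h, truth, params = nrem_recording
    rec125 = e.decimate8(rec)
    short = e.pairs_by_threshold(array, 2, "short")
    spectra = e.state_all_pairs(rec125, h, NREM, sorted(short.pairs))
    g = e.group_average(list(spectra.values()), short)
    grid = coherence_grid()
    sigma = (grid >= 12) & (grid <= 17)
    # uncoupled control: same conditions, gain 0 and no events
    params0 = e.SimParams(duration_s=120.0, seed=11)
    params0.coupling.gain = 0.0
    params0.spindles.rate_per_nrem_min = 0.0
    rec0, _ = e.synth_recording(h, array, params0)
    spectra0 = e.state_all_pairs(
        e.decimate8(rec0), h, NREM, sorted(short.pairs)
    )
    g0 = e.group_average(list(spectra0.values()), short)
    assert g.values[sigma].mean() > g0.values[sigma].mean() + 0.05
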