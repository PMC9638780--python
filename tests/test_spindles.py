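import itertools

import numpy as np
import pytest

import eegconn as e
from eegconn.spindles import SpindleParams, detect_spindles, multisite_spindles
from eegconn.events import IntervalEvent


def burst(fs, dur, f0=14.0, amp=120.0):
    n = int(dur * fs)
    t = np.arange(n) / fs
    return amp * np.hanning(n) * np.sin(2 * np.pi * f0 * t)


def background(fs, dur, seed=0, sd=4.0):
    return np.random.default_rng(seed).normal(0, sd, int(dur * fs))


FS = 1000.0


def plant(x, fs, t0, wave):
    i0 = int(t0 * fs)
    x[i0:i0 + len(wave)] += wave
    return x


def all_nrem(n):
    return np.ones(n, dtype=bool)


def test_planted_burst_duration_and_frequency():
    """A 0.6 s, 14 Hz Hann burst is recovered with ~right duration/freq.

    The long quiet background keeps the envelope-SD baseline low, so the
    boundary threshold sits near the burst's taper tails.
    """
    x = background(FS, 150.0)
    plant(x, FS, 10.0, burst(FS, 0.6))
    events = detect_spindles(x, FS, all_nrem(len(x)))
    assert len(events) == 1
    ev = events[0]
    assert abs(ev.duration_s - 0.6) <= 0.1
    assert ev.properties["peak_freq_hz"] == pytest.approx(14.0, abs=0.5)
    assert 25.0 <= ev.properties["amplitude_uv"] <= 750.0


def test_too_short_burst_rejected():
    x = background(FS, 30.0)
    plant(x, FS, 10.0, burst(FS, 0.1))
    # a reference burst keeps the envelope-SD baseline realistic
    plant(x, FS, 20.0, burst(FS, 0.6))
    events = detect_spindles(x, FS, all_nrem(len(x)))
    assert all(not (9.5 < ev.start_s < 10.7) for ev in events)


def test_close_bursts_merge():
    """Two bursts separated by 0.1 s (< 0.2 s minimum gap) merge."""
    x = background(FS, 30.0)
    plant(x, FS, 10.0, burst(FS, 0.5))
    plant(x, FS, 10.6, burst(FS, 0.5))
    events = detect_spindles(x, FS, all_nrem(len(x)))
    in_window = [ev for ev in events if 9.5 < ev.start_s < 11.5]
    assert len(in_window) == 1
    assert in_window[0].duration_s >= 0.9


def test_amplitude_window_bounds():
    # too small: peak-to-trough below the 25 uV floor -> rejected
    x = background(FS, 30.0, sd=1.0)
    plant(x, FS, 10.0, burst(FS, 0.6, amp=8.0))
    small = detect_spindles(x, FS, all_nrem(len(x)))
    assert all(ev.properties["amplitude_uv"] >= 25.0 for ev in small)
    assert not any(9.5 < ev.start_s < 10.7 for ev in small)
    # too large: peak-to-trough above the 750 uV ceiling -> rejected
    y = background(FS, 30.0)
    plant(y, FS, 10.0, burst(FS, 0.6, amp=900.0))
    big = detect_spindles(y, FS, all_nrem(len(y)))
    assert not any(9.5 < ev.start_s < 10.7 for ev in big)
    # in-window burst under the same conditions is kept
    z = background(FS, 30.0)
    plant(z, FS, 10.0, burst(FS, 0.6, amp=120.0))
    events = detect_spindles(z, FS, all_nrem(len(z)))
    assert any(9.5 < ev.start_s < 10.7 for ev in events)
    assert all(25.0 <= ev.properties["amplitude_uv"] <= 750.0
               for ev in events)


def test_events_confined_to_nrem_mask():
    x = background(FS, 30.0)
    plant(x, FS, 5.0, burst(FS, 0.6))    # inside NREM
    plant(x, FS, 20.0, burst(FS, 0.6))   # outside NREM
    mask = np.zeros(len(x), dtype=bool)
    mask[:int(10 * FS)] = True
    events = detect_spindles(x, FS, mask)
    assert events
    for ev in events:
        assert mask[int(ev.start_s * FS)]
        assert mask[int(ev.end_s * FS) - 1]


def test_empty_nrem_mask_errors():
    with pytest.raises(ValueError, match="NREM"):
        detect_spindles(np.zeros(1000), FS, np.zeros(1000, dtype=bool))


def test_recall_degrades_with_amplitude():
    """Detection recall falls monotonically as planted amplitude drops."""
    recalls = []
    for amp in (120.0, 30.0, 12.0):
        x = background(FS, 60.0, seed=1)
        times = np.arange(5.0, 55.0, 5.0)
        for t0 in times:
            plant(x, FS, t0, burst(FS, 0.6, amp=amp))
        events = detect_spindles(x, FS, all_nrem(len(x)))
        hit = sum(
            1 for t0 in times
            if any(ev.start_s < t0 + 0.6 and t0 < ev.end_s for ev in events)
        )
        recalls.append(hit / len(times))
    assert recalls[0] >= recalls[1] >= recalls[2]
    assert recalls[0] >= 0.9


def _ev(ch, start, end):
    return IntervalEvent("spindle", ch, start, end)


def test_multisite_grouping_simple(array):
    # channels 0, 4, 8 are a vertical chain 1.3 mm apart
    per_channel = {
        0: [_ev(0, 1.0, 1.6)],
        4: [_ev(4, 1.2, 1.8)],
        8: [_ev(8, 1.5, 2.0)],
    }
    n, mean_sites = multisite_spindles(per_channel, array, 2.0)
    assert n == 1
    assert mean_sites == 3.0


def test_multisite_far_channels_not_grouped(array):
    # channels 0 and 1 are 3.5 mm apart (adjacent columns)
    per_channel = {0: [_ev(0, 1.0, 1.6)], 1: [_ev(1, 1.0, 1.6)]}
    n, mean_sites = multisite_spindles(per_channel, array, 2.0)
    assert n == 0
    assert np.isnan(mean_sites)


def test_multisite_matches_brute_force_components(array):
    """Group count equals connected components of the (near AND
    overlapping) graph computed by an independent brute-force oracle."""
    rng = np.random.default_rng(0)
    per_channel = {ch: [] for ch in range(32)}
    nodes = []
    for _ in range(60):
        ch = int(rng.integers(32))
        start = float(rng.uniform(0, 50))
        ev = _ev(ch, start, start + float(rng.uniform(0.2, 1.0)))
        per_channel[ch].append(ev)
        nodes.append((ch, ev))
    n, mean_sites = multisite_spindles(per_channel, array, 2.0)

    import networkx as nx
    dmat = e.pairwise_distances(array)
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for i, j in itertools.combinations(range(len(nodes)), 2):
        ci, ei = nodes[i]
        cj, ej = nodes[j]
        if ci != cj and dmat[ci, cj] <= 2.0 and ei.overlaps(ej):
            g.add_edge(i, j)
    comps = [
        {nodes[i][0] for i in comp} for comp in nx.connected_components(g)
    ]
    sizes = [len(c) for c in comps if len(c) >= 2]
    assert n == len(sizes)
    if sizes:
        assert mean_sites == pytest.approx(np.mean(sizes))


def test_multisite_unknown_channel(array):
    with pytest.raises(KeyError):
        multisite_spindles({99: [_ev(99, 0, 1)]}, array, 2.0)
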