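import numpy as np
import pytest

import eegconn as e
from eegconn.hypnogram import Hypnogram


@pytest.fixture(scope="session")
def array():
    return e.load_array()


@pytest.fixture(scope="session")
def nrem_recording(array):
    """120 s all-NREM synthetic recording with ground truth (seed 11)."""
    params = e.SimParams(duration_s=120.0, seed=11)
    h = Hypnogram(tuple(["NREM"] * 24), 5.0)
    rng = np.random.default_rng(11)
    rec, truth = e.synth_recording(h, array, params, e.CONTROL, rng)
    return rec, h, truth, params


@pytest.fixture(scope="session")
def mixed_recording(array):
    """300 s mixed-state synthetic recording with ground truth (seed 7)."""
    params = e.SimParams(duration_s=300.0, seed=7)
    rng = np.random.default_rng(7)
    h, bouts = e.sample_state_sequence(params, e.CONTROL, rng)
    rec, truth = e.synth_recording(h, array, params, e.CONTROL, rng)
    return rec, h, truth, params


def overlaps(a_start, a_end, b_start, b_end):
    return a_start < b_end and b_start < a_end


def recall_precision(detected, planted):
    """Temporal-overlap match rates between event lists."""
    if not planted:
        return float("nan"), float("nan")
    hit = sum(
        1 for g in planted
        if any(overlaps(d.start_s, d.end_s, g.start_s, g.end_s)
               for d in detected)
    )
    tp = sum(
        1 for d in detected
        if any(overlaps(d.start_s, d.end_s, g.start_s, g.end_s)
               for g in planted)
    )
    recall = hit / len(planted)
    precision = tp / len(detected) if detected else float("nan")
    return recall, precision
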