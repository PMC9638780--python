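"""End-to-end study emulation: simulate two genotype cohorts, run every
analysis stage, and report group statistics.

Per animal: simulate -> artifact mask -> SWD detection + exclusion ->
bout statistics -> per-state spectra -> imaginary coherence by distance
group -> spindle detection (all channels) -> spindle-locked coherograms
-> high-connectivity statistic.  Across animals: standard tests on bout
metrics, a bin-wise cluster permutation on short-distance NREM
coherence spectra, and correlations of SWD burden with bout metrics and
12-22 Hz coherence.

Seed discipline: the global seed expands through
``numpy.random.SeedSequence.spawn`` into per-animal streams, so results
are bit-reproducible for a fixed config and independent across animals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import connectivity, dynconn, geometry, permstats, spectral, spindles, swd
from .hypnogram import (
    NREM, WAKE, Hypnogram, artifact_mask, bout_statistics, exclude_event_times,
)
from .synth import CONTROL, MUTANT, GenotypePreset, SimParams, sample_state_sequence, synth_recording


@dataclass
class StudyConfig:
    n_animals: int = 12              # per genotype
    duration_s: float = 600.0
    sample_rate_hz: float = 1000.0
    distance_threshold_mm: float = 2.0
    n_permutations: int = 40_000
    coherogram_fraction: float = 0.70
    artifact_threshold_uv: float = 750.0
    analysis_channel: int = geometry.DEFAULT_ANALYSIS_CHANNEL
    coherence_state: str = NREM
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals per genotype")
        if not 1.0 <= self.distance_threshold_mm <= 14.0:
            raise ValueError("distance threshold outside [1, 14] mm")


def config_hash(cfg: StudyConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def analyse_animal(
    cfg: StudyConfig,
    preset: GenotypePreset,
    seed: int,
    array: geometry.ElectrodeArray | None = None,
) -> dict:
    """Simulate and fully analyse one animal; returns a result map."""
    if array is None:
        array = geometry.load_array()
    rng = np.random.default_rng(seed)
    params = SimParams(
        sample_rate_hz=cfg.sample_rate_hz,
        duration_s=cfg.duration_s,
        seed=seed,
        **cfg.sim_overrides,
    )
    h, _ = sample_state_sequence(params, preset, rng)
    rec, truth = synth_recording(h, array, params, preset, rng)

    # exclusion: movement artifacts, then detected SWD times
    h_clean = artifact_mask(rec, h, cfg.artifact_threshold_uv)
    swd_events = swd.detect_swd(rec.channel(cfg.analysis_channel), rec.fs)
    swd_seconds = sum(ev.duration_s for ev in swd_events)
    h_clean = exclude_event_times(h_clean, swd_events)

    bouts = bout_statistics(h_clean)

    # single-channel state spectra (bands of mean log10 power)
    psds = spectral.recording_psds(
        rec.channel(cfg.analysis_channel), rec.fs, h_clean
    )
    band_by_state = {}
    for state in (WAKE, NREM):
        try:
            avg = spectral.state_average_psd(psds, h_clean, state)
            band_by_state[state] = spectral.band_average(avg)
        except ValueError:
            band_by_state[state] = None

    # static connectivity on the decimated recording
    rec125 = connectivity.decimate8(rec)
    short = geometry.pairs_by_threshold(array, cfg.distance_threshold_mm, "short")
    long_ = geometry.pairs_by_threshold(array, cfg.distance_threshold_mm, "long")
    wanted = sorted(short.pairs | long_.pairs)
    try:
        pair_spectra = connectivity.state_all_pairs(
            rec125, h_clean, cfg.coherence_state, wanted
        )
        spectra = list(pair_spectra.values())
        short_vals = connectivity.group_average(spectra, short).values
        long_vals = connectivity.group_average(spectra, long_).values
    except ValueError:
        # the state never occurred (or was fully excluded) in this animal
        short_vals = np.full(connectivity.N_BINS, np.nan)
        long_vals = np.full(connectivity.N_BINS, np.nan)

    # spindles on every channel; multisite grouping within 2 mm
    nrem_mask = h_clean.sample_mask(NREM, rec.fs, rec.n_samples)
    per_channel = {}
    if nrem_mask.any():
        for cid in array.channel_ids:
            try:
                per_channel[int(cid)] = spindles.detect_spindles(
                    rec.channel(cid), rec.fs, nrem_mask, channel=int(cid)
                )
            except ValueError:
                per_channel[int(cid)] = []
    n_multi, mean_sites = (
        spindles.multisite_spindles(per_channel, array)
        if per_channel else (0, float("nan"))
    )

    # spindle-locked coherograms over the short-distance pair set
    anchor = per_channel.get(cfg.analysis_channel, [])
    starts = np.array([ev.start_s for ev in anchor])
    high = None
    if len(starts) >= 2:
        tfrs = {}
        chans = sorted({c for p in short.pairs for c in p})
        for c in chans:
            tfrs[c] = dynconn.morlet_tfr(rec.channel(c), rec.fs, starts)
        cohs = []
        for (a, b) in sorted(short.pairs):
            if len(tfrs[a]) >= 2 and tfrs[a].shape == tfrs[b].shape:
                cohs.append(dynconn.event_coherogram(tfrs[a], tfrs[b]))
        if cohs:
            avg = dynconn.average_coherograms(cohs)
            high = dynconn.high_connectivity(avg, cfg.coherogram_fraction)

    total_s = cfg.duration_s
    return {
        "preset": preset.name,
        "seed": seed,
        "bouts": bouts,
        "band_power": band_by_state,
        "short_spectrum": short_vals,
        "long_spectrum": long_vals,
        "n_spindles_anchor": len(anchor),
        "n_multisite_spindles": n_multi,
        "mean_sites_per_multispindle": mean_sites,
        "swd_percent_time": 100.0 * swd_seconds / total_s,
        "n_swd": len(swd_events),
        "high_connectivity": high,
        "ground_truth_counts": {k: len(v) for k, v in truth.items()},
    }


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full two-cohort study emulation.

    Returns a report dict with per-animal results and group statistics;
    if ``out_dir`` is given, JSON/CSV tables are written there together
    with the config hash and seed.
    """
    array = geometry.load_array()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             ss.spawn(2 * cfg.n_animals)]
    animals = []
    for i in range(cfg.n_animals):
        animals.append(analyse_animal(cfg, CONTROL, seeds[i], array))
    for i in range(cfg.n_animals):
        animals.append(
            analyse_animal(cfg, MUTANT, seeds[cfg.n_animals + i], array)
        )

    ctrl = [a for a in animals if a["preset"] == "control"]
    mut = [a for a in animals if a["preset"] == "mutant"]

    def metric(group, fn):
        return np.array([fn(a) for a in group], dtype=float)

    group_stats = {}
    for name, fn in {
        "nrem_n_bouts": lambda a: a["bouts"].n_bouts[NREM],
        "nrem_mean_bout_s": lambda a: a["bouts"].mean_bout_duration_s[NREM],
        "wake_n_bouts": lambda a: a["bouts"].n_bouts[WAKE],
        "wake_mean_bout_s": lambda a: a["bouts"].mean_bout_duration_s[WAKE],
        "nrem_percent": lambda a: a["bouts"].percent_time[NREM],
        "swd_percent_time": lambda a: a["swd_percent_time"],
    }.items():
        a_vals = metric(ctrl, fn)
        b_vals = metric(mut, fn)
        ok = np.isfinite(a_vals) & np.isfinite(b_vals[: len(a_vals)])
        if np.isfinite(a_vals).all() and np.isfinite(b_vals).all():
            group_stats[name] = permstats.standard_tests(a_vals, b_vals)
        group_stats.setdefault(name, {})
        group_stats[name]["mean_control"] = float(np.nanmean(a_vals))
        group_stats[name]["mean_mutant"] = float(np.nanmean(b_vals))

    ctrl_spec = [a["short_spectrum"] for a in ctrl
                 if np.isfinite(a["short_spectrum"]).all()]
    mut_spec = [a["short_spectrum"] for a in mut
                if np.isfinite(a["short_spectrum"]).all()]
    if len(ctrl_spec) >= 2 and len(mut_spec) >= 2:
        perm = permstats.binwise_permutation(
            np.stack(ctrl_spec), np.stack(mut_spec),
            n_perm=cfg.n_permutations, seed=cfg.seed,
        )
    else:
        perm = None

    # SWD burden vs sleep metrics and vs 12-22 Hz short-pair coherence
    grid = connectivity.coherence_grid()
    sigma_sel = (grid >= 12.0) & (grid <= 22.0)
    correlations = {}
    swd_all = metric(animals, lambda a: a["swd_percent_time"])
    for name, fn in {
        "nrem_mean_bout_s": lambda a: a["bouts"].mean_bout_duration_s[NREM],
        "coh_12_22": lambda a: float(np.mean(a["short_spectrum"][sigma_sel])),
    }.items():
        vals = metric(animals, fn)
        ok = np.isfinite(vals) & np.isfinite(swd_all)
        if ok.sum() >= 3 and vals[ok].std() > 0 and swd_all[ok].std() > 0:
            correlations[f"swd_vs_{name}"] = permstats.pearson(
                swd_all[ok], vals[ok]
            )

    report = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "animals": animals,
        "group_stats": group_stats,
        "permutation": None if perm is None else {
            "observed": perm.observed,
            "p_values": perm.p_values,
            "clusters": [asdict(c) for c in perm.clusters],
            "n_permutations": perm.n_permutations,
        },
        "correlations": correlations,
    }

    if out_dir is not None:
        from .io import write_json
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = _strip_arrays(report)
        write_json(serializable, out / "report.json")
    return report


def _strip_arrays(obj):
    import dataclasses
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _strip_arrays(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _strip_arrays(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_strip_arrays(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
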