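# Methods

This note documents the models, estimators and numerical choices behind
`eegconn`, and what the synthetic-data validation does and does not
establish.

## Electrode geometry

The packaged layout emulates a flat 32-electrode epidural grid: 4
columns (ML ±1.75, ±5.25 mm) × 8 rows (AP 3.9 … −5.2 mm, 1.3 mm
spacing), coordinates in mm relative to bregma. The skull surface is
treated as planar and distances are plain Euclidean, matching how such
grids are analysed in practice. The grid's minimum pairwise distance is
exactly 1.3 mm (vertical neighbours) and its maximum is
√(10.5² + 9.1²) = 13.89 mm (opposite corners). The exact per-electrode
coordinates of commercial probes are vendor drawings; this fixture is a
synthetic stand-in that reproduces the published distance extremes, and
any user layout can be supplied as a CSV
(`id,label,ap_mm,ml_mm,hemisphere,region_class`).

Pairs at exactly a threshold distance are assigned to the *short* set,
so short(t) and long(t) always partition the 496 pairs; no fixture pair
sits on an integer-mm threshold, so the rule only matters for user
layouts. Regions are the 6 hemisphere × rostral/middle/caudal groups
(rows 0–2, 3–5, 6–7).

## Hypnograms and bout statistics

Epochs are 5 s, the atomic unit of scoring. A *bout* is a maximal run
of identical non-excluded labels; `EXCLUDED` epochs terminate bouts and
leave the percent-time denominator. Epochs partially overlapping an
excluded interval (artifact sample > 750 µV on any analysed channel, or
a detected SWD) are excluded whole — with 5 s atoms, partial-epoch
bookkeeping is not worth the ambiguity.

The rule-based auto-scorer is a convenience surrogate for visual
scoring: per epoch, accelerometer SD below a quiet cut marks sleep;
within sleep a theta(5–10 Hz)/delta(1–4 Hz) power ratio above 1 with a
delta fraction below 0.4 marks REM, a delta fraction of 1–48 Hz power
at or above 0.4 marks NREM; everything else is wake. It reaches ≥ 0.99
epoch accuracy on the generator's output, but it is validated *only*
against synthetic ground truth; no claim is made about agreement with
human scorers on real data.

## Spindle detection

Band-pass 12–17 Hz with a zero-phase symmetric FIR (1 Hz transition,
applied by a single centred FFT convolution — linear phase means zero
group delay, preserving event timing for coherogram alignment).
Envelope = |analytic signal| smoothed with a 50 ms moving average.
Thresholds are expressed in SDs of the envelope over all NREM samples
of the channel, *above its mean*: detection at mean + 3 SD, boundaries
extended to the mean + 1.5 SD crossings, noise exclusion at
mean + 35 SD. The mean-plus-k·SD form is the standard envelope-threshold
detector; a bare k·SD threshold sits inside the Rayleigh bulk of any
Gaussian background (P(env > 3·SD) ≈ 15% regardless of scale) and
cannot reach usable specificity. Candidates closer than 0.2 s merge;
events must last 0.2–3 s and have a band-passed peak-to-trough
amplitude within 25–750 µV.

Detected durations understate the planted Hann-envelope duration by
design: the boundary threshold crosses inside the taper tails. All
ground-truth matching is therefore by temporal overlap, not boundary
equality.

Multi-electrode spindles: events on different channels within 2 mm
whose intervals overlap are merged by transitive closure (union-find);
the statistic is the number of groups spanning ≥ 2 electrodes and their
mean electrode count. Transitive closure (rather than mutual nearness)
was chosen because a travelling local event can be contiguous without
all sites being pairwise near.

## SWD detection

A sliding 1 s window (0.5 s step) must pass three gates: peak-to-peak
amplitude ≥ 300 µV; a 5–10 Hz fundamental (maximal PSD peak in band)
standing ≥ 3× above the local median floor (±3 Hz, peak bins excluded);
and a *harmonic score* — the minimum over harmonics k = 2..3 of the PSD
within one bin of k·f₀ over its local floor — also ≥ 3. Harmonics of a
periodic discharge are exact multiples up to grid resolution, hence the
±1-bin tolerance. Marked windows merge across gaps ≤ 0.5 s; events
shorter than 1.25 s are dropped. The minimum duration deliberately
exceeds one window length so a single spectrally unlucky window can
never become an event; real discharges last ≥ 2 s and always span
several overlapping windows. Scores are power ratios, so detection
above the amplitude floor is invariant to signal rescaling.

## Spectral estimation

Per-epoch power uses DPSS multitapers with NW = 4 and 7 tapers on the
5 s epoch (≈ ±0.8 Hz smoothing), interpolated linearly onto the fixed
0.2–48 Hz grid (240 bins, 0.2 Hz) and expressed as log₁₀ power. The
taper count and the interpolate-vs-native choice are declared
parameters — reasonable alternatives shift absolute values slightly but
cancel in state contrasts, which are averages of log spectra over a
state's non-excluded epochs. Band summaries average the bins whose
centres fall inside closed intervals (delta 1–4, theta 5–10, sigma
12–17, beta 17–30, gamma 30–48 Hz).

## Imaginary coherence

Recordings are decimated by 8 (`scipy.signal.decimate`, order-8
Chebyshev-I anti-aliasing, zero-phase) to 125 Hz. Per 5 s epoch and
channel pair, coherency is estimated from Welch cross/auto spectra with
2 s Hann segments at 50% overlap — chosen so the native resolution is
exactly the mandated 0.5 Hz and the 99-bin grid (1–50 Hz) needs no
interpolation. The imaginary part is taken per bin, Fisher-z
transformed (atanh — odd, so the lead/lag sign survives), averaged over
the state's epochs and inverse-transformed to the Z⁻¹ value. Values at
|v| ≥ 1 are clipped to 1 − 10⁻¹² with a warning; zero-power bins are
NaN and drop out of the average; epochs shorter than one Welch segment
after exclusion are skipped. The canonical pair orientation is lower
id → higher id; swapping negates every bin.

Per-epoch estimation (rather than state-concatenation) was chosen
because the downstream averaging is defined over epochs; it also makes
the estimator robust to state fragmentation.

Distance-group spectra are arithmetic means of Z⁻¹ over the selected
pairs. Regional coherence averages the member-channel *voltages* first
and then computes one coherency between the two regional signals —
regional averaging before coherency is the documented convention for
the regional analysis, and identical regions then give exactly zero.

## Spindle-locked coherograms

Complex Morlet wavelets with 7 cycles, truncated at ±3 SD of the
Gaussian envelope and normalised to unit energy, are convolved with the
1 kHz signal at the 11 components 12–17 Hz (0.5 Hz). Coefficients are
sampled on a 1 ms grid from 500 ms before to 1500 ms after each
detected spindle start (2000 time points); trials whose window leaves
the record are dropped. For a channel pair,

    value(f, t) = Im( Σ_trials Wx·conj(Wy) / √(Σ|Wx|² · Σ|Wy|²) ).

Pair coherograms are averaged across the selected (short-distance) pair
set per animal, then the maximum of |value| is found over all
11 × 2000 bins and bins above 70% of it are counted; their mean
frequency is reported. The magnitude is used because the sign of
imaginary coherence encodes lead/lag direction only; the threshold is
relative, so the count is invariant to global scaling.

## Permutation statistics

The group test permutes animal labels (default 40 000 draws; an exact
mode enumerates all C(n, n_a) assignments for small groups). The per-bin
statistic is the difference of group means — under label exchange a
studentised statistic changes nothing for equal-variance bins and the
plain difference keeps cluster masses interpretable. One-sided
p̂ = (1 + #{perm ≥ obs}) / (n_perm + 1); a bin is significant at
p̂ ≤ 0.025 or ≥ 0.975 (two-sided α = 0.05). Maximal runs of
same-direction significant bins form clusters with mass Σ|statistic|;
each permutation is thresholded by its own rank within the ensemble and
contributes its maximal cluster mass to the null, giving corrected
cluster p-values that control the family-wise error across bins. Under
a simulated null (12 + 12 animals, 99 bins, 1000 replicates) the
family-wise rate of a corrected-significant cluster stays at or below
the nominal 5% (asserted ≤ 7% in the suite).

Power calculations use the noncentral t distribution
(noncentrality d·√(n/2), df = 2n − 2); with means 75 and 55, SD 15.8
and n = 12 this gives d = 1.27 and power ≈ 0.84 ≥ 0.803, and it matches
a 100 000-experiment Monte-Carlo to < 0.005.

## Synthetic data: what it emulates, and what it does not

Each channel is 1/f^1.5 background noise (RMS 20 µV) plus
state-dependent band-limited Gaussian oscillations (NREM delta 1–4 Hz,
60 µV RMS; REM theta 5–10 Hz, 30 µV RMS; wake is background only,
i.e. desynchronized). The accelerometer is state-dependent noise (SD
0.30 / 0.03 / 0.01 for wake / NREM / REM).

*Spindles*: Poisson focus events during NREM (24 per NREM-minute across
the array — about 2–3 per minute per channel, in the range reported for
rodent somatosensory NREM), Hann-enveloped 12–17 Hz carriers of 0.4–1.2 s
at 120 µV planted on every channel within 1.5 mm of the focus.
*SWDs*: wake-gated harmonic trains (fundamental 6–9 Hz plus 3 decaying
harmonics, 250 µV, 2–5 s, square envelope) applied array-wide.
*Artifacts*: biphasic wake pulses exceeding the 750 µV discard rule.

*Coupling* is deliberately **lagged**: patch channels receive a shared
fraction g of the focus spindle carrier time-shifted by 3 ms per mm of
*signed rostro-caudal offset* (a caudally travelling wave), the
remainder being a private burst of matched envelope; a weak continuous
12–17 Hz source field (2 µV RMS per electrode site) propagates the same
way. The signed delay matters: a symmetric distance-based delay injects
each source into both channels of a pair with opposite relative phase
and the signed imaginary coherency cancels in expectation. Zero-lag
mixing alone would produce exactly zero imaginary coherency, which the
suite uses as the volume-conduction control. Because the shared
fraction, not the burst amplitude, carries the genotype effect, the
mutant preset reduces sigma-band coherence while leaving spindle
counts and amplitudes unchanged — the dissociation the analysis is
designed to resolve.

Dwell times are geometric at epoch resolution (memoryless per state,
wake 150 s, NREM 120 s, REM 60 s means; REM entered only from NREM,
p = 0.35) — the simplest semi-Markov family in which scaling dwell
means (mutant ×1.6 for wake/NREM) produces fewer but longer bouts at
unchanged percent time. The mutant preset also halves the coupling
gain and triples the SWD rate.

What passing tests show: the estimators recover exactly the structures
they target, at the planted effect sizes, under Gaussian stationary
backgrounds. What they do not show: performance under real-data
violations — non-stationary 1/f slopes, true spindle morphology and
frequency chirp, muscle and electrode artifacts below the 750 µV rule,
inter-animal variability in electrode placement, or reference/montage
effects. Generator amplitudes were chosen once to give the detectors a
realistic but not trivial margin; they are parameters of `SimParams`,
not constants.

## Problem sizes and determinism

Validation runs use minutes-long recordings (ground-truth recovery:
600 s; genotype-contrast recovery: 20 runs × 10 animals/group × 90 s of
NREM; permutation calibration: 1000 replicates × 400 permutations) —
sizes chosen as the smallest at which the assertions are statistically
stable. All stochastic stages consume explicit seeds;
`numpy.random.SeedSequence.spawn` expands a study seed into per-animal
streams, so any run is bit-reproducible and animals are independent.

## Known limitations

- The EDF writer emits plain 16-bit EDF with 1 s records and zero-pads
  the final partial second; annotations (EDF+) are not written.
- The SWD detector assumes generalized (recording-wide) discharges and
  detects on one designated channel; focal events would need
  per-channel detection.
- The auto-scorer's thresholds are tuned to the generator's contrast
  and should be re-calibrated before any use on real recordings.
- Coherogram trial alignment uses detected (not ground-truth) spindle
  starts, so boundary jitter of the detector propagates into the
  time axis of the coherogram; event-locked averages are robust to the
  ~tens of ms involved, but single-trial phase maps are not.
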