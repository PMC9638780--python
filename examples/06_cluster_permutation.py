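"""Cluster-corrected permutation test on group coherence spectra, plus
the analytic design calculations (effect size and power).

Builds two synthetic cohorts of per-animal 99-bin spectra with a
contiguous sigma-band group difference, runs the two-sided bin-wise
permutation test (p <= 0.025 / >= 0.975) and reports the
maximal-cluster-mass-corrected clusters.
"""

import numpy as np

import eegconn as e
from eegconn.connectivity import coherence_grid
from eegconn.permstats import PowerSpec

rng = np.random.default_rng(12)
grid = coherence_grid()
n_animals, n_bins = 12, 99

base = 0.1 * np.exp(-((grid - 14.0) ** 2) / 30.0)
ctrl = base + 0.02 * rng.standard_normal((n_animals, n_bins))
mut = base.copy()
mut[(grid >= 12) & (grid <= 17)] *= 0.5  # attenuated sigma coupling
mut = mut + 0.02 * rng.standard_normal((n_animals, n_bins))

res = e.binwise_permutation(ctrl, mut, n_perm=5000, seed=12)
print(f"{res.significant_bins.sum()} of {n_bins} bins significant "
      f"(two-sided permutation, n_perm = {res.n_permutations})")
for c in res.clusters:
    lo, hi = grid[c.start_bin], grid[c.end_bin]
    direction = ">" if c.direction > 0 else "<"
    print(f"  cluster {lo:.1f}-{hi:.1f} Hz (control {direction} mutant), "
          f"mass {c.mass:.2f}, corrected p = {c.corrected_p:.4f}")

spec = PowerSpec(mean_a=75.0, mean_b=55.0, sd=15.8, n_per_group=12)
print(f"\ndesign check: Cohen's d = {e.cohens_d(spec):.2f}, achieved "
      f"power = {e.t_test_power(spec):.3f} at alpha = {spec.alpha}")
print("A corrected cluster p <= 0.05 controls the family-wise error "
      "across all 99 frequency bins.")
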