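"""Permutation statistics with cluster correction, plus standard tests.

The bin-wise group test permutes animal labels (default 40 000 draws),
uses the difference of group means as the per-bin statistic, and calls a
bin significant when its one-sided permutation p is <= 0.025 or
>= 0.975 (a two-sided rule at alpha 0.05).  Maximal runs of
same-direction significant bins form clusters; each cluster's mass (sum
of |statistic|) is referred to the permutation distribution of the
maximal cluster mass, which controls the family-wise error across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

N_PERMUTATIONS_DEFAULT = 40_000
SIG_LOW = 0.025
SIG_HIGH = 0.975


@dataclass(frozen=True)
class Cluster:
    start_bin: int
    end_bin: int           # inclusive
    direction: int         # +1: group A > B, -1: A < B
    mass: float
    corrected_p: float


@dataclass(frozen=True)
class PermutationResult:
    axis: str
    observed: np.ndarray
    p_values: np.ndarray   # one-sided p-hat per bin
    clusters: list[Cluster]
    n_permutations: int
    seed: int

    @property
    def significant_bins(self) -> np.ndarray:
        return (self.p_values <= SIG_LOW) | (self.p_values >= SIG_HIGH)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample t-test power/effect-size computation."""

    mean_a: float
    mean_b: float
    sd: float
    n_per_group: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")


def _cluster_masses(sig: np.ndarray, direction: np.ndarray,
                    stat: np.ndarray) -> list[tuple[int, int, int, float]]:
    """Maximal runs of same-direction significant bins with their mass."""
    out = []
    i = 0
    n = len(sig)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and direction[j + 1] == direction[i]:
            j += 1
        out.append((i, j, int(direction[i]), float(np.abs(stat[i:j + 1]).sum())))
        i = j + 1
    return out


def _group_mean_diffs(pooled: np.ndarray, na: int, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Mean(A)-mean(B) for ``n_perm`` random label permutations."""
    n_total, n_bins = pooled.shape
    nb = n_total - na
    out = np.empty((n_perm, n_bins))
    chunk = max(1, int(2e7 // max(n_total * n_bins, 1)))
    col_sum = pooled.sum(axis=0)
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        order = np.argsort(rng.random((hi - lo, n_total)), axis=1)
        sel = np.take_along_axis(
            pooled[None, :, :], order[:, :na, None], axis=1
        )
        sum_a = sel.sum(axis=1)
        out[lo:hi] = sum_a / na - (col_sum - sum_a) / nb
    return out


def _exhaustive_diffs(pooled: np.ndarray, na: int) -> np.ndarray:
    """Mean(A)-mean(B) for every distinct label assignment."""
    import itertools

    n_total = pooled.shape[0]
    nb = n_total - na
    col_sum = pooled.sum(axis=0)
    rows = []
    for combo in itertools.combinations(range(n_total), na):
        sum_a = pooled[list(combo)].sum(axis=0)
        rows.append(sum_a / na - (col_sum - sum_a) / nb)
    return np.array(rows)


def _max_cluster_masses(stats_mat: np.ndarray, sig_mat: np.ndarray) -> np.ndarray:
    """Per-row maximal same-direction cluster mass (0 where no cluster)."""
    out = np.zeros(len(stats_mat))
    any_sig = sig_mat.any(axis=1)
    for r in np.flatnonzero(any_sig):
        dirs = np.where(stats_mat[r] >= 0, 1, -1)
        cl = _cluster_masses(sig_mat[r], dirs, stats_mat[r])
        out[r] = max(c[3] for c in cl)
    return out


def binwise_permutation(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = N_PERMUTATIONS_DEFAULT,
    seed: int = 0,
    axis_name: str = "frequency",
    exact: bool = False,
) -> PermutationResult:
    """Two-sided label-permutation test per bin with cluster correction.

    ``group_a`` and ``group_b`` are (n_animals, n_bins) arrays.  The
    statistic is mean(A) - mean(B).  p-hat per bin is the one-sided
    add-one estimator (1 + #{perm >= observed}) / (n_perm + 1); values
    <= 0.025 or >= 0.975 are significant.  Maximal runs of
    same-direction significant bins form clusters whose corrected p
    comes from the permutation distribution of the maximal cluster mass.

    With ``exact=True`` every distinct label assignment is enumerated
    (feasible for small groups) and p-hat is the exact proportion
    #{assignment >= observed} / n_assignments (the observed assignment
    is part of the enumeration, so p-hat > 0).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("bin-count mismatch between groups")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two animals per group")
    na = a.shape[0]
    pooled = np.vstack([a, b])
    observed = a.mean(axis=0) - b.mean(axis=0)

    if exact:
        perm_stats = _exhaustive_diffs(pooled, na)
        n_eff = len(perm_stats)
        p_hat = (perm_stats >= observed - 1e-12).sum(axis=0) / n_eff
    else:
        rng = np.random.default_rng(seed)
        perm_stats = _group_mean_diffs(pooled, na, n_perm, rng)
        n_eff = n_perm
        p_hat = (1 + (perm_stats >= observed).sum(axis=0)) / (n_perm + 1)

    sig = (p_hat <= SIG_LOW) | (p_hat >= SIG_HIGH)
    direction = np.where(observed >= 0, 1, -1)
    obs_clusters = _cluster_masses(sig, direction, observed)

    # null of the maximal cluster mass: threshold each permuted dataset
    # by its own rank within the permutation ensemble
    n_rows = len(perm_stats)
    order = np.argsort(perm_stats, axis=0)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_rows)[:, None], axis=0)
    p_perm = (n_rows - ranks) / n_rows  # fraction of ensemble >= value
    sig_perm = (p_perm <= SIG_LOW) | (p_perm >= SIG_HIGH)
    max_mass = _max_cluster_masses(perm_stats, sig_perm)

    clusters = []
    for (i, j, d, mass) in obs_clusters:
        if exact:
            pc = (max_mass >= mass - 1e-12).sum() / n_rows
        else:
            pc = (1 + (max_mass >= mass).sum()) / (n_rows + 1)
        clusters.append(Cluster(i, j, d, mass, float(pc)))
    return PermutationResult(axis_name, observed, p_hat, clusters,
                             n_eff, seed)


def t_test(a, b) -> dict:
    """Two-sample unpaired t-test with pooled variance (df = na+nb-2)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "df": len(a) + len(b) - 2,
            "p": float(res.pvalue)}


def mann_whitney(a, b) -> dict:
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def pearson(a, b) -> dict:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance sample")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p)}


def anova_two_way(values, factor_a, factor_b, interaction: bool = False) -> dict:
    """Two-way ANOVA (type-II sums of squares) via statsmodels."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frame = pd.DataFrame({
        "y": np.asarray(values, float),
        "a": list(factor_a),
        "b": list(factor_b),
    })
    formula = "y ~ C(a) * C(b)" if interaction else "y ~ C(a) + C(b)"
    table = sm.stats.anova_lm(ols(formula, frame).fit(), typ=2)
    out = {}
    for row in table.index:
        if row == "Residual":
            continue
        out[row] = {"F": float(table.loc[row, "F"]),
                    "df": float(table.loc[row, "df"]),
                    "p": float(table.loc[row, "PR(>F)"])}
    return out


def standard_tests(a, b) -> dict:
    """t-test, Mann-Whitney U and Pearson r (where defined) in one map."""
    out = {"t_test": t_test(a, b), "mann_whitney": mann_whitney(a, b)}
    if len(a) == len(b):
        try:
            out["pearson"] = pearson(a, b)
        except ValueError:
            pass
    return out


def cohens_d(spec: PowerSpec) -> float:
    """|mean_a - mean_b| / sd."""
    return abs(spec.mean_a - spec.mean_b) / spec.sd


def t_test_power(spec: PowerSpec) -> float:
    """Achieved power of the two-sided two-sample t-test.

    Uses the noncentral t distribution with noncentrality d*sqrt(n/2)
    and df = 2n - 2.
    """
    d = cohens_d(spec)
    n = spec.n_per_group
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1 - spec.alpha / 2.0, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )
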