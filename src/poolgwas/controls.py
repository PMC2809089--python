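"""Supporting analyses: t-test power, stratification and assay-noise controls.

Pooled case/control comparisons can be confounded by occult stratification
(hidden ancestry differences between case and control pools) and by noisy
assays.  The controls here quantify (a) the overlap of association hits with
SNPs showing the largest between-population frequency differences or the
largest assay noise, against a hypergeometric chance expectation, and (b)
whether principal components of the pool-level allele-frequency matrix
separate phenotype groups beyond what label permutation explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "two_sample_t_power",
    "overlap_control",
    "pca_separation",
    "PcaSeparation",
]


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t power inputs on the arctan measurement scale.

    ``delta`` is the case-control difference in mean pool value, ``sd`` the
    per-pool standard deviation, ``n1``/``n2`` the pool counts per group.
    """

    delta: float
    sd: float
    n1: int
    n2: int
    alpha: float = 0.05

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least two pools per group")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


def two_sample_t_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t test via the noncentral t.

    Uses the pooled-variance test's df = n1+n2-2 and noncentrality
    delta / (sd * sqrt(1/n1 + 1/n2)); equals alpha exactly at delta = 0.
    """
    df = spec.n1 + spec.n2 - 2
    ncp = spec.delta / (spec.sd * np.sqrt(1.0 / spec.n1 + 1.0 / spec.n2))
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_table(deltas, sd: float, designs, alpha: float = 0.05) -> pd.DataFrame:
    """Power over a grid of effect sizes and (n1, n2) pool designs."""
    rows = []
    for delta in deltas:
        for n1, n2 in designs:
            rows.append({
                "delta": delta, "sd": sd, "n1": n1, "n2": n2, "alpha": alpha,
                "power": two_sample_t_power(PowerSpec(delta, sd, n1, n2, alpha)),
            })
    return pd.DataFrame(rows)


def overlap_control(hit_snps: set, suspect_snps: set, universe: set):
    """Observed vs expected overlap of hits with suspect SNPs.

    ``suspect_snps`` are e.g. the SNPs with the largest between-population
    allele-frequency differences, or the noisiest assays.  Expected overlap is
    |hit|*|suspect|/|universe|; the two-sided p comes from the hypergeometric
    distribution (summing all outcomes no more probable than the observed).
    """
    if not universe:
        raise ValueError("empty SNP universe")
    hit_snps, suspect_snps, universe = set(hit_snps), set(suspect_snps), set(universe)
    if not hit_snps <= universe or not suspect_snps <= universe:
        raise ValueError("hit and suspect sets must be subsets of the universe")
    n, k, m = len(universe), len(hit_snps), len(suspect_snps)
    observed = len(hit_snps & suspect_snps)
    expected = k * m / n
    dist = stats.hypergeom(n, m, k)
    support = np.arange(max(0, k + m - n), min(k, m) + 1)
    pmf = dist.pmf(support)
    p = float(min(1.0, pmf[pmf <= dist.pmf(observed) * (1 + 1e-9)].sum()))
    return observed, expected, p


@dataclass
class PcaSeparation:
    """Principal components of the pools-by-SNPs matrix with permutation p's."""

    scores: np.ndarray            # (n_pools, n_components)
    variance_fraction: np.ndarray
    separation_p: np.ndarray      # per component, phenotype separation
    observed_separation: np.ndarray


def pca_separation(pool_matrix: np.ndarray, phenotypes, n_trials: int = 1_000,
                   seed: int = 0, n_components: int | None = None) -> PcaSeparation:
    """PCA of pool-level mean arctan values with phenotype-separation p-values.

    Columns (SNPs) are centered; components come from the SVD of the centered
    matrix with a deterministic sign convention, so results do not depend on
    pool row order.  Per component the statistic is the absolute difference of
    phenotype-group mean scores; its p is empirical over label permutations.
    """
    x = np.asarray(pool_matrix, dtype=float)
    phenotypes = np.asarray(phenotypes)
    if x.shape[0] < 3:
        raise ValueError("need at least three pools")
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("constant pool matrix has no principal components")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    total_var = (s**2).sum()
    keep = s > s.max() * 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    if n_components is not None:
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    scores = u * s
    var_frac = s**2 / total_var

    case = phenotypes == "case"
    obs = np.abs(scores[case].mean(axis=0) - scores[~case].mean(axis=0))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(scores.shape[1], dtype=np.int64)
    for _ in range(n_trials):
        perm = rng.permutation(case)
        stat = np.abs(scores[perm].mean(axis=0) - scores[~perm].mean(axis=0))
        exceed += stat >= obs
    p = (exceed + 1) / (n_trials + 1)
    return PcaSeparation(scores, var_frac, p, obs)
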