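"""Empirical null machinery: Monte Carlo resampling and phenotype permutation.

All significance in this pipeline is resampling-based.  Null trials resample
"pseudopositive" SNPs without replacement from the real SNP map — preserving
its spacing structure — or permute phenotype labels across pools.  Empirical
p-values use the add-one convention p = (x+1)/(n+1), where x counts null
trials whose statistic matched or exceeded the observed value, so zero
exceedances over n trials reports 1/(n+1) rather than zero.

Flavors:

* ``mc_overlap_p`` — chance intersection of two random SNP subsets;
* ``mc_cluster_p`` (Monte Carlo I) — chance extent of distance clustering;
* ``mc_gene_convergence_p`` (Monte Carlo II) — chance cross-sample gene
  convergence under the cluster-then-converge analysis;
* ``mc_gene_level_p`` (Monte Carlo III) — per-gene significance via random
  gene-resident segments of matched length;
* ``permutation_p`` — phenotype-label permutation of the full pipeline
  statistic, pools being the permutation unit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .cluster import ConvergenceCriteria, GenomeIndex, assign_clusters_to_genes

__all__ = [
    "EmpiricalP",
    "NullSummary",
    "mc_overlap_p",
    "mc_cluster_p",
    "mc_gene_convergence_p",
    "mc_gene_level_p",
    "permutation_p",
    "true_positive_fraction",
]


@dataclass
class NullSummary:
    mean: float
    sd: float
    quantiles: dict


@dataclass
class EmpiricalP:
    """Observed statistic against a resampled null.

    ``p = (n_exceed + 1) / (n_trials + 1)`` for Monte Carlo nulls; for exact
    permutation enumeration (``method="exact"``) p is the exact fraction of
    labelings at or beyond the observed statistic (the identity labeling
    guarantees p > 0).
    """

    observed_stat: float
    n_trials: int
    n_exceed: int
    p: float
    seed: int | None
    null: NullSummary | None = None
    method: str = "monte_carlo"


def _empirical(observed, null_stats, seed, method="monte_carlo") -> EmpiricalP:
    null_stats = np.asarray(null_stats)
    n = null_stats.size
    x = int((null_stats >= observed).sum())
    if method == "exact":
        p = x / n
    else:
        p = (x + 1) / (n + 1)
    qs = {q: float(np.quantile(null_stats, q)) for q in (0.5, 0.95, 0.99)}
    null = NullSummary(float(null_stats.mean()), float(null_stats.std(ddof=1)) if n > 1 else 0.0, qs)
    return EmpiricalP(float(observed), n, x, float(p), seed, null, method)


def mc_overlap_p(n_universe: int, n_a: int, n_b: int, observed_overlap: int,
                 n_trials: int = 100_000, seed: int = 0,
                 method: str = "hypergeom") -> EmpiricalP:
    """Chance that two random SNP subsets intersect in >= the observed count.

    Each trial draws subsets of sizes ``n_a`` and ``n_b`` without replacement
    from a universe of ``n_universe`` SNPs; the trial statistic is the
    intersection size — distributed Hypergeometric(N, n_a, n_b), which
    ``method="hypergeom"`` samples directly.  ``method="sets"`` performs the
    literal two-subset sampling (slow; for validation).
    """
    if not (n_a <= n_universe and n_b <= n_universe):
        raise ValueError("subset sizes exceed the universe")
    if observed_overlap > min(n_a, n_b):
        raise ValueError("observed overlap exceeds the smaller subset")
    rng = np.random.default_rng(seed)
    if method == "hypergeom":
        stats = rng.hypergeometric(n_a, n_universe - n_a, n_b, size=n_trials)
    elif method == "sets":
        stats = np.empty(n_trials, dtype=np.int64)
        universe = np.arange(n_universe)
        for i in range(n_trials):
            a = rng.choice(universe, size=n_a, replace=False)
            b = rng.choice(universe, size=n_b, replace=False)
            stats[i] = np.intersect1d(a, b, assume_unique=True).size
    else:
        raise ValueError("method must be 'hypergeom' or 'sets'")
    return _empirical(observed_overlap, stats, seed)


def _clustered_snp_count(index: GenomeIndex, idx: np.ndarray,
                         criteria: ConvergenceCriteria) -> int:
    """Number of SNPs (by sorted-map index) lying in qualifying chains."""
    idx = np.sort(idx)
    if idx.size == 0:
        return 0
    pos = index.positions[idx]
    same_chrom = index.chroms[idx][1:] == index.chroms[idx][:-1]
    ok = same_chrom & (np.diff(pos) <= criteria.max_gap)
    # run lengths of consecutive chained members
    breaks = np.flatnonzero(~ok)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [idx.size]])
    sizes = ends - starts
    return int(sizes[sizes >= criteria.min_cluster_size].sum())


def mc_cluster_p(index: GenomeIndex, n_positive: int, criteria: ConvergenceCriteria,
                 observed_clustered: int, n_trials: int = 10_000,
                 seed: int = 0) -> EmpiricalP:
    """Monte Carlo I: chance extent of clustering of positive SNPs.

    Each trial samples ``n_positive`` pseudopositive SNPs without replacement
    from the real map and counts how many lie in qualifying clusters; the
    empirical p is the fraction of trials matching or exceeding the observed
    clustered-SNP count.
    """
    n = len(index.snp_ids)
    if n_positive > n:
        raise ValueError("n_positive exceeds the SNP map size")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_trials, dtype=np.int64)
    for i in range(n_trials):
        idx = rng.choice(n, size=n_positive, replace=False)
        stats[i] = _clustered_snp_count(index, idx, criteria)
    return _empirical(observed_clustered, stats, seed)


def _convergent_gene_count(index: GenomeIndex, idx_a: np.ndarray, idx_b: np.ndarray,
                           criteria: ConvergenceCriteria, rule: str = "count") -> int:
    genes = []
    for idx in (idx_a, idx_b):
        clusters = index.clusters_from_indices(idx, criteria)
        hits = assign_clusters_to_genes(clusters, index,
                                        min_support=criteria.min_cluster_size, rule=rule)
        genes.append(set(hits["gene_id"]) if not hits.empty else set())
    return len(genes[0] & genes[1])


def mc_gene_convergence_p(index: GenomeIndex, n_pos_a: int, n_pos_b: int,
                          criteria: ConvergenceCriteria, observed_genes: int,
                          n_trials: int = 1_000, seed: int = 0,
                          rule: str = "count") -> EmpiricalP:
    """Monte Carlo II: chance cross-sample gene convergence.

    Each trial draws independent pseudopositive sets of the stated per-sample
    sizes from the real map, runs the cluster-then-converge analysis, and
    counts convergent genes.  The null mean also feeds
    :func:`true_positive_fraction`.
    """
    n = len(index.snp_ids)
    if max(n_pos_a, n_pos_b) > n:
        raise ValueError("pseudopositive counts exceed the SNP map size")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_trials, dtype=np.int64)
    for i in range(n_trials):
        idx_a = rng.choice(n, size=n_pos_a, replace=False)
        idx_b = rng.choice(n, size=n_pos_b, replace=False)
        stats[i] = _convergent_gene_count(index, idx_a, idx_b, criteria, rule)
    return _empirical(observed_genes, stats, seed)


def _segment_stat(index: GenomeIndex, chrom: str, lo: int, hi: int,
                  pos_sets: list[np.ndarray], criteria: ConvergenceCriteria,
                  statistic: str):
    """Features displayed by a genomic segment [lo, hi] on one chromosome.

    ``pos_sets`` holds each sample's positive SNP indices (sorted map order).
    ``statistic="clustered_snps"``: clustered positive count within the
    segment (approach-1 feature, single set).  ``statistic="both_samples"``:
    1 if every sample contributes a qualifying cluster inside the segment.
    """
    per_set = []
    for idx in pos_sets:
        sl = index.chrom_slices.get(chrom)
        if sl is None:
            per_set.append(0)
            continue
        sub = idx[(idx >= sl.start) & (idx < sl.stop)]
        pos = index.positions[sub]
        inside = sub[(pos >= lo) & (pos <= hi)]
        per_set.append(_clustered_snp_count(index, inside, criteria))
    if statistic == "clustered_snps":
        return per_set[0]
    return int(all(c > 0 for c in per_set))


def mc_gene_level_p(gene_id, index: GenomeIndex, positives_a, positives_b=None,
                    criteria: ConvergenceCriteria = ConvergenceCriteria(),
                    n_trials: int = 10_000, seed: int = 0,
                    statistic: str | None = None) -> EmpiricalP:
    """Monte Carlo III: per-gene significance via random gene-resident segments.

    Each trial places a segment of the same length as the gene's flanked
    interval uniformly at random among positions where it lies wholly within
    some annotated gene's flanked interval, and asks whether the segment
    displays at least the features observed in the actual gene — clustered
    positive SNPs for the approach-1 statistic (default when one positive set
    is given) or qualifying clusters from both samples for the approach-2
    statistic (default when two sets are given).
    """
    ann = index.annotation
    matches = ann.index[ann["gene_id"] == gene_id]
    if len(matches) == 0:
        raise ValueError(f"gene {gene_id!r} not in annotation")
    gi = int(matches[0])
    chrom, lo, hi = index.gene_interval(gi)
    seg_len = hi - lo + 1

    pos_sets = [np.sort(index.indices_of(list(positives_a)))]
    if positives_b is not None:
        pos_sets.append(np.sort(index.indices_of(list(positives_b))))
    if statistic is None:
        statistic = "both_samples" if positives_b is not None else "clustered_snps"

    observed = _segment_stat(index, chrom, lo, hi, pos_sets, criteria, statistic)

    # placements: every (gene, start) with the segment wholly inside the
    # gene's flanked interval, weighted by the number of valid starts
    intervals = []  # (chrom, lo, n_valid_starts)
    for g in ann.index:
        c, glo, ghi = index.gene_interval(int(g))
        n_place = (ghi - glo + 1) - seg_len + 1
        if n_place > 0:
            intervals.append((c, glo, n_place))
    if not intervals:
        raise ValueError("gene's flanked interval is longer than every annotated interval")
    weights = np.array([n for _, _, n in intervals], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    gene_pick = rng.choice(len(intervals), size=n_trials, p=weights)
    stats = np.empty(n_trials, dtype=np.int64)
    for i, g in enumerate(gene_pick):
        c, glo, n_place = intervals[g]
        start = glo + int(rng.integers(0, n_place))
        stats[i] = _segment_stat(index, c, start, start + seg_len - 1, pos_sets,
                                 criteria, statistic)
    return _empirical(observed, stats, seed)


def permutation_p(panel_a, panel_b, statistic=None, n_trials: int = 10_000,
                  seed: int = 0, alpha: float = 0.05,
                  chunk: int = 500) -> EmpiricalP:
    """Phenotype-label permutation of a cross-sample pipeline statistic.

    Case/control labels are shuffled across pools *within each sample
    independently* (pools are the permutation unit; per-sample case counts
    are preserved).  The default statistic is the approach-1 reproducible-SNP
    count: SNPs with Welch p < ``alpha`` in both samples.  When the number of
    distinct label assignments is below ``n_trials`` the permutations are
    enumerated exhaustively and the exact p reported.

    A custom ``statistic`` is a callable ``f(means_a, case_a, means_b,
    case_b) -> float`` over pool-mean matrices and boolean case masks.
    """
    ids_a, ids_b = panel_a.snp_ids, panel_b.snp_ids
    if not np.array_equal(ids_a, ids_b):
        raise ValueError("panels must share an identical SNP universe")
    means_a = panel_a.pool_means()
    means_b = panel_b.pool_means()
    ok = ~(np.isnan(means_a).any(axis=0) | np.isnan(means_b).any(axis=0))
    means_a, means_b = means_a[:, ok], means_b[:, ok]
    case_a = panel_a.case_mask()
    case_b = panel_b.case_mask()
    na, nb = means_a.shape[0], means_b.shape[0]
    ka, kb = int(case_a.sum()), int(case_b.sum())

    if statistic is None:
        statistic = lambda ma, ca, mb, cb: int(
            (_welch_positive(ma, ca, alpha) & _welch_positive(mb, cb, alpha)).sum()
        )
    observed = statistic(means_a, case_a, means_b, case_b)

    total = math.comb(na, ka) * math.comb(nb, kb)
    rng = np.random.default_rng(seed)
    if total <= n_trials:
        stats = []
        for combo_a in itertools.combinations(range(na), ka):
            ca = np.zeros(na, dtype=bool)
            ca[list(combo_a)] = True
            for combo_b in itertools.combinations(range(nb), kb):
                cb = np.zeros(nb, dtype=bool)
                cb[list(combo_b)] = True
                stats.append(statistic(means_a, ca, means_b, cb))
        return _empirical(observed, stats, seed, method="exact")

    stats = np.empty(n_trials)
    for i in range(n_trials):
        ca = np.zeros(na, dtype=bool)
        ca[rng.choice(na, size=ka, replace=False)] = True
        cb = np.zeros(nb, dtype=bool)
        cb[rng.choice(nb, size=kb, replace=False)] = True
        stats[i] = statistic(means_a, ca, means_b, cb)
    return _empirical(observed, stats, seed)


def reproducible_count_permutation(panel_a, panel_b, n_trials: int = 10_000,
                                   seed: int = 0, alpha: float = 0.05,
                                   chunk: int = 500) -> EmpiricalP:
    """Vectorized permutation test of the approach-1 reproducible-SNP count.

    Equivalent to :func:`permutation_p` with the default statistic but runs
    all permutations through batched matrix products, making 10,000 trials on
    tens of thousands of SNPs practical.
    """
    if not np.array_equal(panel_a.snp_ids, panel_b.snp_ids):
        raise ValueError("panels must share an identical SNP universe")
    means_a = panel_a.pool_means()
    means_b = panel_b.pool_means()
    ok = ~(np.isnan(means_a).any(axis=0) | np.isnan(means_b).any(axis=0))
    means_a, means_b = means_a[:, ok], means_b[:, ok]
    case_a, case_b = panel_a.case_mask(), panel_b.case_mask()
    observed = int((_welch_positive(means_a, case_a, alpha)
                    & _welch_positive(means_b, case_b, alpha)).sum())
    rng = np.random.default_rng(seed)
    stats = np.empty(n_trials, dtype=np.int64)
    done = 0
    while done < n_trials:
        size = min(chunk, n_trials - done)
        pos_a = _welch_positive_batch(means_a, int(case_a.sum()), alpha, rng, size)
        pos_b = _welch_positive_batch(means_b, int(case_b.sum()), alpha, rng, size)
        stats[done:done + size] = (pos_a & pos_b).sum(axis=1)
        done += size
    return _empirical(observed, stats, seed)


def _welch_positive(means: np.ndarray, case: np.ndarray, alpha: float) -> np.ndarray:
    from .signal import welch_t

    _, p, _, _ = welch_t(means[case], means[~case])
    return p < alpha


def _welch_positive_batch(means: np.ndarray, k: int, alpha: float,
                          rng: np.random.Generator, n_perm: int) -> np.ndarray:
    """Boolean (n_perm, n_snps) of Welch p < alpha under permuted case labels."""
    n = means.shape[0]
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    ind = np.zeros((n_perm, n))
    np.put_along_axis(ind, order[:, :k], 1.0, axis=1)
    x, x2 = means, means**2
    tot1, tot2 = x.sum(axis=0), x2.sum(axis=0)
    s1 = ind @ x
    s2 = ind @ x2
    m1 = s1 / k
    m2 = (tot1 - s1) / (n - k)
    v1 = np.maximum(s2 - k * m1**2, 0.0) / (k - 1)
    v2 = np.maximum(tot2 - s2 - (n - k) * m2**2, 0.0) / (n - k - 1)
    se2 = v1 / k + v2 / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (k**2 * (k - 1)) + v2**2 / ((n - k) ** 2 * (n - k - 1)))
    # |t| vs the two-sided critical value; Welch df lies in the narrow range
    # [min(k,n-k)-1, n-2], over which t_crit(df) is smooth, so a dense
    # interpolation grid replaces a per-element CDF evaluation
    lo, hi = min(k, n - k) - 1.0, n - 2.0
    grid = np.linspace(lo, hi, 4096)
    crit = stats.t.isf(alpha / 2.0, grid)
    pos = np.abs(t) > np.interp(df, grid, crit)
    degenerate = se2 == 0
    pos[degenerate] = (m1 - m2)[degenerate] != 0
    return pos


def true_positive_fraction(observed_genes: int, null: NullSummary) -> float:
    """Estimated fraction of reported genes that are true rather than chance.

    ``(observed - null_mean) / observed``, clamped to [0, 1]; the null mean
    comes from the matching Monte Carlo II run's trial statistics.
    """
    if observed_genes == 0:
        raise ValueError("true-gene fraction undefined with zero observed genes")
    return float(min(1.0, max(0.0, (observed_genes - null.mean) / observed_genes)))
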