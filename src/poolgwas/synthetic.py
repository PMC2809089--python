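"""Synthetic pooled-array study generator.

Emulates the statistical structure the pipeline consumes: two populations
with population-specific allele frequencies, case/control pools of 20
individuals assayed on 3 replicate arrays, replicate-array noise sized so the
replicate SEM is ~0.03, binomial pool composition giving pool-to-pool SEM
~0.02, LD-like blocks in which several nearby SNPs share a planted
case-control allele-frequency difference (5-10%), and a pooled-vs-individual
validation design.

The measurement scale is arctan(f/(1-f)) of the pool allele frequency — a
bounded, monotone proxy consistent with arctan(A/B) under proportional
hybridization; no probe-level physics is modeled.  Base allele frequencies
follow a U-shaped symmetric Beta spectrum mapped to [0.10, 0.90]; the shape
parameter is fixed where the binomial pool-composition variance, averaged
over that spectrum, reproduces the ~0.02 across-pool SEM.

All randomness flows from one master seed through named substreams
(map, truth, pools, validation), so every artifact is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import IntensityPanel, HALF_PI

#: per-array replicate noise SD; SEM of the mean of 3 replicates is then 0.03
DEFAULT_REPLICATE_SD = 0.03 * np.sqrt(3.0)

#: symmetric Beta shape of the base allele-frequency spectrum (see module doc);
#: solved so E[arctan-scale binomial pool variance]/40 matches an across-pool
#: SEM of 0.02 over ~20 pools, with the range keeping boundary clipping rare
FREQ_BETA_SHAPE = 0.149
FREQ_RANGE = (0.10, 0.90)

#: base-frequency window for planted effect loci, keeping f + 0.10 in range
EFFECT_FREQ_RANGE = (0.20, 0.60)

DEFAULT_INDIVIDUALS_PER_POOL = 20
DEFAULT_REPLICATES = 3

#: pool designs (n case pools, n control pools) of the two samples: sample A
#: mirrors 400 case / 280 control individuals in pools of 20, sample B 700/240
DEFAULT_DESIGNS = {"A": (20, 14), "B": (35, 12)}

__all__ = [
    "NoiseModel",
    "SyntheticTruth",
    "simulate_map_and_genes",
    "plant_effects",
    "simulate_pools",
    "simulate_two_sample_study",
    "simulate_validation_design",
    "make_pool_design",
    "draw_base_frequencies",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of the master seed (map/truth/pools/validation)."""
    streams = {"map": 0, "truth": 1, "pools": 2, "validation": 3}
    return np.random.default_rng([seed, streams.get(name, 9)])


@dataclass
class NoiseModel:
    """Measurement and composition noise of the pooled assay.

    ``replicate_sd`` is the per-array noise SD on the arctan scale (default
    0.03*sqrt(3), i.e. replicate SEM 0.03 over 3 arrays); pool composition is
    a binomial draw of 2*n_individuals chromosomes from the population allele
    frequency, which over the default frequency spectrum yields across-pool
    SEM near 0.02.
    """

    replicate_sd: float = DEFAULT_REPLICATE_SD

    def __post_init__(self):
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of planted effects, for scoring recovery."""

    loci: pd.DataFrame          # locus, gene_id, snp_id, pos, effect_a, effect_b
    genes: list                 # gene_ids carrying planted loci
    effect_size: float
    block_span: int
    seed: int

    def effects_for(self, sample: str) -> dict:
        col = "effect_a" if sample.upper().startswith("A") else "effect_b"
        return dict(zip(self.loci["snp_id"], self.loci[col]))

    @property
    def effect_snps(self) -> set:
        return set(self.loci["snp_id"])


def simulate_map_and_genes(n_snps: int = 50_000, n_chromosomes: int = 22,
                           n_genes: int = 500, chrom_length: int = 7_500_000,
                           gene_length_mean: int = 60_000, seed: int = 0):
    """Random SNP map and non-overlapping gene annotation.

    SNP positions are uniform within equal-length chromosomes (matching the
    real panel's ~1 SNP / 3.3 kb density at the defaults); gene lengths are
    Gamma(2, mean/2) and genes are placed without overlap by distributing the
    spare length as random gaps.
    """
    if n_snps < n_genes:
        raise ValueError("need at least as many SNPs as genes")
    rng = _rng(seed, "map")
    counts = np.full(n_chromosomes, n_snps // n_chromosomes)
    counts[: n_snps % n_chromosomes] += 1
    rows = []
    for c in range(n_chromosomes):
        pos = rng.choice(chrom_length, size=counts[c], replace=False) + 1
        pos.sort()
        chrom = f"chr{c + 1}"
        rows.append(pd.DataFrame({
            "snp_id": [f"rs{c + 1}_{i}" for i in range(counts[c])],
            "chrom": chrom, "pos": pos}))
    snp_map = pd.concat(rows, ignore_index=True)

    g_counts = np.full(n_chromosomes, n_genes // n_chromosomes)
    g_counts[: n_genes % n_chromosomes] += 1
    grows = []
    gid = 0
    for c in range(n_chromosomes):
        k = int(g_counts[c])
        if k == 0:
            continue
        lengths = np.maximum(
            rng.gamma(2.0, gene_length_mean / 2.0, size=k), 1_000
        ).astype(np.int64)
        spare = chrom_length - int(lengths.sum())
        if spare <= k:
            raise ValueError("requested genes do not fit in the chromosome")
        gaps = rng.multinomial(spare - k, np.full(k + 1, 1.0 / (k + 1)))
        start = 1
        for j in range(k):
            start += gaps[j] + 1
            grows.append({"gene_id": f"gene{gid}", "chrom": f"chr{c + 1}",
                          "start": start, "end": start + lengths[j] - 1})
            start += int(lengths[j])
            gid += 1
    annotation = pd.DataFrame(grows)
    return snp_map, annotation


def plant_effects(snp_map: pd.DataFrame, annotation: pd.DataFrame,
                  n_loci: int = 20, effect_size: float = 0.10,
                  block_span: int = 25_000, snps_per_block: int = 6,
                  two_population: bool = True, tagging: str = "shared",
                  seed: int = 0) -> SyntheticTruth:
    """Plant clustered case-control allele-frequency effects inside genes.

    Each locus is a run of ``snps_per_block`` consecutive SNPs spanning at
    most ``block_span`` bp wholly inside one gene — an LD-like block whose
    members all shift together by ``effect_size`` in cases.  With
    ``two_population`` the same loci carry the effect in both samples;
    ``tagging="disjoint"`` instead splits each block's SNPs alternately
    between the samples (allelic-heterogeneity fixture: recoverable by the
    cluster-then-converge analysis but not by the intersection analysis).
    """
    if tagging not in ("shared", "disjoint"):
        raise ValueError("tagging must be 'shared' or 'disjoint'")
    rng = _rng(seed, "truth")
    if n_loci == 0:
        loci = pd.DataFrame(columns=["locus", "gene_id", "snp_id", "pos",
                                     "effect_a", "effect_b"])
        return SyntheticTruth(loci, [], effect_size, block_span, seed)

    m = snp_map.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    candidates = []  # (gene_id, window row indices)
    for _, gene in annotation.iterrows():
        sub = m[(m["chrom"] == gene["chrom"]) & (m["pos"] >= gene["start"])
                & (m["pos"] <= gene["end"])]
        if len(sub) < snps_per_block:
            continue
        pos = sub["pos"].to_numpy()
        spans = pos[snps_per_block - 1:] - pos[: len(pos) - snps_per_block + 1]
        good = np.flatnonzero(spans <= block_span)
        if good.size:
            candidates.append((gene["gene_id"], sub.index.to_numpy(), good))
    if len(candidates) < n_loci:
        raise ValueError(
            f"only {len(candidates)} genes contain a {snps_per_block}-SNP run "
            f"within {block_span} bp; cannot plant {n_loci} loci")
    picks = rng.choice(len(candidates), size=n_loci, replace=False)
    rows = []
    genes = []
    for locus, ci in enumerate(picks):
        gene_id, row_idx, good = candidates[ci]
        w = int(good[rng.integers(good.size)])
        block = row_idx[w: w + snps_per_block]
        genes.append(gene_id)
        for j, ri in enumerate(block):
            if tagging == "disjoint":
                ea = effect_size if j % 2 == 0 else 0.0
                eb = effect_size if j % 2 == 1 else 0.0
            else:
                ea = effect_size
                eb = effect_size if two_population else 0.0
            rows.append({"locus": locus, "gene_id": gene_id,
                         "snp_id": m.loc[ri, "snp_id"], "pos": int(m.loc[ri, "pos"]),
                         "effect_a": ea, "effect_b": eb})
    return SyntheticTruth(pd.DataFrame(rows), genes, effect_size, block_span, seed)


def make_pool_design(sample: str, n_case_pools: int, n_control_pools: int,
                     n_individuals: int = DEFAULT_INDIVIDUALS_PER_POOL) -> pd.DataFrame:
    """Pool design table: one row per pool of ``n_individuals`` subjects."""
    rows = []
    for i in range(n_case_pools):
        rows.append({"pool_id": f"{sample}_case{i}", "sample": sample,
                     "phenotype": "case", "n_individuals": n_individuals})
    for i in range(n_control_pools):
        rows.append({"pool_id": f"{sample}_ctrl{i}", "sample": sample,
                     "phenotype": "control", "n_individuals": n_individuals})
    return pd.DataFrame(rows)


def draw_base_frequencies(n_snps: int, rng: np.random.Generator,
                          shape: float = FREQ_BETA_SHAPE,
                          lo: float = FREQ_RANGE[0],
                          hi: float = FREQ_RANGE[1]) -> np.ndarray:
    return lo + (hi - lo) * rng.beta(shape, shape, size=n_snps)


def simulate_pools(design: pd.DataFrame, snp_map: pd.DataFrame,
                   base_freq: np.ndarray, effects: dict | None = None,
                   noise: NoiseModel = NoiseModel(),
                   n_replicates: int = DEFAULT_REPLICATES,
                   seed: int = 0) -> IntensityPanel:
    """Pooled replicate-array panel for one sample.

    Per pool, the realized allele frequency is a binomial draw of
    2*n_individuals chromosomes at the population frequency (shifted by the
    planted effect in case pools); each replicate array records
    arctan(f/(1-f)) plus Gaussian replicate noise, clipped to [0, pi/2].
    """
    rng = _rng(seed, "pools")
    snp_ids = snp_map["snp_id"].to_numpy()
    n_snps = len(snp_ids)
    base_freq = np.asarray(base_freq, dtype=float)
    if base_freq.shape != (n_snps,):
        raise ValueError("base_freq must align with the SNP map")
    delta = np.zeros(n_snps)
    if effects:
        idx = {s: i for i, s in enumerate(snp_ids)}
        for s, d in effects.items():
            delta[idx[s]] = d
    values = np.empty((len(design), n_replicates, n_snps))
    for i, row in design.reset_index(drop=True).iterrows():
        f = base_freq + (delta if row["phenotype"] == "case" else 0.0)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("allele frequency out of [0,1] after effect shift")
        n_chrom = 2 * int(row["n_individuals"])
        f_pool = rng.binomial(n_chrom, f) / n_chrom
        measure = np.arctan2(f_pool, 1.0 - f_pool)
        reps = measure + rng.normal(0.0, noise.replicate_sd, (n_replicates, n_snps))
        values[i] = np.clip(reps, 0.0, HALF_PI)
    return IntensityPanel(design.reset_index(drop=True), snp_ids, values)


def simulate_two_sample_study(n_snps: int = 50_000, n_genes: int = 500,
                              n_loci: int = 20, effect_size: float = 0.10,
                              snps_per_block: int = 6, block_span: int = 25_000,
                              designs: dict = None, tagging: str = "shared",
                              noise: NoiseModel = NoiseModel(), seed: int = 0,
                              n_chromosomes: int = 22,
                              chrom_length: int = 7_500_000):
    """End-to-end study bundle: map, genes, truth, and both samples' panels.

    The two samples come from distinct populations: base allele frequencies
    are drawn independently per population except at planted loci, where both
    populations share the locus (common-allele assumption) and the base
    frequency sits mid-range so the case shift stays in bounds.
    """
    designs = designs or DEFAULT_DESIGNS
    snp_map, annotation = simulate_map_and_genes(
        n_snps, n_chromosomes, n_genes, chrom_length, seed=seed)
    truth = plant_effects(snp_map, annotation, n_loci, effect_size, block_span,
                          snps_per_block, tagging=tagging, seed=seed)
    panels = {}
    freqs = {}
    snp_ids = snp_map["snp_id"].to_numpy()
    effect_idx = pd.Index(snp_ids).get_indexer(truth.loci["snp_id"]) if len(truth.loci) else []
    for k, sample in enumerate(sorted(designs)):
        f = draw_base_frequencies(len(snp_ids), _rng(seed + 1000 * (k + 1), "pools"))
        if len(truth.loci):
            shared = _rng(seed, "truth").uniform(*EFFECT_FREQ_RANGE,
                                                 size=len(truth.loci))
            f[effect_idx] = shared
        freqs[sample] = f
        n_case, n_control = designs[sample]
        design = make_pool_design(sample, n_case, n_control)
        panels[sample] = simulate_pools(
            design, snp_map, f, truth.effects_for(sample), noise,
            seed=seed + 7 * (k + 1))
    return snp_map, annotation, truth, panels, freqs


def simulate_validation_design(n_snps: int = 2_000, pool_sizes=(2, 5, 15),
                               n_individuals: int = 81,
                               noise: NoiseModel = NoiseModel(),
                               n_replicates: int = DEFAULT_REPLICATES,
                               seed: int = 0, min_spread: float = 0.10):
    """Pooled-vs-individual validation: known genotypes pooled into small pools.

    Individuals receive Hardy-Weinberg genotypes at each SNP; they are then
    partitioned into pools of each stated size.  "Expected" is each pool's
    true allele frequency from the individual genotypes (on the arctan scale);
    "observed" is the noisy pooled arctan measure averaged over replicates.
    Returns (expected DataFrame pools x SNPs, observed DataFrame, report) with
    per-SNP Pearson correlations restricted to SNPs whose expected frequency
    spread across pools is at least ``min_spread``.
    """
    rng = _rng(seed, "validation")
    freq = draw_base_frequencies(n_snps, rng)
    genotypes = rng.binomial(2, freq, size=(n_individuals, n_snps))
    pools = []
    order = rng.permutation(n_individuals)
    for size in pool_sizes:
        for start in range(0, n_individuals - size + 1, size):
            pools.append((size, order[start: start + size]))
    expected = np.array([genotypes[idx].sum(axis=0) / (2 * len(idx))
                         for _, idx in pools])
    expected_measure = np.arctan2(expected, 1.0 - expected)
    observed = expected_measure + rng.normal(
        0.0, noise.replicate_sd, (n_replicates, len(pools), n_snps)).mean(axis=0)
    observed = np.clip(observed, 0.0, HALF_PI)
    spread = expected.max(axis=0) - expected.min(axis=0)
    qual = spread >= min_spread
    cors = np.full(n_snps, np.nan)
    em = expected_measure
    for j in np.flatnonzero(qual):
        if em[:, j].std() > 0 and observed[:, j].std() > 0:
            cors[j] = np.corrcoef(em[:, j], observed[:, j])[0, 1]
    report = pd.DataFrame({
        "snp": np.arange(n_snps), "expected_spread": spread,
        "qualifies": qual, "correlation": cors})
    index = [f"pool{size}_{i}" for i, (size, _) in enumerate(pools)]
    return (pd.DataFrame(em, index=index),
            pd.DataFrame(observed, index=index), report)
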