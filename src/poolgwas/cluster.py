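"""Distance-based clustering of positive SNPs and cross-sample gene convergence.

Two complementary strategies identify genes from two independent case/control
samples genotyped on the same SNP panel:

* approach 1, *converge then cluster*: intersect the two samples' nominally
  positive SNP sets ("reproducibly positive" SNPs), chain the shared SNPs
  into distance clusters, and report genes containing enough clustered SNPs;
* approach 2, *cluster then converge*: chain each sample's own positives into
  clusters and report genes tagged by at least one qualifying cluster from
  each sample.  Approach 2 tolerates allelic heterogeneity — the two samples
  may tag the same gene through different SNPs.

A cluster is a maximal chain of positive SNPs in which consecutive members
are separated by at most ``max_gap`` base pairs, with at least
``min_cluster_size`` members.  Genes are extended by symmetric flanks
(default 10 kb) before SNP membership is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

DEFAULT_FLANK = 10_000

__all__ = [
    "ConvergenceCriteria",
    "SnpCluster",
    "find_clusters",
    "cluster_positive_snps",
    "assign_clusters_to_genes",
    "converge_then_cluster",
    "cluster_then_converge",
    "criteria_grid_summary",
    "GenomeIndex",
    "TABLE_CRITERIA_GRID",
]


@dataclass(frozen=True)
class ConvergenceCriteria:
    """Cluster qualification thresholds: minimum size and maximum chain gap."""

    min_cluster_size: int = 3
    max_gap: int = 25_000
    alpha: float = 0.05

    def __post_init__(self):
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


#: the published criteria grid: sizes {3,4} x gaps {25 kb, 10 kb}
TABLE_CRITERIA_GRID = [
    ConvergenceCriteria(3, 25_000),
    ConvergenceCriteria(3, 10_000),
    ConvergenceCriteria(4, 25_000),
    ConvergenceCriteria(4, 10_000),
]


@dataclass
class SnpCluster:
    chromosome: str
    member_snps: list
    positions: np.ndarray
    start: int
    end: int

    @property
    def size(self) -> int:
        return len(self.member_snps)


def find_clusters(positions, criteria: ConvergenceCriteria, *, snp_ids=None,
                  chromosome: str = "") -> list[SnpCluster]:
    """Maximal single-linkage chains of positions with consecutive gaps <= max_gap.

    ``positions`` must be sorted ascending and deduplicated (one chromosome).
    Chains shorter than ``criteria.min_cluster_size`` are discarded.  The
    chaining is deterministic and unique: chain membership depends only on
    which consecutive gaps exceed ``max_gap``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted ascending and deduplicated")
    if snp_ids is None:
        snp_ids = positions
    snp_ids = np.asarray(snp_ids)
    clusters = []
    if positions.size == 0:
        return clusters
    breaks = np.flatnonzero(np.diff(positions) > criteria.max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [positions.size]])
    for s, e in zip(starts, ends):
        if e - s >= criteria.min_cluster_size:
            clusters.append(
                SnpCluster(
                    chromosome=chromosome,
                    member_snps=list(snp_ids[s:e]),
                    positions=positions[s:e],
                    start=int(positions[s]),
                    end=int(positions[e - 1]),
                )
            )
    return clusters


class GenomeIndex:
    """Sorted SNP coordinates plus a flanked-gene interval tree per chromosome.

    Built once from a SNP map and gene annotation, then shared by the
    convergence analyses and the Monte Carlo resampling loops.
    """

    def __init__(self, snp_map: pd.DataFrame, annotation: pd.DataFrame | None = None,
                 flank: int = DEFAULT_FLANK, exons: pd.DataFrame | None = None,
                 exon_only: bool = False):
        m = snp_map.sort_values(["chrom", "pos"], kind="mergesort")
        self.snp_ids = m["snp_id"].to_numpy()
        self.positions = m["pos"].to_numpy(dtype=np.int64)
        self.chroms = m["chrom"].to_numpy()
        self.id_to_idx = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self.id_to_idx) != len(self.snp_ids):
            raise ValueError("snp_id values must be unique")
        # contiguous [start, stop) slice per chromosome in the sorted order
        self.chrom_slices: dict[str, slice] = {}
        if len(self.chroms):
            change = np.flatnonzero(self.chroms[1:] != self.chroms[:-1]) + 1
            bounds = np.concatenate([[0], change, [len(self.chroms)]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                self.chrom_slices[self.chroms[a]] = slice(int(a), int(b))
        self.flank = int(flank)
        self.annotation = None
        self.trees: dict[str, IntervalTree] = {}
        # under exon-only membership a SNP supports a gene only when it lies
        # in an exon or in the flanking windows, not in introns
        self.exon_only = bool(exon_only)
        self.allowed: dict[int, np.ndarray] = {}
        if exon_only and exons is None:
            raise ValueError("exon_only membership requires an exon table")
        if annotation is not None:
            self.annotation = annotation.reset_index(drop=True)
            for gi, row in self.annotation.iterrows():
                start, end = int(row["start"]), int(row["end"])
                lo = max(1, start - self.flank)
                hi = end + self.flank
                # IntervalTree is half-open; +1 makes [lo, hi] inclusive
                self.trees.setdefault(row["chrom"], IntervalTree()).addi(lo, hi + 1, gi)
                if self.exon_only:
                    gene_exons = exons[exons["gene_id"] == row["gene_id"]]
                    ivs = [(lo, start - 1), (end + 1, hi)]
                    ivs += [(int(e["start"]), int(e["end"]))
                            for _, e in gene_exons.iterrows()]
                    self.allowed[gi] = np.array(
                        [iv for iv in ivs if iv[0] <= iv[1]], dtype=np.int64)

    def indices_of(self, snp_ids) -> np.ndarray:
        return np.fromiter((self.id_to_idx[s] for s in snp_ids), dtype=np.int64,
                           count=len(snp_ids))

    def clusters_from_indices(self, idx: np.ndarray,
                              criteria: ConvergenceCriteria) -> list[SnpCluster]:
        """Chain a set of SNP indices (into the sorted map) per chromosome."""
        idx = np.sort(np.asarray(idx, dtype=np.int64))
        clusters = []
        if idx.size == 0:
            return clusters
        chroms = self.chroms[idx]
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        bounds = np.concatenate([[0], change, [idx.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            sub = idx[a:b]
            clusters.extend(
                find_clusters(
                    self.positions[sub],
                    criteria,
                    snp_ids=self.snp_ids[sub],
                    chromosome=chroms[a],
                )
            )
        return clusters

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end + 1))

    def gene_interval(self, gene_idx: int) -> tuple[str, int, int]:
        row = self.annotation.iloc[gene_idx]
        return row["chrom"], max(1, int(row["start"]) - self.flank), int(row["end"]) + self.flank

    def gene_membership(self, gene_idx: int, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of positions counting toward the gene's support."""
        _, lo, hi = self.gene_interval(gene_idx)
        inside = (positions >= lo) & (positions <= hi)
        if self.exon_only:
            ivs = self.allowed.get(gene_idx)
            ok = np.zeros(len(positions), dtype=bool)
            if ivs is not None:
                for a, b in ivs:
                    ok |= (positions >= a) & (positions <= b)
            inside &= ok
        return inside


def cluster_positive_snps(positive_ids, index: GenomeIndex,
                          criteria: ConvergenceCriteria) -> list[SnpCluster]:
    """Chain a set of positive SNP ids into qualifying clusters genome-wide."""
    return index.clusters_from_indices(index.indices_of(list(positive_ids)), criteria)


def assign_clusters_to_genes(clusters: list[SnpCluster], index: GenomeIndex, *,
                             min_support: int, rule: str = "count") -> pd.DataFrame:
    """Map qualifying clusters onto flanked gene intervals.

    Under the default ``rule="count"`` a cluster supports a gene iff at least
    ``min_support`` of its member SNPs fall within the gene's flanked interval
    (boundaries inclusive); under ``rule="any"`` a single member inside
    suffices.  One cluster may support several overlapping genes.  Returns one
    row per supported gene with the distinct supporting SNPs pooled over
    clusters.
    """
    if rule not in ("count", "any"):
        raise ValueError("rule must be 'count' or 'any'")
    need = min_support if rule == "count" else 1
    per_gene_snps: dict[int, set] = {}
    per_gene_clusters: dict[int, list[int]] = {}
    for ci, cluster in enumerate(clusters):
        for gi in index.genes_overlapping(cluster.chromosome, cluster.start, cluster.end):
            inside = index.gene_membership(gi, cluster.positions)
            if int(inside.sum()) >= need:
                members = {s for s, ok in zip(cluster.member_snps, inside) if ok}
                per_gene_snps.setdefault(gi, set()).update(members)
                per_gene_clusters.setdefault(gi, []).append(ci)
    rows = []
    for gi in sorted(per_gene_snps):
        rows.append(
            {
                "gene_id": index.annotation.loc[gi, "gene_id"],
                "chrom": index.annotation.loc[gi, "chrom"],
                "n_snps": len(per_gene_snps[gi]),
                "snp_ids": sorted(map(str, per_gene_snps[gi])),
                "clusters": per_gene_clusters[gi],
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "n_snps", "snp_ids", "clusters"])


def _positive_set(assoc, alpha: float) -> set:
    from .signal import nominal_positive_set

    return nominal_positive_set(assoc, alpha)


def _check_universe(assoc_a: pd.DataFrame, assoc_b: pd.DataFrame):
    shared = set(assoc_a["snp_id"]) & set(assoc_b["snp_id"])
    if not shared:
        raise ValueError("the two samples share no SNPs (disjoint universes)")
    return shared


@dataclass
class ConvergeThenClusterResult:
    reproducible_snps: set
    clusters: list
    clustered_snps: set
    gene_hits: pd.DataFrame
    criteria: ConvergenceCriteria


def converge_then_cluster(assoc_a, assoc_b, index: GenomeIndex,
                          criteria: ConvergenceCriteria = ConvergenceCriteria(3, 25_000),
                          *, rule: str = "count") -> ConvergeThenClusterResult:
    """Approach 1: intersect positives across samples, then cluster and assign genes.

    A SNP is *reproducibly positive* when nominally positive (p < alpha) in
    both samples; no agreement of effect direction is required.  Clusters are
    chained from the reproducible SNPs and genes reported when at least
    ``criteria.min_cluster_size`` clustered SNPs lie in the flanked interval.
    """
    _check_universe(assoc_a, assoc_b)
    repro = _positive_set(assoc_a, criteria.alpha) & _positive_set(assoc_b, criteria.alpha)
    clusters = cluster_positive_snps(repro, index, criteria)
    clustered = {s for c in clusters for s in c.member_snps}
    hits = assign_clusters_to_genes(clusters, index,
                                    min_support=criteria.min_cluster_size, rule=rule)
    if not hits.empty:
        hits.insert(1, "approach", 1)
    return ConvergeThenClusterResult(repro, clusters, clustered, hits, criteria)


@dataclass
class ClusterThenConvergeResult:
    clusters_a: list
    clusters_b: list
    clustered_snps_a: set
    clustered_snps_b: set
    gene_hits: pd.DataFrame
    convergent_snps: set
    criteria: ConvergenceCriteria


def cluster_then_converge(assoc_a, assoc_b, index: GenomeIndex,
                          criteria: ConvergenceCriteria = ConvergenceCriteria(4, 10_000),
                          *, rule: str = "count") -> ClusterThenConvergeResult:
    """Approach 2: cluster each sample's own positives, report genes hit by both.

    Each sample's nominal positives are chained independently; a gene is
    reported iff a qualifying cluster from *each* sample supports it.  The
    samples may tag the gene through entirely different SNPs.  ``convergent
    snps`` are the clustered SNPs (either sample) supporting convergent genes.
    """
    _check_universe(assoc_a, assoc_b)
    per_sample = []
    for assoc in (assoc_a, assoc_b):
        clusters = cluster_positive_snps(_positive_set(assoc, criteria.alpha), index, criteria)
        hits = assign_clusters_to_genes(clusters, index,
                                        min_support=criteria.min_cluster_size, rule=rule)
        per_sample.append((clusters, hits))
    (clusters_a, hits_a), (clusters_b, hits_b) = per_sample
    if hits_a.empty or hits_b.empty:
        genes = pd.DataFrame(
            columns=["gene_id", "approach", "chrom", "n_snps_a", "n_snps_b",
                     "snp_ids_a", "snp_ids_b"])
        convergent = set()
    else:
        merged = hits_a.merge(hits_b, on=["gene_id", "chrom"], suffixes=("_a", "_b"))
        genes = merged[["gene_id", "chrom", "n_snps_a", "n_snps_b",
                        "snp_ids_a", "snp_ids_b"]].copy()
        genes.insert(1, "approach", 2)
        convergent = set()
        for _, row in genes.iterrows():
            convergent.update(row["snp_ids_a"])
            convergent.update(row["snp_ids_b"])
    return ClusterThenConvergeResult(
        clusters_a, clusters_b,
        {s for c in clusters_a for s in c.member_snps},
        {s for c in clusters_b for s in c.member_snps},
        genes, convergent, criteria)


def criteria_grid_summary(assoc_a, assoc_b, index: GenomeIndex,
                          grid: list[ConvergenceCriteria] = TABLE_CRITERIA_GRID,
                          *, rule: str = "count") -> pd.DataFrame:
    """Summary table over the criteria grid, one row per (approach, criteria).

    Mirrors the published layout: clustered positive SNP counts per sample
    (approach 2), convergent SNP counts, gene counts, and each row's overlap
    with the primary approach-1 gene set (size 3, gap 25 kb).
    """
    rows = []
    primary: set | None = None
    for criteria in grid:
        r1 = converge_then_cluster(assoc_a, assoc_b, index, criteria, rule=rule)
        genes1 = set(r1.gene_hits["gene_id"]) if not r1.gene_hits.empty else set()
        if primary is None:
            primary = genes1 if (criteria.min_cluster_size, criteria.max_gap) == (3, 25_000) else None
        rows.append({
            "approach": 1, "min_cluster_size": criteria.min_cluster_size,
            "max_gap": criteria.max_gap,
            "clustered_snps_a": None, "clustered_snps_b": None,
            "convergent_snps": len(r1.clustered_snps),
            "n_genes": len(genes1), "genes": sorted(genes1),
        })
    for criteria in grid:
        r2 = cluster_then_converge(assoc_a, assoc_b, index, criteria, rule=rule)
        genes2 = set(r2.gene_hits["gene_id"]) if not r2.gene_hits.empty else set()
        rows.append({
            "approach": 2, "min_cluster_size": criteria.min_cluster_size,
            "max_gap": criteria.max_gap,
            "clustered_snps_a": len(r2.clustered_snps_a),
            "clustered_snps_b": len(r2.clustered_snps_b),
            "convergent_snps": len(r2.convergent_snps),
            "n_genes": len(genes2), "genes": sorted(genes2),
        })
    out = pd.DataFrame(rows)
    if primary is None:
        primary = set()
    out["overlap_with_primary"] = [len(set(g) & primary) for g in out["genes"]]
    return out
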