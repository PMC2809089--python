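import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from poolgwas import (ConvergenceCriteria, GenomeIndex, find_clusters,
                      assign_clusters_to_genes, cluster_positive_snps,
                      converge_then_cluster, cluster_then_converge,
                      criteria_grid_summary, TABLE_CRITERIA_GRID)
from conftest import brute_force_chains


class TestFindClusters:
    def test_three_snps_within_gap_form_one_cluster(self):
        out = find_clusters([100, 10_100, 20_100], ConvergenceCriteria(3, 25_000))
        assert len(out) == 1
        c = out[0]
        assert (c.start, c.end, c.size) == (100, 20_100, 3)

    def test_wide_gaps_yield_no_clusters(self):
        assert find_clusters([100, 30_000, 60_000], ConvergenceCriteria(3, 25_000)) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            find_clusters([5, 3, 9], ConvergenceCriteria(3, 10))
        with pytest.raises(ValueError):
            find_clusters([3, 3, 9], ConvergenceCriteria(3, 10))

    @given(st.sets(st.integers(1, 1_000_000), min_size=0, max_size=50),
           st.sampled_from([3, 4]), st.sampled_from([10_000, 25_000]))
    def test_matches_brute_force_chain_enumeration(self, positions, size, gap):
        positions = sorted(positions)
        got = find_clusters(positions, ConvergenceCriteria(size, gap))
        expected = brute_force_chains(positions, gap, size)
        assert [list(c.positions) for c in got] == expected

    @given(st.sets(st.integers(1, 500_000), min_size=5, max_size=60))
    def test_members_partition_clustered_positives(self, positions):
        positions = sorted(positions)
        crit = ConvergenceCriteria(3, 20_000)
        out = find_clusters(positions, crit)
        seen = [p for c in out for p in c.positions]
        assert len(seen) == len(set(seen))  # no SNP in two clusters
        for c in out:
            inside = [p for p in positions if c.start <= p <= c.end]
            assert inside == list(c.positions)


def _annotation(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _map_from_positions(chrom_positions):
    rows = []
    for chrom, positions in chrom_positions.items():
        for p in positions:
            rows.append({"snp_id": f"{chrom}:{p}", "chrom": chrom, "pos": p})
    return pd.DataFrame(rows)


class TestGeneAssignment:
    def test_flank_boundary_is_inclusive(self):
        ann = _annotation([("g", "chr1", 50_000, 60_000)])
        for snp_pos, expected in ((40_000, 1), (39_999, 0)):
            positions = [snp_pos, snp_pos + 5_000, snp_pos + 9_000]
            snp_map = _map_from_positions({"chr1": positions})
            index = GenomeIndex(snp_map, ann, flank=10_000)
            clusters = cluster_positive_snps(snp_map["snp_id"], index,
                                             ConvergenceCriteria(3, 25_000))
            hits = assign_clusters_to_genes(clusters, index, min_support=1, rule="any")
            inside = {s for h in hits.itertuples() for s in h.snp_ids}
            assert (f"chr1:{snp_pos}" in inside) == bool(expected)

    def test_exon_only_membership_excludes_introns(self):
        ann = _annotation([("g", "chr1", 1_000, 2_000)])
        exons = pd.DataFrame([("g", 1_000, 1_200), ("g", 1_900, 2_000)],
                             columns=["gene_id", "start", "end"])
        positions = [1_100, 1_150, 1_190, 1_500, 2_050]  # 3 exonic, intron, flank
        snp_map = _map_from_positions({"chr1": positions})
        crit = ConvergenceCriteria(3, 25_000)
        span_index = GenomeIndex(snp_map, ann, flank=100)
        exon_index = GenomeIndex(snp_map, ann, flank=100, exons=exons,
                                 exon_only=True)
        clusters = cluster_positive_snps(snp_map["snp_id"], span_index, crit)
        span_hits = assign_clusters_to_genes(clusters, span_index, min_support=3)
        exon_hits = assign_clusters_to_genes(clusters, exon_index, min_support=3)
        assert span_hits["n_snps"].tolist() == [5]
        assert exon_hits["n_snps"].tolist() == [4]  # intron SNP excluded
        assert "chr1:1500" not in exon_hits["snp_ids"].iloc[0]
        assert "chr1:2050" in exon_hits["snp_ids"].iloc[0]

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            n = 40
            positions = np.sort(rng.choice(400_000, n, replace=False) + 1)
            snp_map = _map_from_positions({"chr1": list(positions)})
            genes = []
            for g in range(6):
                start = int(rng.integers(1, 350_000))
                genes.append((f"g{g}", "chr1", start, start + int(rng.integers(5_000, 60_000))))
            ann = _annotation(genes)
            crit = ConvergenceCriteria(3, 25_000)
            index = GenomeIndex(snp_map, ann, flank=10_000)
            clusters = cluster_positive_snps(snp_map["snp_id"], index, crit)
            hits = assign_clusters_to_genes(clusters, index, min_support=3)
            got = dict(zip(hits["gene_id"], hits["n_snps"]))
            # oracle: plain scan over genes x clusters
            expected = {}
            for gid, _, start, end in genes:
                lo, hi = max(1, start - 10_000), end + 10_000
                supporting = set()
                for c in clusters:
                    members = [p for p in c.positions if lo <= p <= hi]
                    if len(members) >= 3:
                        supporting.update(f"chr1:{p}" for p in members)
                if supporting:
                    expected[gid] = len(supporting)
            assert got == expected


def _assoc(snp_map, positive_ids):
    pos = snp_map["snp_id"].isin(set(positive_ids))
    return pd.DataFrame({
        "snp_id": snp_map["snp_id"],
        "p_value": np.where(pos, 0.01, 0.5),
        "t_value": np.where(pos, 2.5, 0.1),
        "tested": True,
    })


class TestConvergence:
    def setup_method(self):
        # one gene holding a 6-SNP block, plus remote background SNPs
        block = [50_000 + 4_000 * i for i in range(6)]
        background = [300_000 + 40_000 * i for i in range(10)]
        self.snp_map = _map_from_positions({"chr1": block + background})
        self.block_ids = [f"chr1:{p}" for p in block]
        self.ann = _annotation([("target", "chr1", 45_000, 80_000)])
        self.index = GenomeIndex(self.snp_map, self.ann, flank=10_000)

    def test_shared_positives_identify_gene_in_both_approaches(self):
        a = _assoc(self.snp_map, self.block_ids)
        b = _assoc(self.snp_map, self.block_ids)
        r1 = converge_then_cluster(a, b, self.index, ConvergenceCriteria(3, 25_000))
        assert set(r1.reproducible_snps) == set(self.block_ids)
        assert r1.gene_hits["gene_id"].tolist() == ["target"]
        assert r1.gene_hits["n_snps"].tolist() == [6]
        r2 = cluster_then_converge(a, b, self.index, ConvergenceCriteria(4, 10_000))
        assert r2.gene_hits["gene_id"].tolist() == ["target"]
        assert r2.gene_hits[["n_snps_a", "n_snps_b"]].values.tolist() == [[6, 6]]

    def test_disjoint_positive_sets_give_no_reproducible_snps(self):
        a = _assoc(self.snp_map, self.block_ids[:3])
        b = _assoc(self.snp_map, ["chr1:300000"])
        r1 = converge_then_cluster(a, b, self.index)
        assert r1.reproducible_snps == set() and len(r1.gene_hits) == 0

    def test_single_sample_cluster_not_reported_by_approach2(self):
        a = _assoc(self.snp_map, self.block_ids)
        b = _assoc(self.snp_map, [])
        r2 = cluster_then_converge(a, b, self.index, ConvergenceCriteria(4, 10_000))
        assert len(r2.gene_hits) == 0

    def test_different_tagging_snps_found_by_approach2_only(self):
        # allelic heterogeneity: alternate SNPs positive per sample
        a = _assoc(self.snp_map, self.block_ids[0::2] + self.block_ids[1:2])
        b = _assoc(self.snp_map, self.block_ids[1::2] + self.block_ids[0:1])
        crit = ConvergenceCriteria(3, 25_000)
        r1 = converge_then_cluster(a, b, self.index, crit)
        r2 = cluster_then_converge(a, b, self.index, crit)
        assert len(r1.gene_hits) == 0  # intersection too small to cluster
        assert r2.gene_hits["gene_id"].tolist() == ["target"]

    def test_disjoint_universes_rejected(self):
        a = _assoc(self.snp_map, [])
        other = _map_from_positions({"chr9": [1, 2, 3]})
        b = _assoc(other, [])
        with pytest.raises(ValueError):
            converge_then_cluster(a, b, self.index)

    def test_end_to_end_matches_brute_force_recomputation(self, small_study, small_assoc):
        from poolgwas import nominal_positive_set

        index = GenomeIndex(small_study["snp_map"], small_study["annotation"])
        crit = ConvergenceCriteria(3, 25_000)
        r1 = converge_then_cluster(small_assoc["A"], small_assoc["B"], index, crit)
        planted = set(small_study["truth"].genes)
        got = set(r1.gene_hits["gene_id"]) if len(r1.gene_hits) else set()
        assert planted <= got
        # oracle: recompute the gene set with plain loops
        repro = (nominal_positive_set(small_assoc["A"], 0.05)
                 & nominal_positive_set(small_assoc["B"], 0.05))
        m = small_study["snp_map"]
        m = m[m["snp_id"].isin(repro)].sort_values(["chrom", "pos"])
        expected = set()
        for _, gene in small_study["annotation"].iterrows():
            lo, hi = max(1, gene["start"] - 10_000), gene["end"] + 10_000
            sub = m[m["chrom"] == gene["chrom"]]
            for chain in brute_force_chains(sub["pos"].tolist(), 25_000, 3):
                if sum(lo <= p <= hi for p in chain) >= 3:
                    expected.add(gene["gene_id"])
        assert got == expected


class TestGridInvariants:
    def test_criteria_nesting_and_approach_containment(self, small_study, small_assoc):
        index = GenomeIndex(small_study["snp_map"], small_study["annotation"])
        summary = criteria_grid_summary(small_assoc["A"], small_assoc["B"], index)
        genes = {(r.approach, r.min_cluster_size, r.max_gap): set(r.genes)
                 for r in summary.itertuples()}
        for ap in (1, 2):
            assert genes[(ap, 4, 10_000)] <= genes[(ap, 4, 25_000)] <= genes[(ap, 3, 25_000)]
            assert genes[(ap, 3, 10_000)] <= genes[(ap, 3, 25_000)]
            assert genes[(ap, 4, 10_000)] <= genes[(ap, 3, 10_000)]
        for crit in TABLE_CRITERIA_GRID:
            key = (crit.min_cluster_size, crit.max_gap)
            assert genes[(1, *key)] <= genes[(2, *key)]

    def test_output_independent_of_input_order(self, small_study, small_assoc):
        index = GenomeIndex(small_study["snp_map"], small_study["annotation"])
        shuffled_a = small_assoc["A"].sample(frac=1, random_state=0).reset_index(drop=True)
        shuffled_map = small_study["snp_map"].sample(frac=1, random_state=1)
        index2 = GenomeIndex(shuffled_map, small_study["annotation"])
        r = converge_then_cluster(small_assoc["A"], small_assoc["B"], index)
        r2 = converge_then_cluster(shuffled_a, small_assoc["B"], index2)
        assert r.reproducible_snps == r2.reproducible_snps
        assert r.gene_hits["gene_id"].tolist() == r2.gene_hits["gene_id"].tolist()
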