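import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolgwas import (ConvergenceCriteria, GenomeIndex, IntensityPanel,
                      mc_overlap_p, mc_cluster_p, mc_gene_convergence_p,
                      mc_gene_level_p, permutation_p,
                      reproducible_count_permutation, true_positive_fraction)
from poolgwas.empirical import _clustered_snp_count, _empirical
from poolgwas.synthetic import make_pool_design, simulate_pools, NoiseModel
from conftest import brute_force_chains


def mc_se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestMcOverlap:
    def test_zero_overlap_gives_p_one(self):
        e = mc_overlap_p(100, 10, 10, 0, n_trials=500, seed=1)
        assert e.p == 1.0

    @pytest.mark.parametrize("method,trials", [("hypergeom", 200_000), ("sets", 4_000)])
    def test_matches_exact_hypergeometric_tail(self, method, trials):
        # universe 20, subsets 10/10, overlap >= 6
        exact = float(stats.hypergeom(20, 10, 10).sf(5))
        e = mc_overlap_p(20, 10, 10, 6, n_trials=trials, seed=7, method=method)
        assert abs(e.p - exact) <= 3 * mc_se(exact, trials) + 1 / trials

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            mc_overlap_p(100, 10, 5, 6, n_trials=10)

    def test_reproducible_given_seed(self):
        a = mc_overlap_p(1000, 100, 100, 15, n_trials=2_000, seed=5)
        b = mc_overlap_p(1000, 100, 100, 15, n_trials=2_000, seed=5)
        assert (a.p, a.n_exceed) == (b.p, b.n_exceed)

    def test_seed_invariance_within_monte_carlo_error(self):
        target = float(stats.hypergeom(200, 40, 40).sf(11))
        runs = [mc_overlap_p(200, 40, 40, 12, n_trials=50_000, seed=s).p
                for s in (1, 2)]
        assert abs(runs[0] - runs[1]) <= 6 * mc_se(target, 50_000)


def _index_from_positions(positions, genes=None, flank=0):
    snp_map = pd.DataFrame({
        "snp_id": [f"s{p}" for p in positions], "chrom": "chr1",
        "pos": list(positions)})
    ann = None
    if genes is not None:
        ann = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])
    return GenomeIndex(snp_map, ann, flank=flank)


class TestMcCluster:
    def test_observed_zero_gives_p_one(self):
        index = _index_from_positions(range(100, 4_100, 400))
        e = mc_cluster_p(index, 3, ConvergenceCriteria(3, 100), 0, n_trials=200, seed=1)
        assert e.p == 1.0

    def test_matches_exhaustive_enumeration(self):
        # 20 SNPs, choose 4 pseudopositives: C(20,4)=4845 enumerable draws
        rng = np.random.default_rng(9)
        positions = np.sort(rng.choice(60_000, 20, replace=False) + 1)
        crit = ConvergenceCriteria(3, 5_000)
        index = _index_from_positions(positions)
        observed = 3
        count = total = 0
        for combo in itertools.combinations(range(20), 4):
            chains = brute_force_chains([int(positions[i]) for i in combo],
                                        crit.max_gap, crit.min_cluster_size)
            stat = sum(len(c) for c in chains)
            count += stat >= observed
            total += 1
        exact = count / total
        trials = 20_000
        e = mc_cluster_p(index, 4, crit, observed, n_trials=trials, seed=3)
        assert abs(e.p - exact) <= 3 * mc_se(exact, trials) + 1 / trials

    def test_fully_clustered_map_is_extreme(self):
        # every SNP adjacent: any draw of 5 clusters completely, so a
        # 5-clustered observation is matched by every trial
        index = _index_from_positions(range(1_000, 31_000, 1_000))
        crit = ConvergenceCriteria(3, 25_000)
        e = mc_cluster_p(index, 5, crit, 5, n_trials=300, seed=2)
        assert e.p == 1.0
        e6 = mc_cluster_p(index, 5, crit, 6, n_trials=300, seed=2)
        assert e6.p == pytest.approx(1 / 301)


class TestMcGeneConvergence:
    def make_index(self):
        rng = np.random.default_rng(21)
        positions = np.sort(rng.choice(500_000, 500, replace=False) + 1)
        genes = [(f"g{i}", "chr1", 1 + i * 50_000, 1 + i * 50_000 + 20_000)
                 for i in range(10)]
        return _index_from_positions(positions, genes, flank=10_000)

    def test_observed_zero_gives_p_one(self):
        index = self.make_index()
        e = mc_gene_convergence_p(index, 30, 30, ConvergenceCriteria(3, 25_000),
                                  0, n_trials=100, seed=4)
        assert e.p == 1.0

    def test_saturated_pseudopositives_hit_every_reachable_gene(self):
        index = self.make_index()
        n = len(index.snp_ids)
        e = mc_gene_convergence_p(index, n, n, ConvergenceCriteria(3, 25_000),
                                  0, n_trials=5, seed=4)
        assert e.null.sd == 0  # every trial identical: the full map
        assert e.p == 1.0

    def test_self_consistent_across_seeds_and_trial_counts(self):
        index = self.make_index()
        crit = ConvergenceCriteria(3, 25_000)
        small = mc_gene_convergence_p(index, 60, 60, crit, 3, n_trials=400, seed=1)
        big = mc_gene_convergence_p(index, 60, 60, crit, 3, n_trials=4_000, seed=99)
        se = mc_se(max(big.p, 1 / 401), 400) + mc_se(max(big.p, 1 / 4001), 4_000)
        assert abs(small.p - big.p) <= 3 * se + 1 / 400


class TestMcGeneLevel:
    def make_toy(self):
        # dense tiny genome: genes of a few hundred bp
        positions = list(range(10, 2_000, 25))
        genes = [("g0", "chr1", 100, 400), ("g1", "chr1", 600, 1_000),
                 ("g2", "chr1", 1_200, 1_500), ("g3", "chr1", 1_600, 1_900)]
        return _index_from_positions(positions, genes, flank=50)

    def test_gene_holding_all_positives_is_extreme(self):
        index = self.make_toy()
        in_gene = [s for s, p in zip(index.snp_ids, index.positions)
                   if 100 <= p <= 400]
        e = mc_gene_level_p("g0", index, in_gene,
                            criteria=ConvergenceCriteria(3, 100), n_trials=400, seed=8)
        assert e.observed_stat >= 3
        assert e.p < 0.2  # only same-length placements covering g0 match

    def test_no_observed_features_gives_p_one(self):
        index = self.make_toy()
        e = mc_gene_level_p("g0", index, [], criteria=ConvergenceCriteria(3, 100),
                            n_trials=100, seed=8)
        assert e.observed_stat == 0 and e.p == 1.0

    def test_matches_exhaustive_placement_enumeration(self):
        index = self.make_toy()
        positives = [s for s, p in zip(index.snp_ids, index.positions)
                     if 100 <= p <= 400 or 700 <= p <= 800]
        crit = ConvergenceCriteria(3, 100)
        e = mc_gene_level_p("g2", index, positives, criteria=crit,
                            n_trials=20_000, seed=5)
        # oracle: enumerate every placement of the flanked-g2-length segment
        seg_len = (1_500 + 50) - (1_200 - 50) + 1
        pos_of = dict(zip(index.snp_ids, index.positions))
        ppos = sorted(pos_of[s] for s in positives)
        count = total = 0
        for _, start, end in [("g0", 50, 450), ("g1", 550, 1_050),
                              ("g2", 1_150, 1_550), ("g3", 1_550, 1_950)]:
            for s in range(start, end - seg_len + 2):
                inside = [p for p in ppos if s <= p <= s + seg_len - 1]
                stat = sum(len(c) for c in brute_force_chains(inside, 100, 3))
                count += stat >= e.observed_stat
                total += 1
        exact = count / total
        assert total > 0
        assert abs(e.p - exact) <= 3 * mc_se(exact, 20_000) + 1 / 20_000

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            mc_gene_level_p("nope", self.make_toy(), [])


def _noisy_panel(seed, n_snps=400, n_case=4, n_ctrl=4, effect_ids=(), sample="A"):
    design = make_pool_design(sample, n_case, n_ctrl)
    snp_map = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n_snps)],
                            "chrom": "chr1", "pos": np.arange(n_snps) * 500 + 1})
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 0.7, n_snps)
    effects = {s: 0.25 for s in effect_ids}
    return simulate_pools(design, snp_map, base, effects, NoiseModel(), seed=seed)


class TestPermutation:
    def test_label_invariant_statistic_gives_p_one(self):
        pa = _noisy_panel(1)
        pb = _noisy_panel(2, sample="B")
        e = permutation_p(pa, pb, statistic=lambda *a: 7.0, n_trials=50, seed=3)
        assert e.p == 1.0

    def test_strong_planted_effects_are_extreme(self):
        effects = [f"s{i}" for i in range(50)]
        pa = _noisy_panel(3, n_case=6, n_ctrl=6, effect_ids=effects)
        pb = _noisy_panel(4, n_case=6, n_ctrl=6, effect_ids=effects, sample="B")
        e = reproducible_count_permutation(pa, pb, n_trials=400, seed=5)
        assert e.p == pytest.approx(1 / 401)

    def test_exact_enumeration_when_few_labelings(self):
        pa = _noisy_panel(5, n_case=2, n_ctrl=2)
        pb = _noisy_panel(6, n_case=2, n_ctrl=2, sample="B")
        e = permutation_p(pa, pb, n_trials=10_000, seed=1)
        assert e.method == "exact"
        assert e.n_trials == 36  # C(4,2)^2 distinct labelings
        assert e.p >= 1 / 36

    def test_fast_path_agrees_with_generic_path(self):
        pa = _noisy_panel(7, n_case=5, n_ctrl=4)
        pb = _noisy_panel(8, n_case=5, n_ctrl=4, sample="B")
        slow = permutation_p(pa, pb, n_trials=200, seed=11)
        fast = reproducible_count_permutation(pa, pb, n_trials=200, seed=11)
        assert slow.observed_stat == fast.observed_stat
        assert abs(slow.null.mean - fast.null.mean) < 3 * (slow.null.sd + 0.2)

    def test_null_permutation_p_is_calibrated(self):
        # pure-null panels: the permutation p should be ~uniform over runs
        ps = []
        for run in range(80):
            pa = _noisy_panel(100 + run, n_snps=5_000, n_case=6, n_ctrl=6)
            pb = _noisy_panel(900 + run, n_snps=5_000, n_case=6, n_ctrl=6, sample="B")
            ps.append(reproducible_count_permutation(pa, pb, n_trials=150,
                                                     seed=run).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEmpiricalConventions:
    def test_p_monotone_in_observed_and_bounded(self):
        null = np.arange(100)
        ps = [_empirical(obs, null, 0).p for obs in (0, 10, 50, 99, 200)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(1 / 101 <= p <= 1 for p in ps)
        assert ps[0] == 1.0 and ps[-1] == pytest.approx(1 / 101)

    def test_ties_count_as_exceedances(self):
        e = _empirical(5, [5, 5, 1], 0)
        assert e.n_exceed == 2

    def test_true_positive_fraction_limits(self):
        from poolgwas.empirical import NullSummary

        assert true_positive_fraction(100, NullSummary(0, 0, {})) == 1.0
        assert true_positive_fraction(100, NullSummary(100, 0, {})) == 0.0
        assert true_positive_fraction(341, NullSummary(190.0, 5, {})) == pytest.approx(
            (341 - 190) / 341)
        with pytest.raises(ValueError):
            true_positive_fraction(0, NullSummary(1, 0, {}))
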