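"""Power analysis and controls for stratification and assay noise.

Power: two-sided two-sample t at alpha 0.05 for 5% and 10% allele-frequency
differences (converted to the arctan scale at a mid-range frequency) under
both pool designs.  Stratification control: overlap of the approach-1
clustered SNPs with the SNPs showing the largest between-population
frequency differences, against the hypergeometric expectation; plus PCA of
the pooled matrix with phenotype-separation permutation p-values.  Noise
control: same overlap test against the noisiest-assay SNPs.
"""

import numpy as np
import pandas as pd

import poolgwas as pg
from common import PRIMARY_1, STUDY_SEED, load_study, save
from poolgwas.synthetic import DEFAULT_REPLICATE_SD


def main():
    snp_map, annotation, truth, panels, freqs = load_study()
    index = pg.GenomeIndex(snp_map, annotation)
    aa = pg.associate_panel(panels["A"])
    ab = pg.associate_panel(panels["B"])

    # arctan-scale effect and pool SD at a representative frequency f=0.4
    f = 0.4
    g = lambda x: float(np.arctan2(x, 1 - x))
    slope = 1.0 / ((1 - f) ** 2 + f**2)
    sd = float(np.sqrt(slope**2 * f * (1 - f) / 40 + DEFAULT_REPLICATE_SD**2 / 3))
    deltas = [g(f + d) - g(f) for d in (0.05, 0.10)]
    table = pg.power_table(deltas, sd, [(20, 14), (35, 12)])
    table.insert(0, "freq_delta", np.repeat([0.05, 0.10], 2))
    save(table, "power_table.tsv")
    print("power at pool SD %.3f (arctan scale):" % sd)
    print(table.to_string(index=False))

    # stratification: top-10% between-population frequency differences
    universe = set(snp_map["snp_id"])
    diff = np.abs(freqs["A"] - freqs["B"])
    cut = np.quantile(diff, 0.90)
    suspect_strat = set(snp_map["snp_id"].to_numpy()[diff >= cut])
    r1 = pg.converge_then_cluster(aa, ab, index, PRIMARY_1)
    hits = set(r1.clustered_snps)
    rows = []
    for label, suspects in (("ethnicity_differentiated", suspect_strat),):
        obs, exp, p = pg.overlap_control(hits, suspects, universe)
        rows.append({"control": label, "hits": len(hits),
                     "suspects": len(suspects), "observed": obs,
                     "expected": round(exp, 1), "p": p})
        print(f"{label}: {obs} of {len(hits)} clustered SNPs overlap "
              f"(expected {exp:.1f} by chance, p={p:.3f})")

    # assay noise: top-10% replicate variance, pooled over samples
    rep_var = np.nanmean(np.concatenate(
        [np.nanvar(p.values, axis=1, ddof=1) for p in panels.values()]), axis=0)
    cut = np.quantile(rep_var, 0.90)
    noisy = set(snp_map["snp_id"].to_numpy()[rep_var >= cut])
    obs, exp, p = pg.overlap_control(hits, noisy, universe)
    rows.append({"control": "noisiest_assays", "hits": len(hits),
                 "suspects": len(noisy), "observed": obs,
                 "expected": round(exp, 1), "p": p})
    print(f"noisiest_assays: {obs} of {len(hits)} clustered SNPs overlap "
          f"(expected {exp:.1f} by chance, p={p:.3f})")
    save(pd.DataFrame(rows), "controls_overlap.tsv")

    # PCA of all pools together: population split should dominate PC1
    sub = np.sort(np.random.default_rng(STUDY_SEED).choice(
        len(snp_map), 8_000, replace=False))
    mats, phenos, samples = [], [], []
    for name, panel in panels.items():
        mats.append(panel.pool_means()[:, sub])
        phenos.extend(panel.design["phenotype"])
        samples.extend(panel.design["sample"])
    out = pg.pca_separation(np.vstack(mats), np.array(phenos),
                            n_trials=2_000, seed=STUDY_SEED)
    pc1 = out.scores[:, 0]
    is_a = np.array(samples) == "A"
    sep = (pc1[is_a].max() < pc1[~is_a].min()) or (pc1[is_a].min() > pc1[~is_a].max())
    print(f"PC1 explains {out.variance_fraction[0]:.1%} of variance and "
          f"{'cleanly separates' if sep else 'does not separate'} the two "
          f"populations; phenotype-separation p on PC1-5: "
          + ", ".join(f"{p:.3f}" for p in out.separation_p[:5]))
    save(pd.DataFrame({"component": np.arange(1, 6),
                       "variance_fraction": out.variance_fraction[:5],
                       "phenotype_separation_p": out.separation_p[:5]}),
         "controls_pca.tsv")


if __name__ == "__main__":
    main()
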