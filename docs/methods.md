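# Methods

## Measurement model

The pooled assay is summarized per (pool, replicate array, SNP) by
`theta = arctan(A/B)`, the arctangent of the ratio of mean perfect-match
probe intensities for the two alleles.  Probe intensities are averaged
*before* the arctangent (mean-then-arctan); `theta` lies in `[0, pi/2]`,
with `A = 0 -> 0` and `B = 0 -> pi/2` as fixed-allele boundaries and both
intensities zero treated as an undefined measure.  Under proportional
hybridization `theta` is a monotone proxy for the pool allele frequency
`f` via `arctan(f/(1-f))`; the package never attempts to invert it to an
absolute frequency, because every downstream statistic only needs
case/control *differences* on a common monotone scale.

## Association test

Replicates are collapsed to pool means and a two-sided Welch (unequal
variance) t test compares case and control pools, with pools as the
experimental units.  Welch was chosen because the two phenotype groups have
quite different pool counts (e.g. 35 vs 12), which makes equal-variance
pooling fragile; the Satterthwaite degrees of freedom handle this without
assuming balance.  The case/control ratio of mean arctan values is carried
as a descriptive column only.  Degenerate SNPs (zero variance in both
groups) report `t = 0, p = 1` at equal means, or the smallest positive
double with a `degenerate` flag at unequal means, rather than propagating
NaNs.  A SNP missing in any pool of a sample is dropped from that sample's
test and counted in the log.  Nominal positivity is strict `p < alpha`
(default 0.05), so ties at exactly alpha are excluded.

Sex-chromosome SNPs are removed before analysis (so male and female
subjects can be pooled) along with SNPs lacking a defined autosomal
position, which cannot enter distance-based clustering.

## Clustering and gene assignment

A cluster is a maximal single-linkage chain: consecutive positive SNPs at
most `max_gap` apart, reported when the chain has at least
`min_cluster_size` members.  Chain semantics (rather than diameter-bounded
clusters) were chosen because maximal diameter-bounded clusters are not
unique, while chaining is deterministic and order-independent; the
qualification grid is sizes {3, 4} x gaps {25 kb, 10 kb}.

Genes are intervals extended by symmetric 10 kb flanks, 1-based inclusive
internally (BED input is converted on read).  The full gene span is used —
introns included — because intronic SNPs in linkage disequilibrium with the
gene's haplotypes would otherwise be discarded; a cluster supports a gene
when at least `min_cluster_size` of its members fall inside the flanked
interval (boundaries inclusive).  This is the stricter of two defensible
readings ("enough clustered SNPs inside" vs "any overlap with a qualifying
cluster"); the looser rule is available as `rule="any"`.  A cluster
straddling two genes' flanked intervals supports both.

Neither convergence analysis imposes any cross-sample agreement of effect
direction: linkage phase between a tag SNP and a causal variant can differ
between populations, so requiring the same sign would discard true
convergent signals.

These choices make two containments provable, and the tests assert both on
random data: stricter criteria always give gene sets nested inside looser
ones, and every converge-then-cluster gene is also found by
cluster-then-converge at equal criteria.

## Empirical significance

All significance is resampling-based; there are no asymptotic cluster-scan
p-values.  The empirical p-value is `(x + 1)/(n + 1)` with x the number of
null trials whose statistic matched or exceeded the observed value ("ties
count").  The add-one form keeps p positive when no trial reaches the
observed statistic — 0 of 100,000 trials reports 1/100,001, just under
1e-5 — and is the standard bias-safe convention for Monte Carlo tests.

* **Overlap null** — the chance intersection of two random positive sets is
  Hypergeometric(N, n_a, n_b); trials draw from it directly (an explicit
  two-subset sampling mode exists for validation and is checked against the
  closed-form tail).
* **Monte Carlo I** (clustering) — pseudopositive SNPs are sampled without
  replacement *from the real map*, preserving its spacing structure; no
  uniform-position null is ever used, since SNP density varies along the
  genome.  The statistic is the number of pseudopositives in qualifying
  clusters.
* **Monte Carlo II** (gene convergence) — independent pseudopositive sets
  per sample, full cluster-then-converge run, convergent-gene count.  Trial
  set sizes default to each sample's raw nominal-positive count (mirroring
  Monte Carlo I); matching the clustered-positive counts instead is a
  config toggle.  The null mean feeds the true-gene-fraction estimate
  `(observed - null_mean)/observed`, clamped to [0, 1].
* **Monte Carlo III** (per gene) — random segments of the same length as
  the gene's flanked interval, placed uniformly over all positions wholly
  inside some annotated gene's flanked interval.  "Same features" is not
  uniquely determined, so both statistics are implemented: the clustered
  positive-SNP count in the segment (default for one positive set) and the
  indicator that both samples contribute a qualifying cluster (default for
  two sets).
* **Permutation** — case/control labels are shuffled across pools within
  each sample independently; pools are the permutation unit because the
  data exist only post-pooling.  Per-sample case pool counts are preserved
  (label shuffle, not Bernoulli relabeling).  When fewer distinct labelings
  exist than requested trials, the test enumerates them exhaustively and
  reports the exact p.  The default statistic, the reproducible-SNP count,
  runs through a batched matrix-product path: per permutation chunk, group
  sums and sums of squares come from one indicator-matrix product each, and
  the Welch decision `|t| > t_crit(df)` uses a 4096-point critical-value
  interpolation over the narrow attainable df range instead of a
  per-element CDF call.  The generic path accepts any statistic callable
  and is tested to agree with the fast path.

Monte Carlo standard errors for oracle comparisons are `sqrt(p(1-p)/n)`;
resampling functions are bit-reproducible given (seed, trials).

## Power and controls

Power uses the noncentral t distribution of the pooled-variance two-sample
test (`df = n1 + n2 - 2`, ncp `delta / (sd sqrt(1/n1 + 1/n2))`), evaluated
on the arctan scale: an allele-frequency difference is converted through
the local slope of `arctan(f/(1-f))` and the per-pool SD combines binomial
pool composition with replicate noise.  The per-pool sigma is therefore an
explicit input, not a constant of the method — published pooled-study power
figures depend on the sigma convention fed to the calculator, which is why
the power table reports sigma alongside every entry.

Stratification and noise controls compare a hit set's overlap with suspect
SNPs (top-decile between-population frequency differences, or top-decile
replicate variance; the decile is a parameter) against the hypergeometric
expectation `|hit||suspect|/|universe|`, with a two-sided exact p summing
all outcomes no more probable than the observed.  Pool-level PCA centers
SNP columns, takes the SVD with a deterministic sign convention (results
are invariant to pool row order), and attaches a label-permutation p to the
absolute difference of phenotype-group mean scores per component.

## Synthetic data generator

The generator emulates exactly the structure the statistics consume:

* **Map and genes** — uniform SNP positions within equal-length
  chromosomes at the real panel's density (defaults: 50,000 SNPs over 22 x
  7.5 Mb, ~1 SNP/3.3 kb, standing in for the 870k panel; counts scale
  linearly), with non-overlapping Gamma-length genes.
* **Frequencies** — a symmetric Beta(0.149, 0.149) spectrum mapped to
  [0.10, 0.90].  The U shape is deliberate: with binomial sampling of 40
  chromosomes per pool, the across-pool SD of the arctan measure depends
  strongly on frequency, and only a spectrum weighted toward the extremes
  reproduces the pooled assay's observed across-pool SEM of ~0.02 over ~20
  pools (a uniform spectrum gives ~0.027).  The shape parameter solves the
  closed-form variance integral for that target; the range keeps boundary
  clipping of the noisy measure rare.
* **Noise** — per-array Gaussian noise with SD `0.03*sqrt(3)` on the
  arctan scale, so the SEM of the 3-replicate mean is 0.03; values are
  clipped to `[0, pi/2]`.  QC SEMs are aggregated across SNPs as
  RMS (`sqrt(mean variance)/sqrt(n)`), the convention under which these
  targets are reproduced unbiasedly.
* **Effects** — each planted locus is a run of 6 consecutive SNPs spanning
  <= 25 kb inside one gene, all shifted together by the effect size (0.10
  by default) in case pools: perfect within-block LD, the simplest
  structure that makes true effects span several nearby SNPs.  A
  `tagging="disjoint"` mode splits each block's SNPs alternately between
  the samples, the allelic-heterogeneity fixture that cluster-then-converge
  detects and the intersection analysis misses.  Effect-locus base
  frequencies are drawn mid-range (0.20-0.60) and shared between the two
  populations (common-allele assumption), keeping shifted frequencies in
  bounds.
* **Validation design** — 81 individuals with Hardy-Weinberg genotypes
  pooled into sets of 2, 5 and 15; "expected" is the pool's true allele
  frequency on the arctan scale, "observed" the noisy pooled measure, and
  the report correlates them per SNP on SNPs with >= 10% expected-frequency
  spread.

All randomness flows from one master seed through named substreams, so
every artifact is exactly reproducible.

## What the synthetic study does and does not show

Passing the recovery and calibration tests shows the pipeline's logic,
calibration and nulls behave as designed *under the generator's
assumptions*: exchangeable pools, frequency-independent Gaussian replicate
noise, perfect within-block LD, no real population substructure within a
sample, and no batch effects.  Real pooled data violate several of these
(LD decays continuously, noise is probe- and intensity-dependent, pools
can carry construction artifacts), so recovery rates here bound what the
design can do, not what any particular dataset will yield.  One visible
artifact: because planted loci sit at mid-range frequencies while the
background spectrum is U-shaped, effect SNPs have above-average
arctan-scale variance, so the "noisiest assays" control shows an
enrichment in synthetic hits that has no analogue in the real-data logic
of that control.

## Numerical choices and degenerate inputs

Unsorted or duplicated positions are an error in the clustering layer, not
silently fixed.  Interval boundaries are inclusive on both sides after
flanking; flanks clip at position 1.  Empirical p computations use `>=` for
exceedance.  Constant matrices are rejected by PCA; a single replicate
array makes the replicate SEM undefined and is rejected by QC; an array
whose mean offset from its pool's other replicates exceeds 3x the panel's
RMS replicate SD is flagged at WARN.  Seeds are small integers; derived
stream keys stay below 2^31.

## Problem sizes

Default analyses run at 50,000 SNPs (the acceptance checks use 20,000 for
the panel-level targets), 100,000 trials for closed-form-equivalent
overlap nulls, 10,000 permutations, and hundreds of trials for the
cluster-resampling nulls whose statistics are far from the observed values;
these sizes were chosen so the full analysis and test suite run on a
laptop-class single core in minutes while keeping every Monte Carlo
comparison at least three standard errors wide of its decision boundary.

## Known limitations

* No probe-level physics: the generator plants effects on the arctan scale
  through a frequency shift, not through intensity ratios, so assays whose
  A/B response is non-proportional are outside the model.
* Distance is the only proximity notion; no LD estimation from reference
  panels is attempted.
* The exact published cluster counts at full scale depend on the original
  870k-SNP intensity data and are not reproducible from synthetic inputs;
  the desk-scale checks target the claims that are (null overlap rate,
  type-I calibration, permutation extremity).
* Exon-only gene membership (support counted only from exons plus the
  flanking windows) is implemented behind the `exon_only` toggle, but the
  synthetic generator does not model exon structure, so that mode is only
  exercised on hand-built annotations.
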