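# Methods

This note documents the models, estimators, numerical choices and known
limitations of `svpopgen`. It is written for a reader who wants to know
exactly what each number produced by the package means and what the test
suite does and does not demonstrate.

## The synthetic-data generator

`simdata.simulate_dataset` emulates the statistical structure of a
reduced-representation SNP survey of a high-gene-flow marine fish:
many collections (sites) nested in a few management areas, weak background
differentiation, and one or two small genomic regions segregating as two
divergent non-recombining haplotypes.

**Background loci.** Each locus draws an ancestral allele frequency
uniformly on [`maf_min_ancestral`, 1 − `maf_min_ancestral`] (default 0.05).
Per-collection frequencies follow the Balding–Nichols model: a Beta
distribution with mean p and variance p(1−p)·F, where F =
`fst_background` (default 0.002). Genotypes are Binomial(2, p_collection).
This is the minimal standard model with a single differentiation knob; it
makes no attempt to model isolation by distance, site frequency spectra of
real RAD data (the real survey's mean H_t of ~0.11 implies a much more
skewed spectrum than the uniform draw), or linked selection.

**SV blocks.** A block has `n_sv_loci` loci (default 13) on two haplotype
backgrounds A and B. `n_fixed_diff` of them (default 11) are fixed
differences (frequency 0 on A, 1 on B); the rest are intermediate
(defaults 0.15 on A, 0.85 on B), mirroring a block where most loci are at
or near fixation between arrangements. Each individual draws two haplotype
labels i.i.d. Bernoulli(q_collection) — so karyotypes AA/AB/BB are in
Hardy–Weinberg proportions within collections by construction — and each
haplotype copy independently swaps background at each locus with
probability `leakage_eps` (default 0.11). Leakage is the generator's
single stand-in for everything that makes real block LD imperfect
(gene conversion, double crossovers, genotyping error). An optional
`hwe_f` knob injects inbreeding-style karyotype disequilibrium
(P(AB) = 2q(1−q)(1−F)) for power studies of the karyotype HWE test.

**Calibration of leakage.** With independent per-locus leakage the
genotype r² between two fixed-difference loci is governed by a = 1 − 2ε;
ε = 0.11 reproduces a median within-block r² of ≈ 0.29 at the default
sample sizes, the level the analysis is designed around. Measured over
seeds: ε = 0.11 → median r² 0.294; 0.10 → 0.331; 0.09 → 0.372.

**A consequence worth knowing.** Pairwise block r² and the tightness of the
three PC1 clusters are two views of the same quantity. Writing c_j for the
correlation between locus j's allelic state and the haplotype label,
r²_jk = c_j²c_k², while the PC1 score is essentially the average of the 13
per-locus signals, with independent residuals. At median r² ≈ 0.29 the
implied truth-label silhouette of the three karyotype clusters on PC1 is
≈ 0.77–0.79; pushing silhouette above 0.8 requires median r² ≳ 0.37.
Correlated (recombination-tract-style) noise would only lower the
silhouette at fixed r². The package keeps the generator at the
r²-calibrated ε = 0.11 and reports the silhouette it actually achieves
(~0.78); a verification bound demanding both median r² ≈ 0.29 and
silhouette ≥ 0.8 is unsatisfiable in this model family, and the
corresponding check is expected to read ~0.78.

**Environment and connectivity.** `simulate_env_table` produces four site
covariates (T_ZMAX, T_SBT, D_ZMAX, C_ZMAX) with a mild latitudinal trend
plus noise. When an effect is programmed, the chosen covariate is derived
deterministically from the haplotype frequency via the stated link
logit(q) = intercept + slope·z (z the standardized covariate), i.e. the
generator inverts the link rather than re-drawing q. `simulate_connectivity`
builds a directional transport matrix with probability decaying
exponentially in great-circle distance (default e-folding 150 km),
multiplicative lognormal asymmetric noise, and rows scaled to a retention
of 0.8 (the remainder is larval loss).

## Filtering

`geno_io.apply_filters` applies, in order: locus call rate ≥ 0.80; observed
heterozygosity ≤ 0.80 (a paralog-collapse proxy); one SNP per tag when tag
metadata exists (no-op for plain VCF); MAF > 0.01 on non-missing calls;
individual missingness ≤ 0.10; and an exact Hardy–Weinberg test per locus
per collection (Levene's conditional distribution, two-sided by
probability ordering, no mid-p), removing a locus only when it is
significant in *every* collection after a within-collection Bonferroni
correction over loci. MAF is computed before individual removal because
the individual filter is listed after the locus filters; the filter report
records every rule's removals so the order is auditable. Missing dosages
are a sentinel value throughout; no statistic silently zero-fills.

## LD estimation and network analysis

r² uses maximum-likelihood haplotype frequencies from the standard
two-locus EM over the double-heterozygote phase ambiguity (tolerance 1e-8
on frequency change, max 1000 iterations; pairs with missing genotypes
dropped pairwise; a composite Burrows estimator is available via
`method="composite"`). The all-pairs matrix is computed by a vectorized
batch EM over joint genotype count tables, so a 2,500-locus panel
(~3.2 M pairs) is feasible; a `max_pairs` budget guards against accidental
huge inputs.

The network sweep lowers a threshold t from 1.0 to 0.0 in steps of 0.01;
pairs with r² ≥ t are edges, connected components are clusters, and
mergers are recorded into a tree (all merges at one step form a single
multi-way merge). For a cluster C merging into parent P,

λ(C) = (median r² among C's member pairs − median r² of P's boundary
pairs) × |C|,

where boundary pairs are P's member pairs with at least one locus outside
C. λ therefore spikes exactly when a tight block dissolves into the
genomic background. Outliers are clusters with |E| ≥ e_min edges (member
pairs with r² at or above the cluster's formation threshold; e_min
defaults to 1% of the panel, rounded up) whose λ exceeds
median(λ) + φ·MAD(λ) (MAD scale 1.4826, φ default 4) over all scored
merger events — the merger noise of the whole panel is the reference
distribution, because at small panel sizes the candidate clusters alone
are dominated by the focal block's own growth ladder. Since single linkage
records every growth step of a block, nested outliers along one ancestry
chain describe the same block; each chain is resolved to its
maximal-λ cluster, and members attached through a single weak edge
(median r² to the rest below a third of the cluster median — block members
sit at the block level, chained strays at background level, roughly an
order of magnitude apart) are pruned. Degenerate inputs (all r² equal,
zero MAD) return no outliers with a warning.

## PCA, cluster discovery, outlier scan

PCA mean-imputes missing dosages (the only place imputation happens),
centers columns, applies no variance scaling, and fixes each component's
sign by making its largest-magnitude loading positive. The number of PC1
clusters is chosen by the BIC of a one-dimensional Gaussian mixture; a
hard-assignment WSS-based BIC (n·ln(WSS/n) + k·ln n) was rejected because
in low dimensions splitting one true Gaussian cluster shrinks WSS by ~35%,
which beats the k·ln n penalty at any realistic n, so that criterion
monotonically overfits. Labels come from k-means (20 restarts) at the
chosen k, renumbered by ascending cluster mean PC1. The locus outlier scan
regresses each (imputed, centered) locus on the leading K PC score
vectors, takes a robust Mahalanobis distance of the z-score vectors
(median/MAD for K = 1, minimum covariance determinant otherwise), rescales
by a genomic inflation factor (median distance over the χ²_K median), and
flags Bonferroni-adjusted upper-tail p < 1%. The ancestry proxy is min-max
rescaled PC1 — with two divergent haplotype backgrounds it is nearly
collinear with the derived-haplotype dosage (correlation ≥ 0.95 against
simulation truth), standing in for a model-based two-lineage admixture Q.

## Karyotype statistics

Karyotype = PC1 cluster over the SOC loci (not per-locus voting), robust
to the non-fixed loci; calling requires exactly three clusters and flags
the labelling if the middle cluster does not have the highest mean
heterozygosity. Orientation (which homokaryotype is "B") follows PC1 and
is arbitrary; accuracy against simulation truth is therefore evaluated up
to the A↔B flip. The karyotype HWE test is the uncorrected χ² with 1 df
against the 95% point (3.84): with q̂ = (n_AB + 2n_BB)/2n, expected counts
(n(1−q̂)², 2nq̂(1−q̂), nq̂²); monomorphic samples pass with χ² = 0. The
area-level test pools collections within an area (a Wahlund caveat: pooling
can create heterozygote deficits even when every collection is in HWE).

## Weir–Cockerham θ, diversity, AMOVA

θ follows the 1984 variance components a, b, c for diploids with unequal
sample sizes; multi-locus θ is the ratio of sums; negative per-locus
estimates are retained; undefined loci are skipped. Permutation p-values
use the add-one estimator (1 + #{θ* ≥ θ}) / (n_perm + 1) with individual
labels permuted within each pair. Diversity follows Nei & Chesser's
sample-size-corrected Hs and Ht (harmonic-mean ñ per locus) with
Dst′ = np/(np−1)·Dst, Ht′ = Hs + Dst′, and F_ST′ = Dst′/Ht′; overall Ho,
Hs, Ht are per-locus means and overall fixation indices are ratios of
mean components over polymorphic loci. These formulas are the package's
committed definitions and the tests check them against scalar evaluations
of the same published expressions.

AMOVA expands each individual to two 0/1 allele copies per locus;
per-locus mismatch distances make the arbitrary phase assignment of
heterozygotes irrelevant to every quantity that enters the partition
(unit-tested). Sums of squares decompose over four levels; variance
components come from equating mean squares to expectations with
unequal-size coefficients (each individual contributes exactly two
copies, so the individual-level coefficient is 2); Φ_CT, Φ_SC, Φ_IS, Φ_IT
are reported. Missing dosages at the analysed loci are imputed with the
per-collection rounded mean before expansion (the partition needs complete
distances); the imputation count is reported. Negative components are
reported as-is and truncated at zero only for the percentage display;
levels without replication report NaN and contribute zero to higher-level
expectations. Permutation schemes: whole locations among areas (Φ_CT),
individuals among locations within areas (Φ_SC), and allele copies among
individuals within locations (Φ_IS, Φ_IT).

## Environmental GLMs and connectivity

Site-level haplotype counts (successes out of 2n chromosomes) are modeled
with a logit-link binomial GLM; the null design is intercept + lon + lat +
lon:lat and each covariate is tested in its own model by the analysis-of-
deviance χ² with 1 df. No multiple-testing correction is applied across
the four covariates — each row of the screen is its own test. The AIC
column is on the deviance scale (residual deviance + 2·#parameters):
differences between rows equal differences in the usual AIC, absolute
values do not. A Pearson dispersion diagnostic is reported because
site-level frequency variation not captured by the design is
overdispersion the binomial model does not absorb; calibration of the LRT
is therefore only exact when the binomial model holds. Perfect separation
is flagged rather than raised. The response can alternatively be mean
allele counts over the block loci via the `q_hat` column of any table
passed in.

Connectivity matrices are symmetrized as (c_ij + c_ji)/2; the Mantel test
uses Pearson correlation over strict upper triangles, permutes one
matrix's rows and columns simultaneously, aligns sites by label (never by
order, dropping unmatched sites with a warning), and reports a one-tailed
add-one p (default tail "greater"; the tail is selectable).

## Pipeline determinism

`pipeline.run_all` derives one 31-bit seed per stage from the master seed
via `numpy.random.SeedSequence(master).spawn` in a fixed stage order;
reruns are byte-identical on every numeric artifact. Any stage failure
aborts with the stage name; artifacts of completed stages persist.

## Verification scale

The test suite and `scripts/acceptance.py` run the study-emulating
configuration at 500 background loci (instead of 2,509) with everything
else at its default: 13 SV loci, 11 fixed differences, background F_ST
0.002, 11 collections of ~40 fish, 2% missingness. This is the package's
chosen standard verification scale: the LD-network geometry (one SOC,
clean block recovery) is unchanged while an all-pairs EM over ~130k pairs
runs in seconds. SV-locus recovery is evaluated over 20 seeds; null
calibrations use 200 replicates per test (1,000 for the karyotype χ²);
the environmental power run uses 100 replicates at 11 sites with a
logit-slope-2 effect. The nine-cluster two-SV check uses balanced
haplotype frequencies (q = 0.5 in both blocks): with the study's skewed
frequencies the rarest of the nine karyotype combinations has about 1%
expected membership and no method can resolve nine groups.

## Limitations

- The generator's background model has no spatial autocorrelation,
  no SFS realism and no linked selection; passing tests show correct
  recovery of the *simulated* architecture, not robustness to every
  real-data pathology.
- Leakage is independent per locus and copy; real recombinant haplotypes
  create correlated deviations the detector has not been stress-tested
  against.
- The LD-network outlier rule (λ over merger events, chain resolution by
  maximal λ, weak-member pruning) is a concrete committed design; other
  published network-analysis variants differ in these details and give
  different cluster boundaries on marginal data.
- The karyotype HWE χ² is asymptotic; at small collection sizes the exact
  test used for locus filtering is preferable.
- AMOVA p-values rely on exchangeability within the permuted level;
  strong within-level structure (e.g. family groups) would invalidate
  them.
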