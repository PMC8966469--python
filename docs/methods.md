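# Methods

This note documents the statistical model, the defaults and the design
choices behind `triodistort`, in the spirit of a model-description
appendix. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Transmission models and likelihood

At a biallelic SNP with REF allele A and ALT allele B, a trio is
*informative* when at least one parent is heterozygous (on the X: when
the mother is heterozygous, since the father's single X goes to
daughters deterministically). Each informative meiosis transmits B
with probability ½ + ε, where ε ∈ [−½, +½] measures the strength and
direction of transmission distortion. Three nested models are fitted:

| model | parameters | meaning |
|---|---|---|
| M0 | — | Mendelian transmission (ε = 0) |
| M1 | ε | uniform distortion, same in both offspring sexes |
| M2 | ε_m, ε_f | sex-specific distortion (sons / daughters) |

The data at one SNP reduce to (k_m, n_m, k_f, n_f): B-transmissions
and informative meioses per offspring sex. A hom×het autosomal mating
contributes one meiosis (from the het parent); a het×het mating
contributes two, with B-transmission count equal to the child's B
dosage. The likelihood is the product of Bernoulli transmission
events,

    lnL(ε_m, ε_f) = Σ_sex [ k ln(½ + ε_sex) + (n − k) ln(½ − ε_sex) ],

with 0·ln 0 = 0. The het×het multinomial coefficient (and all other
combinatorial constants) is omitted: it cancels identically in MLEs,
profile intervals and every likelihood-ratio statistic, so all
inferential outputs are unaffected; absolute lnL values are defined up
to a data-dependent additive constant.

Maximization is analytic: ε̂ = (k_m + k_f)/(n_m + n_f) − ½ under M1
and ε̂_s = k_s/n_s − ½ per sex under M2. Boundary MLEs (±½) are
allowed, without penalization. 95% confidence intervals are profile
likelihood sets {ε : lnL(ε) ≥ lnL(ε̂) − χ²₁(0.95)/2 = lnL(ε̂) − 1.921},
solved by bisection to |Δε| < 10⁻⁶ and clipped to [−½, ½]. Deviances
d = 2(lnL_big − lnL_small) are referred to χ² distributions with 1 df
(M1 vs M0, M2 vs M1) and 2 df (M2 vs M0); plain χ² is used even at
boundary MLEs (no ½χ² mixture). A site with zero meioses in one sex
has that ε̂ undefined; M2 collapses onto M1 for the missing sex and
the fit is flagged (`collapsed_sex`). With the default informative-trio
thresholds this is essentially never triggered on real input.

## Input handling and filters

Inputs are a multi-sample VCF (GT fields) and a PED-like pedigree
(family, father, mother, child, sex ∈ {1,2} / {M,F}). Trios are
assumed genetically unrelated; this is a modelling assumption, not a
check. Default site filters, each overridable in `FilterConfig`:

* biallelic SNPs only;
* X pseudoautosomal regions removed (hg19 defaults
  chrX:60001–2699520 and chrX:154931044–155260560, 1-based inclusive);
* X-linked sites with at least one heterozygous male call removed;
* sites with ≥ 2 Mendelian errors removed; at a surviving site a
  single erroneous trio has the **child's** genotype masked (error
  attribution to a specific member is impossible, and masking the
  child removes the trio from counting at that site);
* sites with fewer than 150 informative trios (75 on the X) removed —
  at these thresholds the 2-df test has useful power (see the power
  analysis below), which is why smaller counts are not worth testing.

A Mendelian error is any child genotype impossible under biparental
inheritance; with a missing member the trio is flagged only when the
child call is impossible under *every* completion of the missing
genotype (e.g. mother AA with child BB is an error regardless of the
father). Informativeness additionally requires both parental
genotypes called, because transmission from a het×missing mating is
ambiguous. On the X, a daughter's maternal allele is her dosage minus
the father's hemizygous allele, so a missing father makes her meiosis
unresolvable and it is skipped.

Sample sex labels are verified from non-PAR X heterozygosity: below
2% → male, above 6% → female, otherwise unassigned; conflicts with
the pedigree are reported, never silently fixed. Hemizygous ALT calls
count as homozygous, not heterozygous.

The ALT allele is "B" throughout; orientation is taken from the VCF.
A sign flip of ε̂ between adjacent SNPs therefore reflects REF/ALT
orientation, not a change of biology.

## Classification into SA / SL / SD

For a SNP with sex-specific estimates, let s = |ε_m + ε_f| and
M = max(|ε_m|, |ε_f|). With tolerance t (default 0.05, matching the
genome-wide standard deviation of the ε estimates reported for a
cohort of this size):

* **SA** if s < M − t (opposite directions shrink the sum),
* **SD** if s > M + t (same direction grows it),
* **SL** if |s − M| ≤ t (one ε near zero leaves s ≈ M).

This partition is exhaustive and disjoint; at t = 0 it reduces to pure
sign geometry (verified by brute force in the tests). Printed
formulations of the three conditions elsewhere overlap on
[M − t, M + t]; the partition above is the only self-consistent
reading and reduces to the intended geometry.

A called region is labelled by majority vote over its SNPs that are
individually significant (M2-vs-M0 p < 0.05): if the modal category
reaches 75% of the classified SNPs the region takes that label,
otherwise it is `mixed`. Whether the 75% denominator should be all
region SNPs or only the significant ones is genuinely open; we use
significant SNPs (the classification is only meaningful where the 2-df
test rejects) and expose both the cutoff and the majority threshold in
`ClassifyConfig`.

## Local-score region calling

Per chromosome, SNP scores are X_i = −log10(p_i) − ξ, so a SNP
contributes positively exactly when p < 10^−ξ (ξ = 1 aggregates
p < 0.1; ξ = 2, p < 0.01). The Lindley process H_i = max(0, H_{i−1} +
X_i) (H_0 = 0) is computed via the prefix-sum identity
H_i = S_i − min(0, min_{j≤i} S_j), which equals the best
contiguous-segment score ending at i (checked against a brute-force
segment oracle). Every excursion (maximal run of H > 0) whose peak
exceeds the chromosome-wise threshold yields one region, spanning the
excursion start through the first peak position; the full excursion
extent is kept as metadata. The boundary convention (start-to-peak) is
a choice — the segment realizing the maximal score is exactly
[start, argmax] — and the metadata allows the full-excursion
convention instead.

Significance thresholds are Monte-Carlo: the (1 − α) quantile of the
maximal height over replicate chromosomes of i.i.d. uniform p-values
(default 1000 replicates, α = 0.05 per chromosome). This is
assumption-explicit and reproducible given a seed, but it ignores LD:
on strongly autocorrelated p-values the i.i.d. null is misspecified
and the threshold is not exact at the nominal level. An
autocorrelation-aware Gumbel approximation would be the natural
extension; it is not implemented here.

π₀ — the proportion of SNPs in truly Mendelian regions — is estimated
Storey-style on SNPs thinned to ≥ 500 kb apart (greedy left-to-right
within chromosome) to decorrelate p-values:
π̂₀ = #{p > λ}/((1 − λ)·m) with λ = 0.5, capped at 1.

## Intersexual F_ST

Per SNP, males and females of one cohort (offspring by default;
parents selectable) are treated as two populations in the Weir &
Cockerham (1984) variance-component estimator; θ̂ = a/(a + b + c) with
the standard a (among-population), b (among-individual) and c
(within-individual) components. Negative estimates are reported as-is,
preserving a null mean near zero; sites monomorphic in both sexes are
flagged undefined, never imputed. On the X, where males are
hemizygous, the diploid estimator does not apply; we use a
Hudson-style allele-frequency estimator with per-sex sampling
correction (males contribute single alleles; heterozygosity enters
through females only) and flag those rows `haploid` — a nonstandard
but explicit extension.

Region-level comparisons use an empirical matched null: for each
candidate region, pool regions whose length, SNP count and nucleotide
diversity all lie within ±20% (multiplicative) are resampled with a
seeded generator; targets with no admissible match are reported, not
dropped. Recombination-quartile enrichment uses two-sided exact
binomial tests of the per-quartile region count against the null
proportion 0.25, with quartile breakpoints taken from the genome-wide
window distribution.

## Simulation machinery

**Power/calibration design.** One informative meiosis per trio,
offspring sexes Bernoulli(½), 500 replicate sites per scenario, LRTs
at α = 0.05. Sex-antagonistic scenarios are parameterized by the
effect size δ = |ε_m − ε_f| split symmetrically (ε_m = +δ/2,
ε_f = −δ/2); uniform-distortion scenarios by a single ε. This design
analytically reproduces the expected operating characteristics: the
2-df noncentrality ≈ 4·n_sex·ε² per sex gives powers near 0.6 / 0.8 /
0.93 at δ = 0.2 / 0.25 / 0.3 with 150 trios, and the 1-df analogue
≈ 0.69 / 0.96 / 0.998 at ε = 0.1 / 0.15 / 0.2 with 150 meioses. The
simulators draw the sufficient statistics directly (binomial counts),
so a 2000-replicate calibration runs in well under a second;
`frac_double_het` adds het×het matings (two meioses per trio) when a
mating-type mix is wanted.

**Recombination-free windows.** Around a focal SNP, with recombination
intensity λ per megabase (default 0.01, i.e. 1 cM/Mb — unit conversion
is the caller's responsibility), each trio's nearest upstream and
downstream breakpoints are Exponential(λ); the window in complete
linkage across N_T trios is the sum of the two minima, i.e.
Gamma(shape 2, rate N_T·λ). The simulator draws the per-trio
exponentials explicitly and returns method-of-moments shape
(mean²/variance) and rate estimates, recovering shape ≈ 2 and mean
2/(N_T·λ).

**Genotype fixtures.** `make_fixture` writes a plain-text VCF 4.2 +
PED + ground-truth sidecar. Defaults emulate the study conditions the
framework targets: 250 trios with 98 sons and 152 daughters, parents
Hardy–Weinberg at ALT frequencies uniform on [0.30, 0.50] (the
intermediate-frequency regime in which a 250-trio cohort reaches the
150-informative-trio threshold — the regime the method has power in),
an X block with hemizygous fathers and sons outside the PAR, optional
planted distorted regions, Mendelian-error injection (the child call
is replaced by an incompatible dosage where one exists; het×het
matings admit none) and random missingness. What the generator does
**not** emulate: linkage disequilibrium between sites (sites are
independent given the planted ε), realistic allele-frequency spectra,
genotyping error beyond the injected classes, or relatedness between
trios. Passing end-to-end tests therefore demonstrate correctness of
the counting/fitting/calling machinery under the model, not robustness
to LD-driven threshold miscalibration on real genomes (see the
local-score caveat above).

## Haplotype follow-up

For a candidate region with externally phased haplotypes: pairwise
allele-sharing distance (normalized Hamming on haplotypes; mean
|g₁ − g₂|/2 on genotypes; missing sites excluded pairwise, a pair with
no shared site is an error), classical Torgerson MDS (double-centered
Gram eigendecomposition; non-positive eigenvalues dropped with a
warning), and DBSCAN density clustering (scikit-learn; border points
follow the first-discovered cluster, deterministic given input order).
Haplotype transmissions from heterozygous parents are resolved by
nearest-ASD matching of child to parental haplotypes (exact for
cleanly phased trios) and tested for sex bias per haplotype class: an
exact two-sided binomial test of the son fraction among that class's
transmissions against the son fraction among all transmissions from
such parents (a fixed p₀, e.g. ½, is available as an option), plus a
2×2 Fisher exact test (transmitted class × child sex), plus an
optional carrier sex-bias binomial test. A Mantel-type permutation
test (Pearson correlation of off-diagonal distances with the
same/different-sex indicator; labels permuted, p = (1 + #{|r*| ≥
|r|})/(1 + n_perm)) screens for genome-wide genetic structure by sex,
which would confound everything downstream. DBSCAN's eps/min_pts and
the MDS dimensionality have no universal defaults; they are exposed in
`ClusterConfig` (defaults eps = 0.1, min_pts = 5, 2 dimensions).

## Reproducibility and problem sizes

Every stochastic operation takes a seed or an explicit numpy
`Generator` and is bit-reproducible given it; the workflow manifest
records versions, parameters and input checksums, and a rerun with the
same configuration produces byte-identical outputs. The test suite and
the acceptance script use desk-scale problem sizes chosen to match the
framework's own published operating points: 500 replicates per power
cell, 2000 for null calibration, 10⁵ recombination-window draws,
50-replicate cohorts for region-recovery rates, and fixture cohorts of
120–250 trios over tens of SNPs.

## Known limitations

* Monte-Carlo local-score thresholds assume i.i.d. uniform null
  p-values; LD makes them approximate on real data.
* The X-chromosome F_ST estimator for hemizygous males is a pragmatic
  extension, not Weir–Cockerham 1984.
* Parent-of-origin-specific distortion (which parent distorts) is out
  of scope; only offspring sex is modelled.
* Phasing, imputation, relatedness inference and multi-allelic
  decomposition are upstream concerns.
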