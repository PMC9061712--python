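# Methods

This note documents the statistical models implemented in `qtltriad`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical and design decisions that were genuinely
open.

## cis-QTL mapping

Each (variant, feature) pair with the feature anchor within the cis window
(default 1,000,000 bp, boundary inclusive) of the variant position on the
same chromosome is tested by ordinary least squares of the phenotype on
`[1, dosage, covariates]`. Genes are anchored at the strand-aware
transcription start site (annotation `start` for `+`, `end` for `-`); CpGs
at their coordinate. The dosage coefficient's two-sided p comes from the t
distribution on the residual degrees of freedom. Dosages enter un-rounded
(imputed-dosage convention); rows with a missing dosage, phenotype or
covariate are dropped pairwise per association — the smallest-assumption
handling of missingness, chosen over imputation or listwise deletion across
the whole scan.

Multiple testing is controlled by Benjamini–Hochberg step-up over **all
tested pairs of one scan** (all eQTL pairs jointly; all mQTL pairs jointly),
not per-gene permutation q-values: the associations of interest are
pair-level, and a single FDR over the pair list is the matching error
criterion. Calibration of a scan is summarized by the genomic inflation
factor λ = median(χ²₁(1−p)) / 0.4549…, which equals 1.0 exactly when all
p = 0.5.

Covariates follow the standard placental-cohort recipe: fetal sex, ancestry
indicator columns (one-hot, one level dropped), top genotype principal
components for population structure, and top phenotype principal components
for hidden batch structure. PCs are the top left singular vectors of the
column-standardized matrix, sign-fixed by the largest-magnitude loading.
Phenotype PCs are only included when the phenotype matrix has at least 30
features: with only a handful of features the "hidden factor" estimate is
dominated by the very signals under test and regressing it out destroys
power (this is visible in the simulated cohorts, which carry few features
per locus).

Methylation may enter on the beta scale (default) or as
M-values (`log2(b/(1−b))`, clipped at 1e-6); the data do not dictate a
choice and both are exposed.

## Genotype and CpG quality control

Variant filters: missingness > 5%, minor allele frequency < 0.5%, and
Hardy–Weinberg disequilibrium at exact-test p < 1e-4 (dosages rounded to
hard genotypes for the count test). The HWE test conditions on the observed
allele counts and sums the probabilities of all heterozygote counts no more
probable than the observed one, in log space; it is validated against a
brute-force enumeration oracle. Methylation features whose CpG lies within
20 bp (inclusive) of any variant are removed, since a polymorphism under the
probe corrupts the methylation measurement. Multi-allelic and indel VCF
records are skipped on read. Coordinates are 1-based inclusive throughout;
chromosome names are normalized by stripping a leading `chr`.

## Triplets and direction concordance

A variant co-occurs when it has at least one FDR-significant eQTL and one
FDR-significant mQTL association at the same α (default 0.05). Its triplets
are the full cross product of significant eGenes × significant CpGs, so the
triplet count per SNP factorizes and the total is the sum over SNPs.
Direction concordance across triplets is the Spearman correlation of the
mQTL versus eQTL coefficients plus the fraction of opposite-sign pairs;
promoter-proximal methylation classically represses transcription, so an
excess of opposite signs is the biologically expected signature. A
replication mode re-tests the triplet pair list in a second cohort and
reports nominal p < 0.05 agreement, deliberately introducing no new
statistics.

## Causal inference test

For L = dosage, G = candidate mediator, T = outcome, with covariates C in
every component (the conservative choice for a confounded multi-ancestry
design):

- p1: t/F-test of L in `T ~ L + C` — the variant associates with the
  outcome;
- p2: L in `G ~ L + T + C` — the variant associates with the mediator given
  the outcome;
- p3: G in `T ~ G + L + C` — the mediator associates with the outcome given
  the variant;
- p4: an equivalence-style permutation test that conditioning on G removes
  the L–T association. The observed statistic is F for L in `T ~ L + G + C`.
  Surrogate mediators G* = fitted(G|1,L,C) + permuted residuals preserve the
  L–G association but break the G–T|L link; p4 is the smoothed fraction
  (+1 in numerator and denominator, so p4 > 0) of permutations with
  F*(L | G*) ≤ F_obs. **Orientation:** small p4 means the real mediator
  removes the L–T association far more completely than chance mediators —
  evidence *for* mediation. This is stated explicitly because sign
  conventions differ across descriptions of the test.

The omnibus for each direction is the intersection–union maximum of the four
components. With pCausal (L→M→E) and pReverse (L→E→M) at α = 0.05: SME when
only pCausal < α, SEM when only pReverse < α, independent when neither,
unclassified when both. Genotype enters as a numeric additive 1-df term,
matching the QTL model; a categorical (2-df) genotype coding is a known
alternative used by some implementations. The permutation count defaults to
1000 and is fully seeded; the same seed drives both orientations, so
swapping the mediator and outcome inputs exactly swaps the two omnibus
p-values. The surrogate-mediator construction is validated by its
calibration properties (uniform null components, ≤ 2α false-causal rate on
independent-pathway data, ≥ 80% SME recovery at n = 500 with r² = 0.4/0.3),
not by bit-level agreement with any particular legacy implementation.

## MR Steiger directionality

With one SNP instrumenting both molecular traits, the upstream trait is the
one sharing more variance with the instrument: under g→x→y the path rule
gives r²(g,y) = r²(g,x)·r²(x,y) < r²(g,x). The test statistic compares the
two instrument correlations (absolute values, Fisher z-transformed) with
Steiger's (1980) test for dependent correlations sharing one variable,
which accounts for cor(m, e) since both traits are measured on the same
samples — the appropriate variant here; an independent-samples approximation
is available behind a flag. r² from raw data equals t²/(t²+n−2) from the
regression summary, and exact ties are flagged (`TIE`), never silently
broken. Per unique DNAm–gene pair instrumented by several SNPs, the
instrument with the largest exposure r² is kept (the collapse rule is not
externally dictated; best-instrument deduplication is the implemented
decision), then BH-FDR is applied across pairs and tier counts at
q < 0.05/0.1/0.25 reported. Triplets where the CIT label and the Steiger
direction agree (SME↔ME, SEM↔EM) are marked consistent in the triangulation
report.

## Multi-trait colocalization

Per SNP and trait, the Wakefield approximate Bayes factor against the null
is `exp(½ log(V/(V+W)) + ½ z² W/(V+W))` with V = se², z = β/se, averaged
arithmetically over the prior effect variances W ∈ {0.01, 0.1, 0.5}
(configurable). Hypotheses assign each trait to "unassociated" or to a
causal-variant group; groups partition the associated traits, share one SNP
within a group, and must pick **distinct** SNPs across groups (groups
represent distinct causal variants, so coincident assignments are excluded
via inclusion–exclusion over the group blocks, all in log space). For
k = 1/2/3 traits this yields 1/4/14 non-null configurations — 2/5/15
hypotheses counting the null, the familiar 15-hypothesis layout for three
traits whose H-numbering runs from the null (H0) to full sharing
(H14 = GEM). Posteriors are normalized over all 15 outcomes and sum to 1
within 1e-9 by construction. Configuration priors multiply p1 = 1e-4,
p2 = 1e-6, p3 = 1e-7 per group of size 1/2/3; these are the conventional
defaults for this engine family and are configurable and recorded in
output metadata. Note the ABF depends on V relative to the fixed W, so
posteriors are invariant to rescaling a trait's β and se only when W is
rescaled by the same squared factor; with W fixed, the dominant hypothesis
is insensitive to moderate unit changes but exact invariance should not be
expected.

Entry filters mirror recommended practice: at least 50 SNPs shared across
all traits after intersection with MAF > 0.05; smaller loci are skipped with
an explicit reason. Trait order is fixed as (G = GWAS, E = expression,
M = methylation) in labels; the arithmetic is order-invariant. The best SNP
reported for a colocalized locus maximizes the per-SNP evidence of the group
containing the GWAS trait under the winning configuration. Cross-dataset
SNP harmonization matches on (chrom, pos, alleles), flips effect signs for
swapped alleles, and drops strand-ambiguous A/T and C/G variants whose
allele frequency is uninformative (|eaf − 0.5| < 0.08).

## Enrichment statistics

One-sided upper tails P(X ≥ k) are computed from the exact log survival
functions of the binomial (background proportion) or hypergeometric
(background counts) distribution; results below ~1e-320 are reported as an
upper bound rather than underflowing to zero. Because published enrichment
claims often quote a "hypergeometric test" while only printing a background
proportion, the API requires the caller to state the background form
explicitly and records which was used. Spearman correlation uses midranks;
p is exact by full permutation for n ≤ 9 and the t-approximation otherwise.

## Synthetic data: what it emulates, and what it does not

- **Genotypes.** Each haplotype is a latent AR(1) Gaussian across SNPs
  thresholded at the allele-frequency quantile, so marginals are
  Binomial(2, maf) (Hardy–Weinberg) while adjacent-SNP correlation decays
  with `ld_rho`. This reproduces an LD *block*, not a genome-wide LD map.
- **Causal triplets.** Genotypes are standardized inside the generators so
  effects a (SNP→first node), b (node→node) and c (direct) are per-SD and
  comparable across allele frequencies. Gaussian residuals of unit SD; the
  simulated methylation values are continuous Gaussian (M-value-like), not
  bounded beta fractions.
- **Cohort bundle.** Defaults mirror the motivating study design: 291
  samples with genotype + methylation, the first 71 (ancestry-shuffled) also
  with expression; four ancestry groups (fractions 0.33/0.26/0.24/0.17) with
  Balding–Nichols allele-frequency differentiation at Fst-like spread 0.05
  (mild, so covariate adjustment is exercised without overwhelming the
  signal) and an ancestry shift on the molecular traits; causal SNP→node r²
  of 0.4 and node→node r² of 0.3, the effect sizes used throughout the
  recovery simulations; a GWAS trait from an independent sample of 50,000
  (large-cohort regime) with a z-target of 8 at causal loci. Ground-truth
  scenario labels are always emitted, and all generators are byte-stable
  under a fixed seed.
- **Per-locus summary statistics** are produced by actually regressing a
  freshly simulated phenotype on every SNP in an independent sample of the
  stated size — not by sampling z-scores from an assumed distribution — so
  LD-induced correlation among test statistics arises naturally. In the
  pipeline's colocalization stage, per-trait sample sizes default to the
  GWAS size for G and multiples of the molecular cohort sizes for E and M,
  and per-trait z-targets derive from the cohort effect sizes; with the
  study's n = 71 expression subset the expression z-target is weak (~3), so
  end-to-end three-trait colocalization at PPA ≥ 0.8 generally requires
  stronger expression effects than the cohort default — the same power
  asymmetry the real design faces.

What passing tests show: the statistical machinery is correct (oracle
equivalence), calibrated under the null, and able to recover planted causal
structure at realistic effect sizes. What they do not show: robustness to
cell-type heterogeneity, probe artifacts, imputation error, parent-of-origin
effects, or genome-scale multiple-testing burdens, none of which the
generators emulate.

## Problem sizes used in the shipped test suite

Simulation-based checks use: 20-seed null-cohort scans (n = 100, four null
loci); 500 replicates for null uniformity of the first CIT component; 200
replicates at n = 500 with 200 permutations for CIT label recovery and
false-causal rates; 200 replicates at n = 291 for Steiger direction
recovery; 100-replicate locus simulations (100 SNPs, per-trait n of
4000/2000/2000, z-target 8) for colocalization recovery and discrimination;
20 all-null pipeline runs for the end-to-end colocalization false-positive
check. These sizes give comfortable margins on every threshold while the
whole suite completes in a few minutes on one CPU.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq` with rank checks; rank-deficient designs or
  constant dosages are flagged untestable, never reported as p = 1.
- Exactly collinear fits (zero residual) report p = 0 rather than NaN.
- HWE, enrichment tails, ABFs and configuration likelihoods are computed in
  log space; signed log-sum-exp handles the inclusion–exclusion
  cancellations, and numerically non-positive admissible mass maps to zero
  support (−inf).
- BH q-values come from the standard step-up implementation (statsmodels),
  validated against a literal step-up oracle.
- Empty inputs: empty VCF regions and empty scans return empty tables with
  warnings; empty p-vectors are an error for λ (undefined median).
- A single global pipeline seed fans out to stage seeds by fixed offsets
  (cohort +0, CIT +211, locus simulations +977 plus a CRC of the locus id),
  so any stage can be reproduced in isolation.

## Known limitations

- One causal variant per trait per locus; no fine-mapping of multiple
  signals, no LD-matrix (non-summary) colocalization.
- No trans-QTL scans, conditional secondary-signal mapping, or mixed-model
  relatedness correction.
- The CIT permutation null is exchangeable-residual based; heteroscedastic
  residuals would distort p4 slightly.
- Steiger inference assumes a valid instrument; winner's curse and
  measurement-error asymmetry between methylation and expression are not
  corrected and can bias the inferred direction.
- Enrichment helpers reproduce test mechanics, not any specific published
  background population, whose counts are generally not published.
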