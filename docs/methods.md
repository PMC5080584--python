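# Methods

## Model

Every association in the grid is the ordinary least-squares fit of

y_p = Z γ + g_t β + ε, ε ~ N(0, σ² I),

where Z (n_i × (n_c − 1)) is the covariate block with the intercept first
and g_t the additive dosage (expected alternate-allele count in [0, 2]) of
determinant t. n_c counts intercept + covariates + tested determinant, so
the residual degrees of freedom are df = n_i − n_c. The reported statistics
are the textbook quantities for the tested determinant:

β̂ = (X_t'X_t)⁻¹ X_t'y_p, RSS = y'y − B'A⁻¹B, σ̂² = RSS/df,
se = √(σ̂² [A⁻¹]_last,last), t = β̂/se, p = 2·S_t(|t|; df),

with A = X_t'X_t assembled from the shared block a1 = Z'Z, the per-variant
border (a2_t = Z'g_t, a3_t = g_t'g_t), and B from b_cov = Z'Y and
b4 = Y'G. The solver is exact OLS — no approximation is introduced by the
decomposition, only redundant arithmetic is removed. The whole block of
n_p × n_t fits is solved with batched small-matrix operations (stacked
inverse of the (n_c × n_c) A_t, einsum contractions), never a per-pair loop.

## Meta-analysis protocol

All blocks of the sufficient statistics are additive over row-partitions of
the sample, so summing per-site (a1, a2, a3, b_cov, C) and solving with
df = Σ n_k − n_c reproduces the pooled analysis exactly (one model fitted to
the virtual pooled sample; Σ(n_k − n_c) would discount n_c per site and is
not pooled-equivalent). b4 is reconstructed from the encoded pair,
b4 = Σ_k Y_F,k' G_F,k, decoded in variant chunks to bound memory.

Encoding: F has i.i.d. standard-normal entries drawn from a seeded
generator, redrawn from the next seed substream while cond₂(F) ≥ 1e6 (a
Gaussian square matrix is almost surely nonsingular; the guard bounds
round-off amplification in the decoded product at roughly cond(F)·machine
epsilon, i.e. ~1e-10 worst case). An orthogonal F would condition perfectly
but its encoded pair would expose the Gram matrices Y'Y and G'G, so it is
deliberately not used. F and F⁻¹ exist only inside the package-building
call; the serialized package contains exactly the datasets
{a1, a2, a3, b_cov, C, Y_F, G_F} plus public metadata (site id, covariate
names, variant/phenotype manifests and their digests). b_cov = Z'Y is
shipped in the clear: it is aggregate (n_c−1) × n_p data of the same nature
as C and is algebraically required for the central solve. The package
asserts a testable privacy surface — no raw data matrix and no F in the
file — not a cryptographic guarantee.

Merging requires identical covariate names and identical variant/phenotype
manifests (compared by SHA-1 digest) across sites and rejects duplicate
site ids.

## Parameters that matter

- `chunk_variants`, `chunk_phenotypes` (default 1000 × 1000): block sizes of
  the store reads and the solver; they bound peak memory (a block holds
  chunk_v × n_c × chunk_p doubles) and do not affect the statistics beyond
  ~1e-15 BLAS reordering.
- `missing` (`mean`, default, or `drop-stat`): per-variant mean imputation
  keeps n constant per variant, matching common dosage-GWAS practice;
  `drop-stat` instead reports NA for every pair of a variant with missing
  dosages. Mean imputation is applied per run, so a multi-site analysis is
  exactly pooled-equivalent only when dosages are complete or imputed
  identically at every site — per-site means differ from pooled means.
- `maf_min` (default 0 = off): minor-allele-frequency filter; in the
  central meta run the frequency is recovered from the intercept row of the
  summed a2 (Σ dosage / 2N).
- `p_threshold` (default 1.0): records with larger p are not written; NA
  records are always written so degeneracy stays visible.

## Numerical choices

- All derivatives and statistics are 64-bit; stores round-trip bit-exactly.
- Degenerate designs: A_t with min|eig|/max|eig| < 1e-10 (monomorphic
  variant, or dosage collinear with covariates) is not solved; the variant's
  statistics are NA and counted in the run log. The symmetric
  eigendecomposition is batched over the variant chunk.
- RSS is computed as C − B'A⁻¹B and clamped: values within C·1e-12 of zero
  are treated as an exact perfect fit. A perfect fit driven by the
  determinant (nonzero explained SS) yields NA with a perfect-fit flag
  rather than an infinite t, keeping output parseable; a perfect fit that
  owes nothing to the determinant (e.g. a constant phenotype absorbed by the
  intercept) is a clean null and reports β = 0, t = 0.
- Output ordering is fixed (variant-major within the chunk grid) for
  reproducible diffs; results are written with 15 significant digits.

## Synthetic data

The generator emulates a quantitative-trait cohort at desk scale: per
variant an allele frequency uniform on a MAF range (default 0.05–0.5) and
hard dosages Binomial(2, f) (Hardy–Weinberg proportions, no LD — linkage
structure is irrelevant to the per-variant regression algebra); covariates
from a small spec (default: intercept, a uniform[0,1] age-like and a
Bernoulli(½) sex-like column, giving n_c = 4); phenotypes
Y = G·B + Z·Γ + N(0, noise_sd²) with sparse planted effects B recorded in a
truth table and covariate effects Γ drawn once per dataset from N(0, 1).
Defaults: noise_sd = 1, so a planted β is in units of residual SD per alt
allele. Site splitting partitions rows contiguously with largest-remainder
apportionment of the requested fractions.

What passing tests therefore show: exactness of the algebra, calibration
under the generator's idealized null, and pooled-equivalence of the
exchange protocol. What they do not show: behaviour under population
structure, relatedness, LD, imputation uncertainty, or spatially correlated
imaging phenotypes — none of which the generator emulates and all of which
are out of scope for the regression model itself.

## Problem sizes used in the checks

The automated checks run studies of 200 × 500 × 50 (single-site oracle
comparison against an independent per-pair least-squares fit), 900 samples
split into three sites of 300 (exchange vs pooled), 300 × 200 × 50
(10,000-test null calibration), and 100 draws of n = 1000 for recovery of a
planted β = 0.5 — sizes chosen so the full battery completes in seconds
while every code path (chunking, alignment, encoding, merging) is
exercised. Comparisons use relative tolerance 1e-8 with a tiny absolute
floor (1e-12 single-site, 1e-9 for decoded statistics) because statistics
that are numerically zero carry machine-level round-off in both the
implementation and the oracle, amplified through the encoding by cond(F).

## Known limitations

- Linear models only: no logistic regression, mixed models/relatedness
  correction, interaction terms, or genomic control; multiple-testing
  correction is left to downstream tooling.
- One determinant tested at a time; the covariate block is shared by design.
- The encoding obscures row-level data but is not a formal privacy proof;
  aggregate quantities (Z'Y, allele frequencies via a2) are shared in the
  clear as in any summary-statistics meta-analysis.
- BGEN/PLINK-bed inputs and genotype QC (HWE, call rate) are out of scope;
  VCF and delimited dosage tables are the supported inputs.
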