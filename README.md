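# hdassoc

Exact mass-univariate linear regression for high-dimensional association
studies — many genetic determinants crossed with many quantitative
phenotypes (GWAS of expression panels, metabolites, imaging voxels) — plus a
privacy-preserving multi-cohort meta-analysis that reproduces pooled-analysis
statistics without exchanging individual-level data.

## The problem and the method

A brain-wide × genome-wide study fits the same small regression

```
y_p = Z γ + g_t β + ε,        p = 1..n_p phenotypes,  t = 1..n_t variants
```

for every phenotype–variant pair: `Z` is the shared covariate block
(intercept, age, sex, …) and `g_t` the additive dosage of variant *t*.
Fitting the pairs independently repeats almost all of the arithmetic.
Writing `X_t = [Z | g_t]`, the normal-equations matrix

```
A_t = X_t'X_t = [[ Z'Z    Z'g_t  ],
                 [ g_t'Z  g_t'g_t ]]
```

shares its covariate block `a1 = Z'Z` across all variants, and the
right-hand side splits into `b_cov = Z'Y` (once per study) and
`b4 = Y'G` (one dot product per pair). With `C_p = y_p'y_p`, every β,
standard error, t-statistic and p-value follows from
`(a1, a2, a3, b_cov, b4, C)` by small-matrix algebra — no approximation,
and the per-pair cost drops from a full least-squares solve to O(1)
arithmetic on precomputed products.

Those quantities are also the OLS sufficient statistics, and they are
additive over row-partitions of the sample. K cohorts can therefore mail
them to a central site and obtain *exactly* the pooled-analysis statistics
(df = Σn_k − n_c). The large block `b4` (n_p × n_t entries) is never
shipped: each site draws a private random nonsingular matrix `F` and sends
the encoded pair `Y_F = F'Y`, `G_F = F⁻¹G`, whose product
`Y_F'G_F = Y'F F⁻¹G = Y'G` recovers `b4` exactly while the payload grows
additively, O(n_i·(n_p + n_t)). `F` never leaves the site, so neither raw
phenotypes nor raw genotypes are exchanged.

## Worked example

```
hdassoc simulate --out study2 --config sim.yaml      # plants rs25 -> pheno3, beta = 0.35
hdassoc analyze --genotype study2/genotype.h5 --phenotype study2/phenotype.h5 \
    --covariates study2/covariates.h5 --out results.tsv --p-threshold 1e-4
```

with `sim.yaml` declaring 500 samples × 200 variants × 8 phenotypes,
`noise_sd: 1.0` and one planted effect `[24, 2, 0.35]`. Output:

```
# hdassoc 0.1.0 | config 4ba43743bbd1
phenotype_id  variant_id  chrom  pos    ref  alt  n    beta               se                  t                 p                     df
pheno3        rs25        1      25000  A    G    500  0.323438074030015  0.0659054224611803  4.90760944929118  1.25268334439501e-06  496
```

The only pair passing p ≤ 1e-4 is the planted one: β̂ = 0.323 (truth 0.35,
well within one standard error 0.066), t = 4.91 on 496 = 500 − 4 degrees of
freedom. The same dataset split into three virtual sites, exported with
`hdassoc export-site` and merged with `hdassoc meta`, reproduces these
numbers to ~1e-12.

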