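# Methods

## The model

`cowas` tests whether the genetically regulated co-expression of two
molecular exposures (typically plasma proteins) is associated with a complex
trait, while accounting for each exposure's direct effect. It extends the
two-sample, two-stage least squares design of TWAS/PWAS.

Stage 1 assumes additive genetic control of each exposure,

    A_i = gamma_A + Z_A,i' beta_A + eps_A,i
    B_i = gamma_B + Z_B,i' beta_B + eps_B,i

with Z_A, Z_B the dosage vectors of the exposures' xQTLs. Co-expression is
defined through the product of the residuals,

    C_i = (A_i - E[A_i | Z_A,i]) (B_i - E[B_i | Z_B,i]) = eps_A,i * eps_B,i,

and its genetically regulated component E[C_i | Z_i] is modeled as a linear
function of the union Z of both xQTL sets, C_i = gamma_co + Z_i' beta_co +
eps_C,i. Because the marginal genetic effects on the means are subtracted
first, beta_co captures genetic modulation of the *correlation* between the
two exposures rather than correlation induced by shared mean effects or by
environment. An alternative product mode replaces C with the product of the
centered observed expression values, which is closer to a conventional
interaction model; both modes are implemented and share all downstream
machinery.

Stage 2 assumes the trait is linear in the three genetically regulated
components,

    Y_i = gamma_Y + theta_A E[A|Z_A] + theta_B E[B|Z_B] + theta_co E[C|Z] + eps_Y,i.

With weights fitted on sample 1 (size n1), predictors are imputed on sample
2 (size n2) as A* = Z* w_A, B* = Z* w_B, C* = Z* w_co and the trait is
regressed on them jointly, so each estimate is conditional on the other two.
Two tests are primary: the interaction Wald test W = theta_co^2 /
Var(theta_co) ~ chi2(1), and the global F test against an intercept-only
model, F = ((n2-4)/3) (RSS_null - RSS)/RSS ~ F(3, n2-4) with RSS_null =
n2 - 1 for a standardized trait. Per-coefficient Wald tests for theta_A and
theta_B are computed and reported but are secondary.

## Summary-statistic testing

Stage 2 is usually run from GWAS summary statistics. Marginal Z scores are
converted to standardized effects b_j = z_j / sqrt(n - 2 + z_j^2) (the exact
inversion of the simple-regression t statistic on standardized variables).
With W the p x 3 padded weight matrix and Sigma the LD (variant correlation)
matrix from a reference panel,

    S = W' Sigma W,   v = W' b,
    theta_hat = S^-1 v,   R^2 = theta_hat' v,
    Var(theta_hat) = ((1 - R^2) / (n2 - 4)) S^-1,
    F = ((n2 - 4)/3) R^2 / (1 - R^2).

When Sigma and b are computed on the GWAS sample itself this is
algebraically identical to the individual-level OLS, which is the contract
the test suite pins (agreement to 1e-6 in theta and 1e-4 in the global
p-value). The single-exposure PWAS statistic is the 1-column special case
with residual df n2 - 2.

Numerical safeguards: if cond(S) > 1e8 a trace-scaled ridge term
(1e-6 tr(S)/3) I is added and the result flagged `regularized`; R^2 is
clipped to [0, 0.999] (weights fitted out of sample can otherwise push
theta' v outside [0, 1]) and clipping is flagged; per-variant GWAS sample
sizes are collapsed to their median for the degrees of freedom, overridable.

## Preprocessing

- Variant QC filters, in fixed order so report counts are reproducible:
  missingness > 10%, minor allele count < 100, minor allele frequency < 1%
  (f = mean dosage / 2), Hardy-Weinberg equilibrium P < 1e-15 (1-df
  chi-square against expected genotype counts), palindromic allele pairs
  (A/T, C/G), missing identifiers. HWE requires hard calls; with fractional
  dosages the filter is skipped and noted in the report. These thresholds
  are the package defaults and can all be changed.
- Expression normalization per pair: restrict to samples non-missing for
  both proteins (no imputation), Blom rank-inverse-normal transform (offset
  0.375, ties averaged), regression on standardized covariates plus
  intercept, residuals re-standardized. The adjustment refuses to run with
  fewer than (number of covariates + 10) complete samples.
- Marginal pQTL scan: simple regression of the adjusted phenotype on each
  standardized dosage (missing dosages mean-imputed per variant, never for
  QC counts); with both sides standardized, beta equals the Pearson
  correlation and p-values use t with n - 2 df.
- Screening (sure independence screening): the top 100 variants per protein
  by marginal P value or |effect size|, optionally restricted to the cis
  window (gene start - 500 kb to gene end + 500 kb, closed interval,
  1-based). Ties break by (chrom, pos, id), making the output invariant to
  row order. The co-expression model's feature set is the union of the two
  screened sets, exposure weights zero-padded into the union order.
- A greedy LD pruner (r^2 < 0.8 within a sliding window) is available as an
  optional step. Window and step can be given in variant counts (default,
  the common tool convention for this flag form) or base pairs.

## Stage-1 training choices

Penalized linear regression with the elastic-net family: alpha = 1 (lasso,
default), 0.5 (elastic net), 0 (ridge), objective
(1/2n)||y - Xw - c||^2 + lambda (alpha ||w||_1 + (1-alpha)/2 ||w||^2).
The lambda path has 100 log-spaced values from lambda_max (smallest lambda
with an all-zero solution; for ridge the same grid anchored at the
alpha = 0.001 convention) down to 1e-3 lambda_max; lambda is chosen by
minimum mean 10-fold cross-validation error, folds assigned by a seeded
shuffle, ties resolved toward the larger lambda. Genotype columns are
standardized (ddof = 1) before fitting and the stored weights are on the
standardized-dosage scale, with allele metadata retained so stage 2 can
re-standardize its own panel consistently. The co-expression target is
centered by the fitted intercept but never rescaled — its scale carries the
covariance signal.

Evaluation follows the 80/20 protocol: single-protein performance is the
test-split correlation between measured and imputed expression; the
co-expression correlation compares the 80%-trained co-expression prediction
on the test split against the residual target computed there with
single-protein models trained on *all* samples (in product mode, against
the observed product). After evaluation all three models are re-trained on
the full sample. A pair is "well imputed" when all three correlations
exceed 0.03 (a correlation rather than R^2 filter, so negatively correlated
predictors never pass); a pair with an all-zero weight vector in any model
is flagged non-imputable, which subsumes the undefined-correlation case.

## Synthetic data generator

The generator emulates the study conditions the estimator assumes: sparse
cis architecture (defaults: p = 50 variants, 5 causal per protein with
standardized effect 0.3 each, about 30% heritability), hard-call genotypes
with MAF ~ Uniform(0.05, 0.5) (independent by default; an AR(1) latent-
haplotype mode with parameter phi produces LD for exercising those code
paths), and a residual correlation that is itself genetic:
rho_i = tanh(eta0 + Z_i' eta) with 5 coQTLs of strength 0.3. The tanh link
keeps rho in (-1, 1) while staying locally linear, matching the linear
coQTL model in the small-effect regime; residuals are bivariate normal with
unit variances, so E[C_i | Z_i] = rho_i exactly. The trait on the second,
disjoint sample is theta_A g_A + theta_B g_B + theta_co rho + noise
(defaults theta = (0.1, -0.1, 0.2), noise sd 1), and marginal GWAS Z scores
are computed on it per variant. Everything is a pure function of the
config, including the seed.

What the generator does not emulate: realistic LD from reference
haplotypes, allele-frequency/effect-size coupling, trans effects,
case-control ascertainment, population structure, or assay artifacts.
Passing tests therefore demonstrate internal statistical correctness of the
estimator and its calibration under the assumed model, not robustness to
those real-data features.

## Validation performed by the test suite and acceptance script

- Closed forms: the global F at (n2 = 104, RSS_null = 103, RSS = 51.5)
  equals 100/3; the Wald p at |theta/se| = 1.959964 equals 0.05; the Blom
  transform matches a direct normal-quantile oracle to 1e-12.
- Summary/individual equivalence across simulated datasets with in-sample
  LD (max |theta difference| < 1e-6).
- Null calibration: with theta = 0, empirical rejection of the interaction
  and global tests at alpha = 0.05, and a Kolmogorov-Smirnov check of the F
  statistic against F(3, n2 - 4). The test suite uses 1,000 replicates at
  n1 = 500, n2 = 2,000; the acceptance script uses 500.
- Effect recovery against a brute-force two-stage OLS oracle on the same
  data. The test suite uses 200 replicates at n1 = 5,000, n2 = 20,000; the
  acceptance script uses 100 at n1 = 2,000, n2 = 10,000.
- Determinism: identical config + seed reproduce byte-identical pipeline
  output directories.

## Known limitations

- One pair at a time; no joint modeling of larger protein complexes.
- Inherits instrumental-variable caveats: horizontal pleiotropy and sample
  overlap between training and GWAS cohorts bias estimates (overlapping
  sample ids trigger a warning, nothing more).
- The greedy pruner is a simple reference implementation, not a
  reproduction of any specific tool's pruning dialect; half-called
  genotypes and other tool-specific dosage encodings are out of scope.
- Stepwise variable selection for stage 1 is not implemented.
- theta_co is interpretable as the effect of genetically regulated
  co-expression only under the stated linearity and unit-variance residual
  assumptions; in product mode the estimand differs (it targets the
  interaction of observed expression).
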