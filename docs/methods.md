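# Methods

This note documents the models behind `crosstrait`, the choices made where
the design was genuinely open, and what the synthetic-data experiments do
and do not demonstrate about real data.

## The scientific setting

Two late-onset diseases — an ALS-like trait (lifetime risk K1 = 1/400,
liability-scale SNP heritability h2 = 8.2%) and a schizophrenia-like trait
(K2 = 1/100, h2 = 23%) — are modelled as binary outcomes of latent standard
normal liabilities. A genetic correlation r_g couples the per-variant effect
sizes of the two traits; the headline generating value is r_g = 14.3% with
confidence range (7.05%, 21.6%). The package answers four questions around
that estimate: how to obtain it from summary statistics (LD score
regression), what it implies for comorbidity (liability model), whether it
could be an artifact of misdiagnosed cases (misdiagnosis rate and the
cohort-heterogeneity test), and whether it can be leveraged for discovery
(conditional FDR, polygenic risk scores).

## LD score regression

The univariate model is `E[chi2_j] = a + N h2_obs ell_j / M`, where `ell_j`
is the sum of adjusted squared correlations `r2 - (1-r2)/(n-2)` over panel
variants within a map window (1 cM default; self term included). Estimation
is weighted least squares with weights
`1 / (max(ell_j, 1) * (a + N h2 ell_j / M)^2)` — the first factor discounts
over-counted high-LD variants, the second the heteroskedasticity of chi2 —
iterated twice from an unweighted pass. The constrained-intercept mode fixes
a = 1 (subtracting 1 from chi2 and fitting through the origin), appropriate
when confounding is otherwise controlled. Chi-square values above 80x the
mean are winsorized (with a logged count) to guard small synthetic panels
against single-variant leverage. Per-variant sample sizes enter through
their mean. Standard errors are leave-one-block-out jackknife over 200
contiguous variant blocks (configurable); for the genetic correlation the
entire three-regression statistic is recomputed per deleted block.

The bivariate regression `E[z1 z2] = c + sqrt(N1 N2) rho_g ell_j / M` has a
free intercept c that absorbs the null correlation induced by overlapping
samples (approximately `N_shared / sqrt(N1 N2)` for shared controls), which
is why the r_g estimate is robust to control sharing — a property the
acceptance suite checks directly at 20% sharing. Observed-scale and
liability-scale r_g coincide because the scale conversion factors cancel in
the ratio. Alleles are aligned by id, flipping the second trait's z where
effect/other alleles are swapped.

The observed-to-liability conversion is
`h2_liab = h2_obs K^2(1-K)^2 / (P(1-P) z^2)`, `z = phi(Phi^-1(1-K))`, with
sample case fraction P — exact for the score-test statistics the generator
produces.

## The synthetic generator and what it emulates

Two tiers:

* **Direct tier** (used for all regression-recovery experiments): per-SNP
  LD scores are drawn as `1 + Gamma(2, 2)` (mean 5), and z-score pairs come
  from the LDSC generative model itself, with variances
  `1 + N h2_obs ell/M`, covariance
  `sqrt(N1 N2) rho_g_obs ell/M + N_s/sqrt(N1 N2)`, at the real studies'
  N (36,052 / 79,845) and M = 50,000 SNPs. This tier verifies the estimator
  against its own generative assumptions at scale, in seconds.
* **Genotype tier**: haplotype panels with independent LD blocks (Poisson
  block sizes; within a block every variant shares one frequency and each
  haplotype copies its previous allele with probability `exp(-30 d_cM)`,
  giving monotone LD decay and exactly zero cross-block LD); individuals are
  formed by random haplotype pairing; liability = standardized-genotype
  score + normal residual of complementary variance; cases exceed
  `Phi^-1(1-K)`. Case ascertainment is rejection sampling with a budget of
  `500 max(n_cases/K, n_controls/(1-K))` draws. Population strata perturb
  panel frequencies by Balding-Nichols Beta draws parameterized by F_st,
  applied by flipping a matching number of haplotype alleles per column so
  within-block LD survives. Shared controls are literally the same rows in
  both cohorts.

Desk-scale genotype experiments use common-disease parameters (K = 0.1-0.2,
h2 = 0.3, hundreds of cases, a few hundred to 1,500 variants) so that
rejection sampling and dense linear algebra stay in milliseconds; the
acceptance experiments that target printed numbers use the direct tier at
the study's true N, K and heritabilities. What the passing tests show is
that the estimators recover their generating truths under the stated models;
they do not probe real-data complications — imputation error, allele
frequency/LD mismatch between panel and cohort, long-range LD, rare-variant
architecture — which the generator deliberately omits.

Association statistics are score tests: phenotype and standardized dosages
are residualized on covariates (plus intercept) and
`z_j = sqrt(df) * corr(x_j, y)`. Monomorphic variants are dropped with a
log record.

## Structure-preserving permutation

The permutation null shuffles case-control labels only within cubes of the
top-3 principal component space (equal-width bins per axis; bins per axis =
round(n_cubes^(1/3))), preserving global and per-cube case counts exactly.
Two desk-scale calibrations matter. First, the cube count must be well below
the sample size (default 64 cubes for ~1,000 individuals): with as many
cubes as individuals most cells are singletons and labels barely move.
Second, permuted-data heritability is only null when the association
statistics are structure-controlled, as in the original pipeline
(per-stratum association then meta-analysis); `permutation_null_h2`
therefore includes the top-3 PCs as score-test covariates by default. At
small M the leading PCs also absorb some genuine polygenic signal, so the
unpermuted fit with PC covariates is attenuated — irrelevant for the null
check, but worth knowing when reusing the helper.

## Liability-threshold comorbidity mathematics

The joint risk `P(L1 > t1, L2 > t2)` is a bivariate-normal orthant
probability computed as a one-dimensional integral of the conditional
survival function against the normal density (adaptive quadrature, absolute
tolerance 1e-10, finite upper limit t1 + 14 SD). The comorbidity odds ratio
comes from the implied 2x2 probability table and is symmetric in trait
order. Confidence ranges are plug-in: the r_g CI endpoints are propagated
holding both heritabilities fixed, which is how the parenthetical ranges
track the r_g interval.

With the point estimates h2 = (0.082, 0.23), r_g = 0.143, K = (1/400,
1/100): OR = 1.176, reciprocal joint risk 34,094, range 1.084-1.275. Two
printed reference values — the misdiagnosis rate 4.86% and the upper OR
bound 1.26 — correspond exactly to a schizophrenia h2 of ~0.21 rather than
the rounded 0.23 (the tests document this consistency); with 0.23 the
misdiagnosis formula `C/(C+1)`, `C = rho_g N_SCZ/N_ALS`, gives 5.08%, a
0.2-percentage-point difference. The implementation always computes from
the user-supplied inputs and does not special-case either value.

The required incident cohort size uses the one-sample binomial test of the
comorbid rate `P(trait2 | trait1) = p_joint/K1` against baseline K2,
one-sided alpha = 0.05 and power 0.80 by default (the sidedness is a flag:
the published description does not fix it). The normal-approximation sample
size is refined by an exact binomial power scan, requiring the power
condition to hold for a run of consecutive n because binomial power is
non-monotone in n; above five million the approximation is returned as-is.
The exact published cohort size (16,448) depends on an unpublished variant
of the power equation, so only the oracle agreement and monotonicity in
effect size are asserted.

## Conditional FDR

`cfdr_i = p1_i * #{p2_j <= p2_i} / #{p1_j <= p1_i, p2_j <= p2_i}`, ties
inclusive, clipped to `[p1_i, 1]` — the empirical-cdf estimator, chosen over
modelled mixture densities because it is exactly testable against a
double-loop oracle (a Fenwick tree gives O(M log M)). Conditioning
statistics are first residualized on LD score
(`chi2_resid = max(chi2 - slope*ell, 1e-8)`) so conditioning reflects shared
signal rather than shared LD; because a chi-square(1) has substantial mass
near zero, the floor keeps a fraction of the ell-dependence (the refit slope
shrinks by roughly half rather than vanishing — tested as such). Shared
controls are handled by null decorrelation
`z_adj = (z2 - c z1)/sqrt(1-c^2)` with c from the bivariate cross-intercept
or the design value `N_s/sqrt(N1 N2)`; the exact shared-control algebra of
the original method is unpublished, so this stand-in is validated by
calibration properties only. Loci are greedy clumps (ascending cFDR,
members at panel r2 > 0.1). Under independent null traits the discovery
rate at cFDR < q stays below q; with planted shared signal the estimator
is a discovery booster, not a strict FDR controller.

## Cohort-heterogeneity test

For independent risk alleles of trait A evaluated in trait-B cases, a
misdiagnosed subgroup induces positive pairwise dosage correlations; uniform
pleiotropy does not. The statistic sums case-minus-control correlation
differences scaled by `sqrt(N_eff)`, `N_eff = 1/(1/N_case + 1/N_ctrl)`,
with weights `w_ij = delta_i delta_j / sqrt(p_i q_i p_j q_j)`
(`delta = p_case - p_control` after risk-allele orientation, which flips
both frequencies and dosage coding); an alternative
`delta_i delta_j sqrt(p_i q_i p_j q_j)` scheme sits behind a flag. The
normalized sum is standard normal under the null; calibration is exact to
within finite-sample inflation that vanishes by n ≈ 1,000 per group, the
regime the tests use (the original application had ~28,000 cases). Risk
allele frequencies may come from cohort data or from effect sizes via
`p' = OR*p / (OR*p + 1 - p)`.

## PRS engine

Discovery variants are filtered (MAF >= 0.01, strand-ambiguous A/T-G/C
removed, optional INFO >= 0.3 when the column exists), clumped greedily in
two rounds (250 kb / r2 > 0.5 then 5,000 kb / r2 > 0.2) with ties in p
broken by (chrom, pos, id) so the result is order-independent, and scored at
twelve p-value thresholds as `sum(beta * dosage)` with mean-imputation of
missing dosages and allele alignment by sign flip. The explained-variance
increment is Nagelkerke's pseudo-R^2 of the full logistic model minus the
covariate baseline, with the intercept-only likelihood as the common
reference; the p-value is the Wald test of the score term (a likelihood
ratio alternative would be a one-line change; Wald matches standard GLM
reporting). Decile odds ratios use rank-based bins with stable tie-breaks
and decile 1 as reference. Covariates include principal components selected
by a joint logistic fit at p < 0.0005 (Bonferroni for 100 PCs); at desk
scale the monotonicity experiments disable PC selection since without
population structure the leading PCs only absorb polygenic signal. Desk
scale cannot reproduce the published 0.12% increment at N = 26,000; the
tests instead verify that the mean increment rises with the generating
genetic correlation over {0, 0.143, 0.5} and that label permutation drives
it to ~0.

## Numerical and interface choices

* All on-disk artifacts are tab-delimited text with a `#` header embedding
  the seed and a parameter hash; floats are written at 17 significant
  digits and read with round-trip parsing, so write/read is lossless.
* Positions are 1-based (BIM convention); internal intervals half-open.
* Degenerate inputs fail loudly with typed errors (parameter / generation /
  analysis) rather than returning defaults; a zero-variance risk score
  yields a zero increment with a missing p-value.
* The pipeline's comorbidity stage is parameterized by the configured
  architecture (not the noisy desk-scale r_g estimate) so reports are
  deterministic given the config; the estimate and its jackknife CI are
  reported alongside.

## Known limitations

No coalescent realism, no imputation/INFO modelling, no X chromosome, no
partitioned heritability, no conjunctional FDR, no age-structured
epidemiology. The jackknife SE is validated within a factor of 1.5 of the
across-replicate SD; at a few hundred SNPs (pipeline demo scale) the
bivariate r_g estimate is extremely noisy and only its CI behavior is
meaningful.
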