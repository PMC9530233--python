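# Methods

This note documents the models implemented in `agexpr`, the defaults and
numerical choices, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Synthetic cohort generator

The generator (`agexpr.simulate`) produces cohorts in which every
downstream estimate has a known ground truth.

**Genotypes.** Unlinked biallelic SNPs with allele frequencies uniform on
[maf_low, maf_high] (default [0.05, 0.5]); dosages are binomial(2, maf)
draws, i.e. Hardy–Weinberg equilibrium with no linkage disequilibrium or
population structure. Each gene gets its own block of SNPs placed within
±1 Mb of a nominal TSS on a single synthetic chromosome; genes are spaced
4 Mb apart so cis windows never overlap.

**Cohort.** Ages uniform on [20, 80] years (real donor-age distributions
are not uniform; uniform is a stand-in that covers the full decadal-bin
range evenly, not a claim about any cohort), sexes Bernoulli(0.5),
optional standard-normal batch covariates.

**Expression.** Per gene, with total variance normalized to 1,

    y = Σᵢ βᵢ xᵢ + β_age·A + β_agesex·(A·S) + (batch) + ε

where A is the cohort z-score of age and S binary sex. Coefficients are
rescaled against the *realized sample variance* of each predictor block
so that the requested variance fractions (h², R²_age, R²_agesex) are hit
exactly in-sample rather than only in expectation — this makes parameter
recovery tight at moderate n and is why the truth table records both
requested and realized fractions. The noise is Gaussian with per-sample
variance

    resid · max(1 + het_slope·A, 0.05),   resid = 1 − h² − R²_age − R²_agesex,

so `het_slope > 0` produces older samples with noisier expression. The
0.05 floor (5% of the baseline residual variance) prevents degenerate
near-zero-variance samples when |het_slope| is large. When a requested
age-slope sign is 0 but R²_age > 0 the sign is drawn at random.

**Constraint scores.** A pLI-like covariate is generated from a Gaussian
copula on the rank-normal scores of the generative age slopes, giving a
Spearman correlation with β_age close to the requested target (exactly
monotone at ±1; for Gaussian copulas the realized Spearman is
(6/π)·asin(ρ/2), e.g. 0.48 at ρ = 0.5, which is well within every test's
tolerance). Scores are mapped to [0, 1] by the normal CDF.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and tag-SNP structure
(lead-SNP selection is easier here than in real cis windows), population
stratification, non-uniform age distributions, count noise of RNA-seq
(expression is Gaussian on a normalized scale; the pipeline exponentiates
it into abundance space before JSD), trans effects, and cell-type
composition shifts.

## Preprocessing

- **Gene filter**: TPM > 0.1 in ≥ 20% of samples *and* ≥ 6 reads in
  ≥ 20% of samples (thresholds configurable). The TPM comparison is
  strict, the read-count one inclusive, following the stated
  inequalities. Synthetic cohorts carry no counts matrix; the read
  criterion is then skipped with a logged warning.
- **SNP filter**: MAF > 0.05 (strict) and Hardy–Weinberg χ² p > 0.05.
  The HWE test is a 1-df chi-square on hard genotype calls (dosages
  rounded to the nearest integer when no hard calls exist); the source
  analyses name the filter, not the test, so the standard biallelic
  chi-square was chosen. Monomorphic SNPs return p = 1 and are removed by
  the MAF criterion, not treated as errors.
- **Age groups**: old = age ≥ cutoff (default 55, the cohort median in
  the motivating data; 45/65 re-runs are a config change). Ties go to
  "old" per the ≥ convention. The larger group is downsampled uniformly
  without replacement, seed-deterministically.
- **Latent factors**: hidden expression covariates are computed as the
  top-k right singular vectors of the *age-residualized* expression
  matrix (each gene regressed on age first). Because every factor lies in
  the row space of the residuals, its Pearson correlation with age is
  zero to machine precision. This is a principal-component stand-in for
  PEER: the defining property being preserved — factors orthogonal to age
  computed on age residuals — is exactly the property tests can check;
  the variational-Bayes machinery of PEER itself is deliberately not
  re-implemented. Default k = 15. Only age is removed before the factor
  computation; other covariates enter later at the residualization stage.
- **Residualization**: per-gene OLS against an intercept plus covariates,
  computed via an SVD-orthonormal basis so collinear covariate columns
  are absorbed (with a warning) rather than failing the run.

## Young/old eQTL contrast

The lead SNP per gene is the marginal-regression minimum-p SNP on the
full (un-split) cohort, ties broken by lower position then lexicographic
id; both group fits then reuse that SNP so the contrast is paired on SNP
identity. Group fits are OLS of expression on dosage + covariates +
intercept; a constant dosage within a group is flagged and reported with
p = 1. The tissue-level contrast applies Welch's unequal-variance t-test
to the two groups' p-value sets after a −log₁₀ transform (p floored at
1e-300). The −log transform is an interpretation — "p-value
distributions" could also mean raw p — chosen because QQ-style
comparisons of heavy-tailed p-value sets operate on the log scale and raw
p is bounded and skewed; `transform="raw"` switches to raw p. Two
degenerate cases are defined rather than errors: identical constant
vectors give t = 0, p = 1 (no evidence), perfectly separated constant
vectors give p = 0 (infinite evidence); `welch_t` itself raises when both
samples have zero variance.

## Heterogeneity (JSD) and heteroskedasticity

Profiles are normalized to sum to 1 per sample (all-zero samples are
excluded with a warning). Entropy uses log₂ with 0·log 0 = 0, so JSD of
disjoint supports is exactly 1 bit; tiny negative rounding of the mixture
entropy difference is clipped at 0. √JSD is used as the distance
everywhere (it satisfies the triangle inequality; raw JSD is retained in
outputs). The six-bin slope pools within-bin pairwise √JSD values over
decadal bins [20,30) … [70,80] (last bin closed, out-of-range samples
dropped with a warning) and regresses them on the pair's mean age by OLS.

The per-gene heteroskedasticity test regresses expression on intercept +
age + covariates, squares the residuals, divides by their mean (the
divisor is the squared residuals' own mean, making the response mean 1 —
the exact divisor was not specified in the source description and this
choice makes β_het a relative-variance slope), and regresses the result
on *standardized* age so β_het is per-SD-of-age and comparable across
cohorts. Significance is the two-sided t-test on that slope; BH
adjustment across genes. The OLS t-test on squared residuals is only
asymptotically calibrated (squared residuals are skewed), which is why
the calibration benchmark checks the empirical type-I rate at n = 300
rather than assuming exactness. Proportion-valued inputs (cell-type
compositions) can be logit-transformed first via
`transform="invlogit_ready"`.

## Joint model and variance partition

Design: z-scored dosages of all polymorphic cis-window SNPs, the
cohort-z-scored age, and optionally the standardized age×sex column
(dropped with a warning when constant or collinear with age, e.g. in
single-sex cohorts). The penalized objective is

    min  (1/2N)·Σⱼ (yⱼ − β₀ − xⱼᵀβ)² + λ·(α‖β‖₁ + (1−α)/2·‖β‖₂²)

with α = 0.5 and λ selected by 10-fold cross-validation (shuffled folds
seeded for determinism) over a 100-value log-spaced path by minimum mean
squared error — no 1-SE rule, matching transcriptome-imputation
convention. The implementation is scikit-learn's coordinate descent,
whose objective is this exact parametrization; correctness is checked
against the closed-form soft-threshold/ridge-shrinkage solution on
orthonormal designs and the OLS limit as λ→0.

Each R² component is the squared Pearson correlation between observed y
and that block's linear predictor. The two-argument R²(·,·) notation and
per-block evaluation rule out a sum-of-squares decomposition (which is
not additive when blocks are correlated); the squared correlation is
also invariant to the elastic net's scalar shrinkage of a single-column
block, which is why R²_age recovery is essentially unbiased. A
variance-ratio variant (`r2_method="ratio"`) is available. The
environment component is 1 − h² − R²_age − R²_agesex floored at 0 (the
floor can bind due to rounding when components are tiny).

The two-group heritability contrast refits genetics-only models (no age
column — age is range-restricted within a group and would absorb genetic
signal) independently in the balanced young/old groups and reports
per-gene h²_young − h²_old.

## Downstream statistics

Tissue specificity S_g = Σ_t (1 − R²_t/R²_max)/(n−1); all-zero profiles
are undefined and raise. The constraint regression includes a gene only
when the relevant component is predictive (R² > 0; the age component for
β_age regressions, h² for h² regressions — the inclusion wording "age or
genetics" is ambiguous, so the component-matched reading is the default
and the column is configurable). Classification threshold p < 10⁻³;
top-expression-quartile exclusion is available as a robustness flag.
Mutation-frequency regressions require strictly more than 200 tumor
samples per gene. Pathway contrasts pool β_age over genes × tissues
within each class, t-test per pathway, BH across pathways, FDR < 0.01.

## Pipeline and seeds

`run_pipeline` executes synthesize/ingest → filters/groups → eQTL
contrast → JSD + heteroskedasticity → joint model → downstream, writing
TSV/JSON outputs plus a manifest (config, seeds, version, completed
stages). Every stochastic stage receives
`sha256(master_seed:stage_name) mod 2³¹`, so a master seed fixes the
whole run; identical configs produce byte-identical tables. `report`
refuses to summarize incomplete runs.

## Benchmark problem sizes

The self-validation benchmarks (`agexpr.benchmarks`, also behind
`scripts/acceptance.py`) use: 200 genes × n = 600 on the
{0, 0.1, 0.3}² (h², R²_age) grid for variance-partition recovery and for
the model-consistency correlations; 2000 homoskedastic null genes at
n = 300 and 200 heteroskedastic genes at n = 600 for test calibration;
50 replicate tissues of 200 genes at 300 samples/group (old slopes
halved, h²_young = 0.2) plus 200 null tissues for the eQTL contrast;
50 replicates × 1000 genes for Medawar classification; 1000 random
distributions/profiles/p-vectors for the oracle-equivalence checks.
These sizes were chosen as the smallest at which the targeted effects are
comfortably identified; the whole set completes in a few minutes on one
CPU.

## Known limitations

- Training-set R², as in the motivating analyses — not out-of-sample
  prediction accuracy; h² here is a predictive-R² analogue, not a REML
  estimate.
- No LD-aware lead-SNP logic; with real genotypes the lead SNP is a tag,
  not the causal variant.
- The heteroskedasticity t-test's finite-sample calibration degrades for
  very heavy-tailed expression noise.
- Squared-correlation block R²s can double-count variance when the age
  and genetic blocks are correlated by chance; the environment remainder
  absorbs (and is floored against) this.
- GSEA-style enrichment is out of scope: the per-gene tables exported by
  the pipeline are the ranked inputs an external enrichment tool would
  consume.
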