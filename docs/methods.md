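# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## The analysis in one paragraph

Annual ring series from a full-sib progeny trial are turned into
drought-response phenotypes (resistance, recovery, resilience of basal area
increment around discrete drought years) and dendroclimatic correlation
functions against standardized drought indices. Per-tree phenotypes then
enter an individual-tree ("animal") mixed model with either the pedigree
relationship matrix A (ABLUP) or the marker-based VanRaden matrix G
(GBLUP), giving variance components, heritabilities, genetic correlations,
and breeding values. Cross-validation measures predictive ability and
accuracy, and the accuracy ratio times the breeding-cycle-length ratio
gives the relative selection response of genomic over pedigree selection.

## Synthetic-trial generator

The generator is the package's substitute for unreleased field data; its
defaults define the study conditions and are chosen once.

- **Mating design.** Randomized round-robin pair selection among founders
  under per-parent usage bounds, retried up to 1000 times. The reference
  design (33 parents, 158 families, 1–7 trees per family) implies
  316 parent slots, which 33 parents can only cover with 9–10 uses each;
  when a requested usage band is aggregate-infeasible the generator falls
  back to the balanced floor/ceil band with a warning rather than failing.
- **Genotypes.** Founders drawn in Hardy–Weinberg proportions at per-SNP
  allele frequencies uniform on the configured MAF band; progeny by
  Mendelian gene dropping, SNPs unlinked. No linkage, no LD: GBLUP needs
  genome-wide relatedness only, and LD-based imputation is out of scope.
- **Breeding values.** Causal SNPs are sampled without replacement;
  per-SNP effect vectors are multivariate normal across traits and then
  linearly rescaled so the realized sample covariance of breeding values
  equals the target Σ_a exactly. This removes between-replicate variance in
  the simulated genetic variance; the identity BV = dosage × effects is
  preserved by applying the same transform to the effects. With few causal
  SNPs and small samples a single draw can align poorly with G (parameter
  recovery is a distributional property, not a per-seed one), which is why
  recovery checks run at ~600 individuals, thousands of SNPs and hundreds
  of causal loci, averaged over seeds.
- **Climate.** Monthly temperature follows a sinusoidal seasonal cycle
  around a boreal site mean (2.5 °C, amplitude 12.5 °C, latitude 63.55°);
  precipitation is gamma-distributed around a summer-peaked climatology
  (~600 mm/yr). In drought years May–September precipitation is scaled by
  0.35 and temperature raised 2 °C, emulating the 2002–2003 and 2006
  episodes.
- **Ring growth.** Ring width is
  trend(age) × exp(g_i + s·c_y + env_i + e_{iy}) × m_{iy}: a Hugershoff-type
  age trend (peak ≈ age 18, so the juvenile phase spans roughly the first
  15 years, matching the analysis' exclusion window), a standardized
  growing-season water-balance signal c_y (coefficient 0.25), a permanent
  per-tree micro-site effect (log-SD 0.35), AR(1) lognormal noise
  (φ = 0.5, innovation SD 0.25), and a drought-year multiplier with mean
  0.6, modulated by the tree's standardized resistance breeding value
  (slope 0.12, mean-corrected so the population mean multiplier is exactly
  the configured value). Recovery breeding values analogously modulate the
  first two post-drought years. The drought-severity → growth-reduction
  form is a modeling convenience; no field-data claim attaches to it.
  Slopes and noise scales were set so the emergent per-tree phenotypes
  carry low-to-moderate heritability (drought ratios ≈ 0.2, mean BAI
  ≈ 0.3, statics 0.4), the regime reported for such traits in conifer
  progeny trials. Note that realized drought growth reduction combines the
  climate-mediated response and the explicit multiplier; tests that check
  recovery of the multiplier constant disable the climate pathway.
- **What the generator does not emulate.** Spatial field structure,
  linkage/LD, selection or drift across generations, measurement error in
  wood anatomy, cross-dating errors. Passing tests show the pipeline's
  statistical machinery is correct under the stated model, not that real
  ring data meet these assumptions.
- **Reproducibility.** One master seed; each generator consumes a named
  substream (`substream(seed, "pedigree")`, …), so components are
  individually bit-reproducible.

## Drought indices

Thornthwaite PET uses the annual heat index from each calendar year's
monthly mean temperatures, the standard exponent polynomial, and day-length
correction from solar declination; PET = 0 at T ≤ 0 °C. The
high-temperature (> 26.5 °C) table branch is omitted as irrelevant for
boreal input. SPI fits a zero-inflated gamma (MLE on the positive part) to
scale-aggregated precipitation per calendar month; SPEI fits a
three-parameter log-logistic to precipitation − PET by unbiased
probability-weighted moments. Left-skewed monthly samples, for which the
PWM shape estimate is invalid, are handled by fitting the negated sample
and using the complementary CDF; degenerate (constant) samples yield a zero
index with a warning; if a fit remains invalid the Gringorten empirical
plotting position is used, again with a warning. The aggregation scale
defaults to 3 months (a seasonal window); the reference period defaults to
the full input span.

## Ring-series processing

- **BAI** from ring widths, pith-anchored by default; the bark-anchored
  mode subtracts widths inward from a supplied outer radius and equals the
  pith-anchored result when the radius equals the width sum.
- **Detrending** uses the discrete penalized second-difference smoother
  (the discrete cubic smoothing spline) with penalty
  λ = (2 sin(π/W))⁻⁴, which places the 50% frequency response exactly at
  the stiffness wavelength W (default 0.67 × series length). The index is
  raw/fitted with the fit floored at a small ε.
- **Prewhitening** fits AR(1) by conditional least squares on the centred
  index and returns residuals re-centred to the pre-fit mean; |φ| ≥ 1
  raises. The AR order is fixed at 1 by design; no order search.
- **Chronologies** are Tukey biweight means (tuning constant 9 × MAD,
  iterated to convergence) per group-year with recorded sample depth;
  years before a configurable start (default 1990) are dropped to skip the
  juvenile phase.
- **Drought response** windows default to 3 years pre and post around the
  drought years; the 2006 episode is excluded from the response traits by
  default (the reference window is 2002–2003). RL = RS × RC holds by
  construction and is asserted.
- **Climate–growth correlations** pair ring year t with months May–December
  of t−1 and April–September of t (lowercase/uppercase labels). The
  stationary bootstrap (geometric blocks, mean length 4 years, 1000
  replicates) is run twice: jointly resampled pairs give the coefficient's
  distribution, and independently resampled series realize its null law
  under no association while preserving autocorrelation. The reported
  interval is the basic-bootstrap CI built from the null percentiles
  shifted to the estimate, so "CI excludes zero" coincides with a test
  whose small-sample false-positive rate is near the nominal 5% — the
  plain percentile interval is markedly anti-conservative at ~22 years.

## Relationship matrices

QC drops SNPs by missingness (> 40%) and then by MAF (< 5%), in that
declared order. The simple mean/mode imputer is an explicit stand-in for
LD-based imputation. A uses the tabular recursion with unknown parents
contributing zero; G is VanRaden's first method with observed sample
allele frequencies (the standard choice; note this centring biases mean
relatedness slightly downward in family-structured samples). G is blended
as (1−w)G + wI (default w = 0.01; blending toward A is available since the
choice is unspecified in practice), verified positive definite by Cholesky,
with the condition number recorded.

## Mixed model

The univariate engine eigendecomposes K over phenotyped individuals; the
restricted likelihood then profiles analytically over the residual variance
and is maximized over the log variance ratio by a 61-point grid presearch
plus bounded scalar refinement (xatol 1e−10), making fits deterministic.
Missing phenotypes are excluded from the likelihood and predicted through
the mixed-model equations at the REML estimates — the cross-validation
masking mechanism. Prediction-error variances come from the inverse MME
coefficient matrix; h² standard errors from the delta method on the inverse
numerical Hessian (central differences, relative step 1e−5). Fixed effects
are intercept-only: phenotypes are assumed spatially pre-adjusted upstream.

The bivariate engine works on the same rotation; the likelihood decomposes
into per-eigenvalue 2×2 blocks, and the six parameters (two genetic
variances, r_a, two residual variances, r_e; log/tanh transformed with
correlations bounded at ±0.999) are maximized by Nelder–Mead with warm
starts from the univariate fits and the sample correlation, restarted up to
three times until the likelihood changes by < 1e−8. Likelihood-ratio tests
use the plain chi-square (1 df for r_a = 0, 2 df for r_a = r_e = 0),
matching standard practice even though correlation bounds can make the
boundary case conservative. With duplicated traits the likelihood has a
ridge; the correlation starts keep the optimizer on the r ≈ 1 solution.

## Evaluation

Cross-validation partitions are simple random (unstratified by family),
10 folds × 10 replicates by default; metrics aggregate fold → replicate
mean → mean ± empirical SE over replicates. PAC uses the GBLUP h² for both
models, deliberately preserving the cross-model convention even when it
inflates ABLUP's PAC. TAC is computed per validation individual within
folds for GBLUP, and from the full-data fit (no CV) for the ABLUP
benchmark; its SE is reported both over replicates and over individuals,
since the convention is ambiguous. Scenario cycles: backward selection
36 → 18/11 years, forward 21 → 18/11; efficiency is printed at one decimal
with unrounded internals.

## Problem sizes

The shipped study configuration uses 33 parents / 158 families
(~600 progeny), 3 000 SNPs with 500 causal, 10-fold × 3-replicate CV; the
test suite uses smaller designs (~300 progeny, 1–5 k SNPs) and seed-averaged
Monte-Carlo checks. These sizes are the package's default desk-scale
conditions; all operations scale to larger panels, with the REML engine's
cost dominated by one n×n eigendecomposition per fit.

## Known limitations

- Two traits maximum in the mixed model; no dominance, epistasis, spatial
  residuals, or Bayesian whole-genome regression.
- VCF support is deliberately minimal (diploid, biallelic, GT-only).
- The log-logistic PWM fit requires shape > 1; heavy-tailed or strongly
  skewed monthly samples fall back as described above.
- The A-matrix recursion is O(n²) dense — ample for progeny-trial scale,
  not for national evaluations.
- Pointer-year detection, cross-dating statistics and superposed-epoch
  analysis are out of scope.
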