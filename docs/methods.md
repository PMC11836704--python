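# Methods notes

This note records the models, conventions and numerical choices behind
`seedsmr`, including the places where the design was genuinely open and a
convention had to be fixed.

## Respirometry model

A sealed chamber of headspace volume *V* (µl) at temperature *T* (°C) and
ambient pressure *P* (kPa) holds *n* seeds.  Aerobic respiration removes
O₂ at a constant rate, so pO₂ declines linearly; the replicate-level
estimate is the OLS slope of pO₂ on time.

**Trace conditioning.** Fluorescence O₂ readings are noisy, so the signal
is smoothed with a centred moving average (default window 3).  Edges are
dropped rather than padded — padding would bias the slope at the
endpoints; the time stamps are averaged with the same kernel so a linear
signal remains exactly linear.  Readings after pO₂ first falls below a
fraction (default 0.8) of the initial value are discarded to avoid
hypoxic depression of metabolism; recoveries above the threshold are not
re-admitted, because a chamber that has gone hypoxic is physiologically
suspect from then on.  A replicate with fewer than 4 surviving points is
unusable.

**Slope → V̇O₂.** The ideal-gas mole-fraction conversion is

V̇O₂ = (−slope / P_dry) · V · 273.15/(273.15 + T) / n   (µl O₂ seed⁻¹ h⁻¹ STP)

with P_dry = P − SVP(T) − pCO₂, SVP the Arden-Buck saturation vapour
pressure (chambers are run near 100% RH, so the headspace is assumed
water-saturated).  Under the assumed respiratory exchange ratio of 1,
evolved CO₂ replaces consumed O₂ mole-for-mole and total pressure is
constant; when a measured pCO₂ channel exists it is subtracted from the
dry pressure, otherwise no CO₂ correction is attempted.  Instrument
pipelines differ in their exact STP conventions, so `slope_to_vo2` accepts
a user-supplied `stp_correction` hook replacing the temperature ratio.

**Outlier rule.** Microbial contamination typically inflates apparent SMR
and is often invisible.  Replicates are filtered by a single-pass 2-SD
rule on the species' replicate slopes, computed **leave-one-out**: each
replicate is compared with the mean and SD of the *other* replicates.
The pooled variant (mean and SD over all replicates including the
candidate) is provably unable to flag two or more equal contaminated
replicates out of ten — the deviation-to-SD ratio is bounded at
√((n−m)(n−1)/(m n)) < 2 for m ≥ 2, n = 10, independent of how extreme the
contamination is — so the leave-one-out form is used.  It keeps everything
when all slopes are identical, is permutation-invariant, and is not
iterated.  Under iid normal slopes its per-replicate exclusion probability
is 2·S_t(2√((n−1)/n); n−2) ≈ 0.094 at n = 10 (S_t the Student survival
function), which the test suite verifies by simulation.

**Aggregation.** Per-species SMR_t is the arithmetic mean of the kept
replicates' per-seed V̇O₂; the measurement temperature is the replicate
mean.  Standardization to 20 °C uses SMR₂₀ = SMR_t · Q₁₀^((20−T_t)/10)
with Q₁₀ = 2.5 by default — the conventional factor for carbohydrate-
oxidizing tissue in this temperature range.  The transform is exactly
invertible, which the generator exploits.

## Germination kinetics

Cumulative germination is fitted with the three-parameter log-logistic
curve f(t) = d / (1 + exp(b (ln t − ln e))): d is the upper asymptote (%),
e the inflection time (days), b < 0 a dimensionless steepness.  T₅₀ is
defined **relative to the fitted asymptote** (time to d/2, which equals e
under this parameterization), not as the time to 50% of sown seeds; the
two differ whenever d < 100, and the relative definition matches the
default ED behaviour of the standard dose-response packages.  Optimizer
starts: d₀ = max observed, e₀ = time of the observation nearest d₀/2,
b₀ = −2; d is bounded at 100.  All-zero germination has no defined curve
and is an error; non-monotone input (scoring noise) warns and proceeds.
G_max = 100 · germinated / (sown − cut-test dead): seeds with dead embryos
are removed from the denominator.

## Phylogenetic covariance, λ and K

The Brownian covariance C has C[i,j] = shared root-to-MRCA path length and
diagonal the root-to-tip depths (Myr; branch lengths are used as given, no
unit conversion).  Pagel's transform multiplies the off-diagonals by
λ ∈ [0, 1] and leaves the diagonal unchanged.

λ is estimated by maximizing the profiled Gaussian likelihood (mean and
variance profiled analytically) with bounded scalar optimization on
[0, 1], tolerance 1e-6; the interior optimum is compared against both
endpoints, so boundary ties are reported as boundary values.  Because the
nulls λ = 0 and λ = 1 sit on the boundary of the parameter space, the LRT
p-values use the 50:50 χ²₀:χ²₁ mixture; both tests are reported, since
"significant signal" can mean either rejection of independence or
rejection of pure Brownian motion.

Blomberg's K is the observed MSE₀/MSE ratio (mean squared deviation from
the phylogenetically corrected mean over the GLS mean squared error)
divided by its Brownian expectation (tr C − n/Σ C⁻¹)/(n−1); K = 1 under
Brownian motion.  Significance is one-sided (signal = large ratio) from
random tip-label permutations, default 999, with add-one smoothing and a
mandatory seed.  Both statistics are affine-invariant in the trait, which
the suite checks, and both are validated against `phytools::phylosig` to
numerical precision on a shared fixture.

## Allometric regression

OLS and PGLS share one GLS code path (OLS is the identity-covariance
special case, so the two coincide at λ = 0 on an ultrametric tree).  PGLS
coefficient estimation profiles λ by **REML** (less biased for variance
parameters); model comparison against OLS re-profiles λ at **ML**, because
REML likelihoods are not comparable across mean structures.  AIC counts
intercept, slope, σ² and (when estimated) λ, and includes the full
Gaussian constant — absolute AIC values therefore differ from conventions
that drop constants, and only ΔAIC between models on the same response is
meaningful.  Coefficient SEs use the REML σ̂² with n − 2 df; the PGLS fit
is validated against `nlme::gls` with `ape::corPagel` to 1e-6.

Residuals carried into the correlate analyses are **ordinary vertical
deviations** in log₁₀ units (observed minus fitted line), not
phylogenetically whitened: the scientific quantity of interest is how far
a species' SMR sits above or below the allometric expectation.  Whitened
residuals (L⁻¹e) are available behind a flag for model diagnostics.  The
PGLS "residual R²" is 1 − SSE_gls/SSE_null with the null being the
phylogenetic mean-only model under the same covariance.

The isometry test is a single-sample t: |1 − b̂| / SE(b̂) with n − 2 df,
two-sided.

## Residual correlates

Univariate screens are OLS regressions reported with F = t² (1, n−2 df);
a 0/1 domestication indicator makes the slope the crop-vs-wild mean
difference.  Direct trait comparisons between groups use Welch's
unequal-variance t with Satterthwaite df, since germination-trait
variances differ strongly between crops and wild species.

Climate classes are analysed twice: an unordered one-way ANOVA (classes
with fewer than 2 species dropped first — a singleton contributes no
within-group variance), and a single-df a-priori contrast for the monotone
aridity trend over the ordered classes (default Csa < BSh < BWh) using
centred equally-spaced coefficients on the group means with the pooled
ANOVA error term.  A forward-difference scheme is available behind a flag;
for three groups the average-successive-difference contrast coincides with
the linear one.  The single-df form is used because a monotone ordered
hypothesis is most powerfully tested with one trend degree of freedom.

The bioclim panel (15 variables) is reduced by backward elimination:
at each step the term with the largest type-III p-value above α_stay
(default 0.05) is removed and the model refitted, ties broken
alphabetically; for single-df continuous terms without interactions the
type-III F equals the squared coefficient t, which the suite asserts.
A p-value criterion (rather than AIC) was chosen as the elimination rule
as the most direct reading of "insignificant parameters removed".
Correlated covariates are retained by design — they can carry distinct
ecological effects — so the design matrix may be ill-conditioned; fitting
uses QR-based least squares and the condition number of the standardized
design is reported.  Exactly aliased columns are a hard error naming the
offending pairs.

## Synthetic data generator

The generator emulates the statistical structure of a comparative seed
energetics study; its defaults are the study-scale conditions used
throughout testing:

* **Tree** — birth–death (b = 0.1, d = 0.05 Myr⁻¹) conditioned on the tip
  count by resampling on total extinction, rescaled to height 160.5 Myr
  (an angiosperm-wide scale), 108 species by default.  Terminal edges are
  extended by a shared exponential waiting time before rescaling so the
  youngest divergence is strictly older than the present — otherwise the
  stopping-at-an-event convention leaves zero-length cherries and a
  singular covariance.
* **Traits** — log₁₀ mass is Brownian on the tree (tip mean 0.9, tip SD
  0.9 log₁₀ mg: a few-mg median spanning roughly four orders of
  magnitude); log₁₀ SMR₂₀ = log₁₀(0.057) + 0.75·log₁₀M + ε with ε
  multivariate normal, covariance σ²·λ-transform(C), σ = 0.5, λ = 0.6.
  Measurement temperatures are uniform on 18–30 °C and the generated
  at-temperature rate is the inverse-Q₁₀ image of SMR₂₀, forcing the
  pipeline to re-standardize.
* **Traces** — 30-min sampling over 24 h, pO₂₀ = 20 kPa, Gaussian reading
  noise SD 0.05 kPa.  Seeds per chamber (1–150) are chosen so the clean
  decline sits near 0.12 kPa h⁻¹ (≈3 kPa over a day, safely above the
  hypoxia cutoff); very large seeds get a proportionally larger chamber
  instead, mirroring the practice of matching chamber size to seed size.
  The clean slope is the exact algebraic inverse of the pipeline's
  conversion, so noiseless recovery is exact by construction — the
  noiseless test checks the inverse identity, not numerical luck.
  Contamination multiplies a replicate's slope by 5 with probability 0.2
  (or for an exact 20% of replicates when configured), emulating microbial
  respiration.
* **Germination** — each seed germinates with probability d/100 at a
  log-logistic time (b ∈ [−5, −2], d ∈ [40, 100], e ∈ [4, 14] days for
  wild species, [2, 5] for crops), scored cumulatively every 3.5 days for
  8 weeks, 50 seeds per species.
* **Status and climate** — 14 crops and 7 weeds per 108 species,
  assignment shuffled so status is independent of the tree.  Crops carry a
  +0.5 log₁₀ SMR shift.  Native species get an ordered climate class
  (Csa/BSh/BWh with probabilities 0.55/0.08/0.37 and shifts
  0/0.25/0.5 log₁₀ units) and a 15-variable bioclim panel that is
  block-correlated (temperature block and precipitation block, ρ = 0.7
  within blocks) with annual mean temperature causally linked to the
  residual (0.2 log₁₀ units per SD).  All shifts are folded into the
  measured rates, so they flow through the whole chain.

What the generator does **not** emulate: real climate geography (bioclim
values are exchangeable Gaussians, not raster extractions), measurement
drift or instrument recalibration, dormancy heterogeneity within a seed
lot, phylogenetically structured domestication, or mass-measurement error.
Passing tests therefore demonstrate that the estimators recover the
generating process under the stated noise model — not that any particular
field dataset satisfies that model.

## Problem sizes and reproducibility

The calibration suite and `scripts/acceptance.py` use 50 twenty-tip
instances for the estimator-exactness oracle, 100 datasets of 108 species
for slope/λ recovery, 100 two-hundred-tip replicates per condition for
signal calibration, 2000 replicates for the type-I error rates, and 30
species × 10 chambers for respirometry recovery — sizes at which the
Monte-Carlo standard errors are comfortably inside the asserted bands.
Every stochastic step takes an explicit seed; the pipeline is a pure
function of (inputs, config, seeds), and identical reruns produce
byte-identical outputs.

## Known limitations

* The λ transform is the standard tip-variance-preserving form; λ > 1 and
  non-ultrametric λ variants are out of scope.
* The hypoxia rule keys on the first reading of the (smoothed) trace; a
  grossly aberrant first reading shifts the threshold.
* Backward elimination inherits the usual caveats of stepwise selection
  (post-selection p-values are optimistic); it is provided as the
  screening tool it is, not as causal inference.
* `compare_models` with a REML-profiled fit will understate the PGLS
  likelihood; the pipeline re-profiles at ML for comparisons, and direct
  users should do the same.
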