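# seedsmr — the metabolic energetics of seeds

`seedsmr` is a Python toolkit for the comparative analysis of seed standard
metabolic rate (SMR): the minimum aerobic metabolism of quiescent,
fully hydrated (but not germinating) seeds, measured as oxygen consumption
V̇O₂ in µl O₂ seed⁻¹ h⁻¹ at STP.  It is aimed at seed ecologists and
comparative physiologists who want to go from raw closed-system
respirometry traces and a time-calibrated phylogeny to allometric
coefficients, phylogenetic-signal statistics and ecological correlates of
metabolic residuals.

## The analysis it implements

Metabolic rate scales with body mass as a power law, **MR = a·M^b**, with
*b* ≈ 0.75 across most plant and animal groups (allometry) rather than
*b* = 1 (isometry).  The package implements the complete chain needed to
estimate and interrogate this relationship for seeds:

1. **Respirometry** — each chamber's pO₂ trace is smoothed with a
   three-point moving window, truncated once pO₂ falls below 0.8 of its
   initial value (hypoxia guard), converted to a slope (kPa h⁻¹) by OLS,
   and transformed to V̇O₂ at STP via the dry-gas mole fraction
   (total pressure minus water vapour, RER assumed 1).  Replicates whose
   slope falls more than 2 SD from the other replicates of the same species
   are excluded — microbial contamination inflates apparent SMR.
2. **Q₁₀ standardization** — rates measured at species-specific optimal
   temperatures (18–30 °C) are standardized to 20 °C with
   SMR₂₀ = SMR_t · Q₁₀^((20 − T_t)/10), Q₁₀ = 2.5.
3. **Allometry** — OLS and PGLS regressions of log₁₀ SMR₂₀ on log₁₀ dry
   mass.  PGLS uses the Brownian covariance **C** from the tree with
   Pagel's λ scaling the off-diagonals, λ estimated by REML profile on
   [0, 1]; a single-sample t-test decides allometry (*b* ≠ 1) vs isometry;
   AIC / likelihood-ratio comparison of the two models.
4. **Phylogenetic signal** — Pagel's λ by maximum likelihood (with boundary
   LRTs against λ = 0 and λ = 1) and Blomberg's K with a tip-permutation
   test, for both log mass and log SMR.
5. **Germination kinetics** — three-parameter log-logistic fits
   f(t) = d / (1 + exp(b·(ln t − ln e))) of cumulative germination,
   yielding G_max (final % of viable seeds) and T₅₀ (time to half the
   fitted asymptote, = e).
6. **Residual correlates** — the PGLS residuals (vertical deviations in
   log₁₀ units, independent of mass and phylogeny) are screened against
   germination traits, a crop-vs-wild contrast, Köppen-Geiger climate
   classes (one-way ANOVA plus a single-df a-priori aridity-trend
   contrast Csa < BSh < BWh) and a 15-variable bioclim panel via backward
   stepwise regression with type-III F statistics.

A synthetic-data generator (`seedsmr.simulate`) produces every input the
pipeline consumes — birth–death trees, λ-structured traits, raw pO₂ traces
that invert the respirometry math exactly, binomial germination counts and
block-correlated climate covariates — so the whole chain is testable
offline and parameter recovery is measurable against known truth.

## Worked example

Generate a synthetic study (60 species, true b = 0.75, λ = 0.6) and run the
full pipeline:

```bash
seedsmr simulate --seed 42 --n-species 60 --outdir demo
cat > config.yaml <<EOF
inputs:
  tree: demo/tree.nwk
  traits: demo/traits.csv
  traces: demo/traces.csv
  germination: demo/germination.csv
options: {n_perm: 499, seed: 1}
output_dir: demo_results
EOF
seedsmr run config.yaml
```

which prints (abridged):

```json
{
  "ols":  {"intercept": -0.617, "coef_a": 0.242, "slope": 0.816,
           "se_slope": 0.097, "r2": 0.544, "n": 60},
  "pgls": {"intercept": -0.573, "coef_a": 0.267, "slope": 0.788,
           "se_slope": 0.124, "lambda": 0.281, "r2": 0.411, "n": 60},
  "isometry_test": {"t": 1.908, "df": 58, "p": 0.0614}
}
```

Read: the fitted OLS power law is SMR₂₀ = 0.242·M^0.816; accounting for
phylogeny (PGLS, λ̂ = 0.28) flattens the exponent slightly to 0.788 and
widens its standard error from 0.097 to 0.124, so at n = 60 this synthetic
draw cannot quite reject isometry (p = 0.061).  `demo_results/` also holds
`smr_table.csv` (per-species SMR₂₀ recovered from the raw traces),
`signal_stats.json` (λ and K for both traits), `residuals.csv` (the PGLS
vertical deviations) and `correlates.csv` (a tidy factor × slope × F × p
table of the residual screens).

The same stages are importable directly:

```python
from seedsmr import fit_pgls, pagel_lambda_ml, process_traces, q10_correct
```

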