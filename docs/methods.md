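# Methods

`nutflex` implements a complete analysis chain for studies of macronutrient
regulation and metabolic flexibility in wild primates: habitat fruit
availability → daily macronutrient intake → urinary biomarkers of metabolic
state.  This note records the models, their assumptions, the defaults, and
the design decisions taken where more than one defensible choice existed.

## Data model

**Fruit availability.** The fruit availability index (FAI) for a calendar
month is the percentage of monitored phenology trees bearing fruit.  Months
are split into *low* and *high* fruit periods at the median FAI over a
reference span; months exactly at the median are labelled low (a
deterministic, scarcity-conservative tie rule).

**Intake accounting.** Daily intakes are carried in kcal for available
protein, total nonstructural carbohydrates (TNC), lipid and neutral
detergent fiber (NDF).  Non-protein energy is NPe = TNC + NDF + lipid, and
total energy is protein + NPe (an exact bookkeeping identity, tested on
every simulated day).  When intakes are built from feeding records, kcal =
dry grams × nutrient fraction × a kcal/g factor; the factors default to
4 / 4 / 9 / 1.6 (protein / TNC / lipid / NDF, the fermentable-fiber
convention for NDF) and are explicit configuration, since published
conversion conventions vary between food-composition pipelines.

**Urine cleaning and matching.** Urinary analyte concentrations scale with
hydration, so concentrations are corrected to a reference specific gravity:
`corrected = value × (SG_ref − 1)/(SG − 1)` with SG_ref = 1.023.  Samples
with SG < 1.002 are excluded *before* correction (the correction diverges
as SG → 1; exclusion-first is the only numerically safe order).  Duplicate
assays with a coefficient of variation above 15% have that analyte voided
(strict inequality on both boundaries; a software pipeline cannot re-assay,
so "rerun or drop" collapses to drop).  δ15N is an isotope ratio, not a
concentration, and is never SG-corrected.  Colorimetric ketone readings
collapse to presence/absence with *trace* counted positive by default
(dipsticks detect only acetoacetate and miss mild ketosis, so any colour
change is treated as a detection; a switch restores the stricter rule).
Each sample is matched to the same individual's feeding follow exactly one
day before collection, and only full nest-to-nest follow days are eligible;
unmatched and partial-day samples are dropped and counted.

## Protein-prioritization power law

The protein-leverage diagnostic fits

    log %P_ij = c + a_j + L·log E_ij + ε_ij,
    a_j ~ N(0, σ_a),  ε_ij ~ N(0, σ_e),

where %P is percent energy from protein, E total daily energy, and j
indexes individuals.  L = −1 is complete protein prioritization (constant
absolute protein), L = 0 is no proportional regulation.  The fit is on the
log-log scale: the power function is exactly linear there and intake noise
is multiplicative.  Priors are deliberately vague and overridable:
c ~ N(0, 5) on centered data, L ~ N(0, 2), both SDs half-Normal(0, 1).

Because the hierarchy is Gaussian-Gaussian, the random intercepts are
integrated out analytically (per-group covariance σ_e²I + σ_a²11′ has
closed-form determinant and quadratic form), so the sampler explores only
(c, L, σ_a, σ_e); intercepts are reconstructed afterwards from their
conditional Gaussian.  This marginalisation is exact and removes the
funnel geometry that otherwise slows ensemble mixing.  With random slopes
enabled the deviations are sampled explicitly (non-centered).

R² is the Bayesian fitted-variance ratio per posterior draw,
var(fitted)/(var(fitted)+σ_e²), reported as mean and 95% interval.

## Robust correlation

Concurvity screening among intake variables (and among biomarkers) uses a
multivariate Student-t model: y_i ~ MVT(ν, μ + α_j, S) with
S = diag(σ)·R·diag(σ), variable-specific random intercepts per individual,
LKJ(η = 2) prior on R, half-Normal(0, 1) on σ after per-variable
standardisation, and ν ~ Gamma(2, rate 0.1) shifted above 2 so the
covariance exists.  R is parameterised through C-vine canonical partial
correlations (tanh-transformed to the real line); the vine construction
guarantees every posterior draw of R is positive definite, and the implied
LKJ marginals are verified against their closed-form Beta moments by
quadrature in the tests.  Random intercepts are variable-specific (one
α per individual per variable); whether they should instead be shared
across variables is not determined by the screening purpose, and the
variable-specific form is the more flexible default.

## Bayesian penalized-spline GAMMs

Each response is regressed on one predictor through a low-rank penalized
thin-plate smooth (default k = 10), with fixed covariates entering
linearly and a maximal random-effect structure (random intercept plus
random slopes on the predictor and covariates per individual).  Families:
Gaussian (identity), log-normal and gamma (log link), Bernoulli (logit).
One nutritional predictor per model; correlated predictors are fitted in
separate models rather than jointly.

The basis is built from the cubic radial function |x−x′|³ on the distinct
predictor values (quantile-thinned above 400 knots), projected orthogonal
to the constant+linear null space and eigen-truncated to the leading k−2
energy eigenvectors.  Columns are rescaled by the inverse square root of
their penalty eigenvalues (then to unit RMS), which turns the wiggliness
penalty into an identity prior precision: spline weights are d ~ N(0, τ²I)
with τ ~ half-Normal(0, 1) as the smoothing prior, and the constant and
linear trend remain unpenalized.  Fixed coefficients get N(0, 5) priors;
Gaussian responses are standardized internally so those scales are
meaningful; random-effect SDs are half-Normal(0, 1) (sampled as |t| with t standard
normal); the spline weights are non-centered (d = τ·d_raw); the gamma
shape and the Gaussian/log-normal dispersion are sampled on the log scale
with weakly-informative initialisation from moment estimates.

"Distributional" regression is location-only by default (constant
dispersion); an optional linear model on the log dispersion in the
predictor can be enabled per model.  Family selection for a new response
compares Gaussian, log-normal and gamma candidates by AIC, with gamma
parameters from the method of moments (shape = mean²/var, rate = mean/var).

Random slopes on covariates that are constant within individual (sex) are
retained under the maximal-structure default and absorbed by
regularisation; they are identifiable only through the prior, and can be
dropped via `random_slopes=()`.

## Derivative-based region detection

For each fitted smooth, first derivatives are estimated per posterior draw
by forward finite differences: evaluate the smooth on a grid, shift the
grid by ε = 1e-4 × (grid range), difference, divide.  Grid points where
the central 95% interval of the slope draws excludes zero are flagged, and
contiguous runs of flagged points with a common sign become *credibly
non-flat regions* (increasing/decreasing).  Intervals are pointwise, not
simultaneous — the literal rule, with no multiplicity adjustment across
grid points; simultaneous bands would be a stricter extension.  The
default grid is 200 evenly spaced points over the observed predictor
range.  Against closed-form derivatives of polynomial test smooths the
finite differences are accurate to <1e-3 at the default ε, and region
boundaries land within one grid step of analytic sign changes.

## Posterior computation

Inference runs on an affine-invariant/differential-evolution ensemble
sampler (emcee) over an unconstrained parameterisation (log scale for
likelihood dispersions, |t| half-normal coordinates for hierarchical
scale parameters, tanh for partial correlations), with vectorised
log-posteriors.  Hierarchical blocks are non-centered, and between
ensemble segments a pair of likelihood-invariant rescaling MH moves
(an interweaving, ASIS-style update along the exact (scale, raw) ->
(g*scale, raw/g) symmetry) decorrelates scales from their raw
coordinates, removing the funnel geometry.
Walkers play the role of chains: rank-normalised split-Rhat and bulk/tail
ESS are computed across walkers with arviz, and a fit is flagged
non-converged when any Rhat ≥ 1.01.  There is no Hamiltonian dynamics, so
the divergence count is always zero; PSIS-LOO Pareto-k diagnostics are
computed from pointwise log-likelihoods on a draw subsample.  Named run
profiles: `test` (4000 ensemble sweeps, 2000 warmup) and `paper` (7000
sweeps, 3500 warmup, mirroring the long-run convention for this kind of
analysis).  Models with many latent coordinates mix more slowly in an
ensemble sampler than in gradient-based samplers, so the hierarchical
GAMMs default to a 6× longer run and hierarchical correlation fits to 4×;
ensembles start from overdispersed, moment-centered clouds (a point-mass
start would collapse the ensemble's proposal scale).  Fixed seed plus
fixed data gives bit-identical chains.

## Synthetic-data generator

The generator is the test bed standing in for field data.  It emulates:

* **Phenology** — a monthly FAI process (annual sinusoid + AR(1) noise +
  occasional fruiting spikes, clipped to 0.6–13.8%), realised by fruiting
  exactly the rounded target number of randomly chosen trees so monthly
  FAI stays inside the observed 0.5–14% range.  Defaults are calibrated so
  the median split gives low/high period means near 2.44%/6.68%.
* **Intake** — log E = log(P_ref + NPe_link(FAI)) + u_j + e with a
  saturating logistic NPe link (1770→2450 kcal, midpoint FAI 4.2), and
  log %P = log %P_ref + L(log E − log E_ref) + a_j + ε, so the
  prioritization exponent is exact by construction.  Scenarios:
  `complete_prioritization` (L = −1), `partial_prioritization` (L = −0.73,
  the study-like default), `no_prioritization` (L = 0), `flat_null`
  (L = 0 and all links flat).  Noise SDs (0.30 on log E, 0.19 on log %P,
  individual SDs 0.13/0.09) give marginal CVs near 40% for NPe and ~23%
  for protein, the regime in which recovery tests at n ≈ 1600 are
  informative.  Defaults land mean %protein-energy at ~10.1, mean NPe:P
  near 9.7 and a between-period caloric increase near +19%.
* **Biomarkers** — C-peptide log-normal with a saturating energy link,
  urea gamma (shape 4) with a declining-in-TNC log-mean, δ15N Gaussian
  rising when TNC is low, ketone presence Bernoulli with a logit declining
  in both the prior day's TNC and the month's FAI (detectable ketosis
  tracks sustained scarcity, and the presence/absence model being
  emulated carries FAI as a covariate) with the intercept calibrated at
  truth-construction time so marginal positivity is 9.2% and the
  low/high-period split of positives lands near 6.6%/2.6% of samples.  All biomarker locations carry
  per-individual random intercepts.  Urine concentrations are multiplied
  by (SG−1)/(SG_ref−1) with SG ~ truncated-Normal(1.023, 0.009, >1), so
  the SG correction inverts the dilution exactly and ~1% of samples fall
  below the SG 1.002 exclusion; assay CVs are gamma-distributed with ~2%
  exceeding the 15% filter.
* **Ground truth** — every generating parameter lives in `SimTruth`,
  including the correlation matrix of log intakes (measured on a large
  internal reference draw at truth construction, so it is the exact
  marginal estimand of the correlation model) and is serialisable to YAML
  for truth-vs-estimate reporting.

Determinism: one master seed; each table derives its own stream by a fixed
spawn key, so identical (config, truth) reproduce byte-identical CSVs.

**What the generator does not emulate.** Spatial tree structure, masting
dynamics, social behaviour, assay plate effects, isotope drift, and — by
default — within-individual day-to-day autocorrelation of intake (an AR(1)
option exists, default 0, since the field literature does not pin the
value).  Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed statistical structure, not robustness to
every feature of real field data.  The paper-reported period contrasts in
NPe:P (8.5 → 11.6) sit slightly outside what a single exact power-law
generator can produce jointly with a +19.2% energy contrast and
near-constant protein; the defaults match those contrasts directionally
within ~20%.

## Problem sizes used in the tests

The suite runs everything at desk scale as a design choice: the analytic
benchmark at 40 individuals × 40 days; exponent recovery over 20
replicates at ~1600 follow-days; correlation recovery at ~800 days; smooth
recovery at ~600–1100 matched samples; shared session fixtures avoid
refitting the GAMMs per test.  The `paper` sampler profile and full-size
runs are available through the same interfaces.

## Known limitations

* The ensemble sampler trades gradient information for simplicity; very
  high-dimensional maximal GAMMs mix slowly and can sit marginally above
  the Rhat 1.01 gate at the default run length.  Fits report this honestly
  via their `converged` flag rather than loosening the gate.
* Supplementary-material model details that the main analysis text does
  not fix (whether FAI enters biomarker models as a second smooth, random
  slopes in the power model, which distributional parameters were
  modelled) are implemented as documented defaults with switches:
  FAI enters linearly, the power model uses random intercepts, and
  dispersion is constant unless requested.
* FAI weights all fruiting trees equally (no fruit-biomass weighting).
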