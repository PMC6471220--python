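# Methods

## Scope and data model

The package analyses zebrafish whole-feed trials in which a maize component
is substituted into an experimental diet. The housing unit — a tank of 20
fish, 10 per sex — is the biological replicate and the experimental unit for
all group-level inference. Input tables are plain CSV with fixed units
(g, mm, mg, days) and no automatic unit conversion; missing values are empty
cells and propagate as missing, never as zero, because pooled-sample assays
can fail independently of each other. Validation is total: a trial either
loads with every invariant satisfied (positive weights and lengths, unique
(fish, day) pairs, every tank mapped to exactly one existing diet) or
raises. Sex is mandatory on fish and organ records because somatic indices
are analysed per sex; endpoint rows carry a sex-stratum of `male`, `female`
or `pooled`. Column dictionaries are in `column_dictionaries.md`.

## Endpoint definitions

**Length–weight allometry.** `W = a·L^b` is fitted to all fish of a trial
at day 0 by ordinary least squares on `log W` vs `log L` — the standard
fisheries treatment, corresponding to a multiplicative error model with a
closed-form solution, which makes downstream condition factors exactly
reproducible. At least 10 fish and non-zero length variation are required;
exponents outside 2–4 are flagged but not rejected. A consequence of the
log-log fit used in testing: the geometric mean RCF of the fitting
population is exactly 1.

**Relative condition factor.** `RCF = W/(a·L^b)`; 1 means the fish sits on
the population curve. Invariant under jointly rescaling `W` and `a`.

**Absolute growth rate.** `AGR = (mean final − mean initial fork length)/t`
per tank, in mm/day, from the first to the last measurement day. Because
tank means are used, AGR's statistical unit is the tank by construction.

**Somatic indices.** `HSI`/`GSI` = 100 × pooled organ weight / summed body
weight of the same 10 fish, reported in percent (the convention in the fish
literature; the index is scale-invariant either way).

**Diet energetics.** Gross energy = `(17.5·C + 24·P + 39.5·L)/100` kJ/g
from the g/100 g composition — a fixed linear combination, so it is exactly
homogeneous in composition. Coefficients of variation use the n−1 sample
SD. In the packaged composition report, macronutrient CVs are computed from
the composition cells directly, while the gross-energy CV is computed from
the 1-decimal-rounded energy values, matching how published composition
tables display that row (computing it from unrounded energies shifts the
dose-series value from 4.5 % to 4.6 %).

**Nutrient uptake.** Apparent uptake = `100·(1 − fecal mass/one-day feed
mass)` per macronutrient; the raw feces-to-feed ratio is also exposed. A
fecal mass exceeding the feed dose yields a negative uptake, which is
flagged rather than clipped — it is physically possible with carry-over and
should be visible. Uptake is computed per collection event; averaging
across events is left to the caller. The daily feed dose defaults to 2.5 %
of the tank's total initial wet weight.

## Group statistics

Replicate-level endpoints (AGR, somatic indices, uptake) are tested by
one-way ANOVA on tank values. Individual-level endpoints (RCF, length) use
the nested mixed model: diet fixed, tank random nested in diet, tested with
`F = MS_diet / MS_tank(diet)` on (a−1, T−a) degrees of freedom. For
balanced data this is algebraically identical to ANOVA on tank means (the
test suite asserts the identity to 1e−10); testing fish directly against
the residual would be anticonservative because tankmates are correlated —
the simulation suite shows the naive test more than doubles its nominal
type-I error at a moderate tank variance while the nested test holds 5 %.

Dunnett's many-to-one procedure compares each diet to the 0 %-substitution
control. The k contrasts share the control group, giving the product
correlation `corr(T_i, T_j) = λ_i λ_j` with `λ_i = sqrt(n_i/(n_i+n_0))`
(equicorrelation ½ in balanced designs). Two-sided adjusted p-values are
`P(max_j |T_j| ≥ |t_i|)`, evaluated by deterministic quadrature: an 80-node
Gauss–Hermite integral over the shared control deviate inside an adaptive
integral over the pooled scale (chi with N−k−1 df). The same machinery
yields critical values by root-finding. With k = 1 the computation reduces
to the Student t-test to ~1e−12; for k = 5, ν = 12 the two-sided 5 % critical
value is 2.901, matching classical tables, and the quadrature agrees with an
independent QMC multivariate-t evaluation to ~1e−3 and with a 400,000-rep
Monte Carlo of the max-|t| tail to MC precision. The classical
homoscedastic (pooled-variance) form is used; a Levene pre-check logs a
warning on heteroscedasticity but never switches to a Welch variant
silently. The significance threshold is 0.05 throughout, two-sided.

Dose–response is summarised by Pearson correlation between substitution
percentage and tank endpoint values; diet formulation quality by an
unpaired pooled-variance t-test of the 0 % diet against the commercial
control.

## Equivalence testing

The distribution-wise equivalence criterion asks whether a test–control
difference is small relative to the *natural response variation*: the
spread of the endpoint across feeding groups given different non-GM
reference varieties of the same crop.

**Variance components.** The reference model is
`value = μ + variety + trial + tank(variety×trial) + ε` with independent
zero-mean random effects, fitted by REML (statsmodels MixedLM; Powell
search with tight tolerances, gradient fallback — the profiled surface of
these small models defeats line-search methods surprisingly often).
Components are non-negative by construction; boundary estimates are logged
because truncation distorts the EL. With a single reference trial — the
common case, and the design simulated here — the trial component is
confounded with variety; it is reported as 0 with an explicit flag and the
limitation is logged in the report. Tank-level endpoints report the
between-tank variance as `σ²_tank` with zero residual. In balanced designs
the REML solution coincides with the expected-mean-squares estimator, which
the tests use as an independent oracle (to 1e−6; the optimizer floor is
~3e−8).

**Equivalence limit.** `EL = multiplier × sqrt(σ²_variety + σ²_trial)` —
the SD of endpoint means across reference populations. The default
multiplier 1 mirrors the widely used one-SD convention while staying
configurable; a `fixed` mode using one sample SD of the raw reference
values is available for comparison with fixed-limit practice. A zero EL
raises rather than silently degenerating.

**Scaled difference and CI.** The contrast estimate is
`(mean_test − mean_control)/EL` with a 95 % t-interval from the pooled
between-tank variance (df = n₁+n₂−2). By default the EL is treated as a
fixed scale — the conventional reading of an EL-scaled forest plot. An
optional Satterthwaite correction folds the delta-method variance of the
estimated EL (an SD from `n_varieties` population means, relative variance
≈ 1/(2(n_varieties−1))) into the interval via an effective df; it is off by
default because it mixes reference and trial uncertainty in a way the
fixed-EL display does not. The estimate is exactly antisymmetric under
swapping the groups and invariant under rescaling all values and the EL
together.

**Classification.** Proof of equivalence: CI ⊂ (−1, +1). Equivalence more
likely than not: estimate inside, CI outside. Equivalence not likely:
estimate outside [−1, +1], CI overlapping. Proof of non-equivalence: CI
entirely outside. An estimate exactly on ±1 is treated as not inside. The
verdict is monotone in CI width at fixed estimate: shrinking a CI can never
move a result away from the proof categories. Non-proof is never treated
as disproof.

**Stratification.** Sex-specific endpoints (HSI, GSI, organ energy
reserves) are tested per sex-stratum, with the EL derived from the matching
stratum of the reference data; other endpoints are pooled. Endpoints
missing from the reference data are reported as per-endpoint errors without
aborting the rest of the report.

## Synthetic data

The generator reproduces the hierarchy the analysis assumes. Defaults are
the study conditions: 3 tanks per diet group, 20 fish per tank (10 per
sex), substitution levels 0–25 % in 5 % steps plus a commercial control,
10 reference varieties at 15 % substitution, 2.5 %/day ration, 28-day dose
trials. Day-0 lengths are Normal(34 mm, 2.5 mm); weights follow
`W = 1.05e−5·L^3` with 13 % lognormal scatter (a ~34 mm, ~0.42 g adult).
Dose-trial injections: AGR slope −0.002 mm/day per % substitution and a
male-HSI slope of 0.012 %-points per % in the range-finding design, both
zeroed under *Artemia* supplementation (the live feed rebalances the diet);
carbohydrate uptake declines 0.35 %-points per % substitution from an 85 %
baseline.

Reference/case-study endpoints each carry a noise family chosen for their
support — normal for lengths and distances, lognormal (additive effects on
the log scale) for strictly positive endpoints like somatic indices and
energy reserves, binomial on the logit scale for offspring rates — with
variety, trial, tank and fish SDs on the link scale. The default
between-tank SD is 0.4 × the between-variety SD for every endpoint: with 3
tanks per group this makes 95 % CIs broad relative to the EL range (half
width ≈ 0.9 EL even under exact equivalence) while keeping ~95 % of null
point estimates inside (−1, +1) — the replication realism the equivalence
analysis must confront, chosen analytically from the t-interval geometry
rather than fitted to any test outcome. The three case-study arms share one
mean (near-isogenic material; no variety-level draw separates them), and
`arm_shifts` displace an arm by a chosen number of EL units — a GM-only
shift emulates a transgene effect, a shift shared by GM and NS a
transformation-process effect. Case-study values are emitted at tank level;
fish-level averaging is considered already absorbed into the between-tank
SD.

Randomness comes from one seeded root stream split hierarchically
(design → endpoint → tank), so a (config, seed) pair fully determines every
value and adding fish does not perturb tank-level draws.

What the generator does *not* emulate: real assay error structure
(between-batch drift in the Bradford/anthrone/lipid chemistry), mortality
and sampling attrition, correlations between endpoints within a tank, or
multi-trial reference designs with estimable trial variance (supported by
the fitter, but the packaged designs are single-trial). Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the assumed hierarchy, not that real trials satisfy that hierarchy.

## Numerical choices and test problem sizes

- Dunnett quadrature: 80 Hermite nodes, adaptive outer integral split at
  the chi mode, absolute tolerance 1e−11; critical values by Brent
  root-finding to 1e−10.
- REML: Powell, maxiter 5000, xtol/ftol 1e−12; `cg`/`lbfgs` fallback.
- CSV floats are parsed with round-trip precision so write→read→write is
  byte-stable; this is what makes run manifests digest-reproducible.
- Half-up rounding to one decimal for composition-table display.
- Calibration checks use 5,000 null replicates for the nested-ANOVA size
  and 20,000 for the Dunnett family-wise error (the FWER simulation is
  vectorised, so the larger size is cheap and tightens the Monte Carlo
  error well inside the ±0.008 acceptance band). Variance-component
  recovery at 50 varieties × 10 tanks × 5 fish is assessed on the mean of
  12 replicate fits, because a single dataset of that size carries ~21 %
  sampling SD on the variety variance — no estimator could meet a 15 % band
  per seed; the averaged check is a bias test at the design's size.
  CI coverage uses 2,000 replicates; the contrast-pattern check uses 12
  seeded case studies against 12 seeded reference datasets.

## Known limitations

- The EL rests on the variety component alone whenever the reference data
  come from one trial; between-trial variation in such data is invisible
  and the EL is accordingly optimistic. The report flags this.
- The Satterthwaite EL-uncertainty correction is a delta-method
  approximation, untested against a gold standard beyond its limiting
  behaviour; it defaults to off.
- Nested ANOVA for unbalanced data uses the standard moment-based F
  approximation rather than a likelihood-ratio test.
- Lognormal endpoints receive EL-unit shifts multiplicatively (exact on the
  log scale); for the small sigmas used this matches the raw-scale shift to
  first order but is not identical.
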