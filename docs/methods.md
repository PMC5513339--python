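# Methods

## The problem being simulated

A prognostic model is developed in a treatment-naïve cohort to predict an
individual's probability of a binary outcome *in the absence of* a
particular risk-lowering treatment — the quantity used to decide whether
to start that treatment. At external validation time some individuals in
the validation cohort have received the treatment. Their observed
outcome frequency is then lower than their untreated risk, so the model
appears to overestimate risk (calibration bias), and if treatment is
concentrated in high-risk individuals the observed risk distribution is
compressed, which also depresses observable discrimination. The package
simulates this situation under controlled data-generating mechanisms and
evaluates the analysis strategies meant to undo it.

## Data-generating model

Each individual carries three independent predictors X1, X2, U drawn
from N(0, 0.2) — configs store the SD, `sqrt(0.2) ≈ 0.447`, to avoid
silent variance/SD confusion. The untreated risk is

    Risk = expit(β0 + β1·X1 + β2·X2 + βu·U),

with default coefficients (−1.50, 1, 1, 0), giving a population outcome
incidence of ≈20% and an attainable c-index of ≈0.67. U is never
available to any fitted model; scenarios with βu > 0 make it an
unmeasured confounder of treatment and outcome.

Treatment allocation is either random, `P(Tr) = p`, or logistic in the
*true* untreated risk, `P(Tr) = expit(b·Risk − a)`. The allocation model
is evaluated at the true generating risk (not a fitted estimate), as the
scenario definitions are written in terms of Risk; the `(a, b)`
parametrization keeps the scenario tables' printed numbers verbatim in
the configs. Fifteen built-in scenarios cover: a moderate risk-allocation
association (the default, a = 1.95, b = 10, ~50% treated); randomized
allocation; a risk-dependent treatment effect; a near-deterministic
18%-risk treatment threshold (a = 18, b = 100 — a practical positivity
violation); treated fractions of 25%/50%/75% crossed with treatment odds
ratios 0.8/0.5/0.3; and an unobserved predictor with βu ∈ {1, 2, 4}
(allocation intercepts 1.90/1.80/1.55 as the scenario table prints them,
holding ~50% treated). Empty cells inherit scenario-1 defaults. The
expected treated fraction is stored as documentation and verified
empirically in tests; it is an emergent property of the allocation model,
never enforced.

Treatment multiplies a treated individual's outcome *odds* by `OR_Tr`:
`risk_observed = expit(logit(Risk) + log OR_Tr)`. `OR_Tr` is constant, or
(scenario 3) `OR_Tr(Risk) = 1/(1 + exp(c + d·Risk))` with (c, d) =
(−1, 5), a protective effect that strengthens with risk, evaluated at the
true risk.

### Potential-outcome coupling

Both the counterfactual untreated outcome and the observed outcome exist
for every simulated individual. By default one shared uniform deviate per
individual thresholds both risks, so a protective treatment can only
switch an outcome from 1 to 0. The coupling leaves every marginal
distribution — hence every estimand reported here — unchanged; what it
adds is a per-row testable monotonicity and lower Monte-Carlo variance of
within-replicate contrasts. Independent redraws are available via
`couple_outcomes=False` and are verified to preserve marginals.

### Random-number discipline

All randomness derives from one master seed through labelled substreams
(`SeedSequence` spawn keys hashed from hierarchical labels such as
`scenario_1/rep42/val/outcomes`). Any single replicate is reproducible in
isolation, and scenarios can be run in any order, or alone, with
identical results.

## Fitted models

All fits are maximum-likelihood logistic regressions through a single
kernel (IRLS via statsmodels GLM/binomial) with relative convergence
tolerance 1e-8 and a 100-iteration cap (both configurable). Degenerate
outcomes raise immediately; (quasi-)complete separation is converted to a
structured error carrying iteration diagnostics. The prognostic model
regresses the untreated outcome on X1 and X2 in the development cohort —
matching the generating model's observable part; U is unobservable by
design, which for scenarios 13–15 makes the prognostic model marginally
(not conditionally) calibrated.

The propensity model regresses the treatment indicator on, by default,
the prognostic model's *predicted untreated risk* as a single covariate.
The generating allocation is logistic in the true risk, so this choice
makes the fitted propensity form match the generating form up to
estimation error; with a large validation set it recovers the generating
allocation coefficients. A `raw_predictors` alternative (X1, X2 entered
linearly) is provided, and run manifests record which was used. This was
a genuinely open design point: a propensity model written as linear in
the predictors cannot be exactly correctly specified when allocation is
logistic in `expit`-transformed predictors; the risk-scale default
resolves the tension in favour of correct specification.

Two updating procedures are implemented for completeness and labelled
non-recommended in output: intercept recalibration (intercept-only refit
with the original linear predictor as offset — by the score equation the
recalibrated mean prediction equals observed incidence, driving O:E to 1
by construction and thereby *masking* the very mis-calibration being
measured) and treatment-indicator refits (offset variant keeping the
original coefficients, or a full refit; no treatment-by-predictor
interactions — the simulated effects are constant on the odds scale
except scenario 3, and interactions are out of scope).

## Weights

Untreated individuals receive `w = 1/(1−PS)`: the weighted untreated
subset then stands in for the full (untreated-counterfactual) cohort, and
with true propensities the weights over the untreated sum back to the
cohort size (Horvitz–Thompson mass, tested at n = 10^6 within 2%). The
IPW-only strategy also needs weights for treated individuals; the
standard inverse-probability-of-received-treatment form `1/PS` is used
there. Truncation caps weights at a percentile (default 98th) of the
weight distribution *among the individuals entering the analysis* — i.e.
after excluding the treated for the exclude-variants — matching the
estimator actually evaluated; truncation never increases a weight and the
100th percentile is the identity. Weights are used raw: both metrics are
invariant to rescaling all weights by a positive constant (tested to
1e-12), so normalization would be cosmetic; raw values are kept for
diagnostics.

## Metrics

The weighted c-index assigns each (event i, non-event j) pair the mass
`w_i·w_j`, counts tied predictions one half (standard c-statistic
convention), and is computed by an O(n log n) rank/cumulative-sum
algorithm; an exhaustive O(n²) pair loop is retained as a test oracle,
and unit weights are verified to reproduce ROC AUC exactly. The O:E
ratio is the ratio of weighted means `Σw·y / Σw·p` (not a mean of
per-individual ratios). Calibration curves use ten equal-mass quantile
bins of the weighted predicted-risk distribution — deterministic and
exactly testable against a direct group-by — with bin merging (and a
warning) when distinct predictions run out; a Nadaraya–Watson smoothed
variant exists for plotting only. Undefined metrics (no events or no
non-events with positive weight) are flagged at the replicate level and
excluded from summary means, with flag counts reported; at 20% incidence
and n = 1000 such replicates are vanishingly rare.

## Monte-Carlo design and problem sizes

A replicate = fresh development cohort (n = 1000, untreated) + fresh
validation cohort (n = 1000, ~treated per scenario) + model development +
strategy evaluation; the propensity model is fitted once per replicate on
the full validation cohort and shared by the three IPW variants (fit PS →
weight → exclude → truncate). Summaries report the mean and SD of each
metric's replicate distribution. The package's default reproduction runs
use 1,000 replicates per scenario, for which the Monte-Carlo standard
error of a reported mean is SD/√1000 ≤ 0.005 for every table entry —
small enough to compare against 10,000-replicate reference means to ±0.01 — and a
15-scenario run completes in a few minutes on one CPU; replicate counts
are a parameter, and 10,000-replicate runs simply scale linearly. Pooled
calibration curves accumulate analysis rows across blocks of n = 1000
validation individuals, refitting the development model per block
(pooling N individuals is therefore equivalent to combining N/1000
replicates), with 10^6 pooled individuals as the default: decile bins of
the *weighted* untreated subset thin out in the high-risk tail, and 10^6
keeps that tail's Monte-Carlo noise well below the mis-calibration
signals being compared.

## What the simulations do and do not show

The generator emulates the core mechanism — a single, binary,
point-in-time, effective treatment whose use may depend on true risk —
under exactly known models. It does not emulate: censoring or
time-to-event outcomes; correlated or non-normal predictors; treatment
nonadherence or time-varying treatment; multiple concurrent treatments;
or model misspecification of the prognostic model beyond the omission of
U. Conclusions about the strategies therefore carry over to real
validation studies only insofar as those features do not dominate; in
particular the IPW results assume the propensity model can be correctly
specified from measured data, which scenarios 13–15 deliberately break.

## Numerical and degenerate-input conventions

- IRLS convergence: relative tolerance 1e-8, max 100 iterations.
- Propensity scores of exactly 1 (untreated) or 0 (treated) raise a
  positivity error naming the individual; near-one scores produce the
  large-but-finite weights the positivity-violation scenario is designed
  to exhibit.
- Percentile truncation interpolates linearly between order statistics
  (`numpy.percentile`), computed over masked weights only.
- Quantile bin edges come from weighted midpoint-interpolated quantiles;
  duplicate edges are merged with a warning.
- Single-replicate runs report SD = 0 with a warning rather than NaN.
- Replicates whose development fit fails are flagged and counted, never
  silently resampled.
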