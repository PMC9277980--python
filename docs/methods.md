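# Methods

This note documents the models, conventions, and numerical choices behind
discountkit, and what the synthetic-data tests do and do not establish.

## Adjusting-amount staircase

Within one delay condition the immediate offer starts at half the delayed
amount A (so $1000 for A = $2000) and is adjusted by A/4, A/8, … — up after
a "delayed" choice, down after an "immediate" one. The procedure is a
binary search on the subjective value of the delayed reward. After the
t-th choice the pending offer equals the amount a (t+1)-th trial would
present; after all 6 choices that pending amount **is** the indifference
point (one extra application of the adjustment rule, not an average of the
last two offers).

Consequences used throughout the tests:

* every reachable estimate is an odd multiple of A/2^(t+1) ($15.625 at the
  defaults), so currency arithmetic is exact in binary floating point and
  equality checks are exact;
* for any deterministic threshold responder with true value v strictly
  inside (0, A), |estimate − v| ≤ A/2^(t+1);
* the (choice sequence → amount sequence) map is pure, so a trial table can
  be replayed and verified bit-for-bit (`staircase.replay_frame` does this
  whenever AuC is scored from trials).

Delays are labelled ("1 week" … "10 years") and mapped to days with the
astronomical averages 1 month = 30.4375 d and 1 year = 365.25 d. Only the
AuC normalization consumes these values; the staircase never does. The
convention is configurable per `DelayCondition`.

An agent exactly indifferent between the two offers chooses the delayed
reward. This tie-break is deterministic and measure-zero under any
continuous model of subjective value; it only matters for lattice-aligned
synthetic agents.

Missing or extra responses within a condition are refused (`StateError`)
rather than imputed: a partial staircase does not identify an indifference
point on the same lattice.

## Simulated responders

Agents combine a discount model — hyperbolic V = A/(1+kD), exponential
V = A·e^(−kD), or hyperboloid V = A/(1+kD)^s — with a choice policy.
The deterministic policy thresholds on V; the logistic policy chooses the
immediate reward with probability sigmoid((immediate − V)/τ). Noise acts on
the currency difference, so the temperature τ is a dollar scale and the
policy converges to the threshold rule as τ → 0. The discount rate k is
per day. These agents are testing infrastructure: the analysis itself is
deliberately model-free (AuC), and no discounting model is ever fitted to
scored data.

## AuC

Indifference points are normalized — delay by the longest task delay
(3652.5 d), value by A — and integrated by the trapezoid rule. A (0, 1)
anchor point is prepended by default so the curve spans the whole unit
interval and a never-discounting responder scores exactly 1; because the
anchoring convention is not universal, it is a flag and both variants are
exercised in the tests. AuC is invariant to rescaling of currency and of
time, and strictly increasing in every indifference point.

## Questionnaires, exclusions, vaccination coding

GAD-7 and PHQ-9 items (0–3) are summed per scale after range validation
(missing items are an error, never zero). The distress index is the sum of
the two sample-standardized totals: mean 0 by construction, standard
deviation sqrt(2+2r) where r is the correlation between the totals, and
invariant to affine rescaling of either raw scale. Because the
standardization is sample-level, the index is only defined for a cohort,
not for an individual in isolation.

Exclusions are applied in a fixed precedence order — ineligible, incomplete,
missing vaccination status, more than one failed attention check (one
failure is retained), excluded country — and a row failing several rules is
counted under the first. The precedence is a documented package convention;
the counts are provably independent of row order. The four-level
vaccination status maps {full, partial} → vaccinated and both unvaccinated
levels → unvaccinated.

Education enters the regression as a single ordinal numeric term (1–3);
gender is stored for descriptives but is not a predictor. Predictors are
used on their raw scales — an income coefficient is "per point of the
0–100 scale" — and no standardization is applied before fitting.

## Severity index

The six metrics are z-scored with the n−1 denominator, making the SVD
decomposition identical to an eigendecomposition of the correlation matrix
(λ_j = s_j²/(n−1), Σλ = p). Components with λ > 1 are considered reliable
(the threshold is an argument; note that for finite samples of independent
columns the leading sample eigenvalue sits slightly above 1, so literal
retention failure requires raising the threshold). The SVD leaves the sign
of each component arbitrary; the index fixes the gauge by requiring a
positive PC1 loading on deaths per 100k, so higher scores always mean a
more severe situation.

Rows may be unique country-weeks or one row per participant (each
participant contributing their country's record for their survey week);
the participant mode — the default in the pipeline — weights country-weeks
by how many participants they cover. The index is descriptive: country
random intercepts absorb country-level effects in the regression, so the
severity score is deliberately not a predictor.

## Multilevel logistic regression

The marginal likelihood integrates the country intercepts out of the
Bernoulli likelihood. With the Laplace approximation, for group j with
mode û_j of the penalized log-likelihood and W_j = Σ p(1−p) at the mode,

    log L_j ≈ l_j(û_j) − û_j²/(2σ²) − ½ log(1 + σ² W_j).

Numerics:

* inner problem: scalar Newton per group, vectorized across groups, step
  clipped to ±5, converged to |step| < 1e-10 (the penalized likelihood is
  strictly concave in each u_j);
* outer problem: L-BFGS-B over (β, log σ), gradient tolerance 1e-6,
  followed by up to three Newton polish steps using central-difference
  gradient/Hessian, which brings exact invariances (predictor shifts and
  rescalings) to ~1e-9. The objective is a pure function of the parameters:
  inner modes are never warm-started across outer evaluations, because the
  resulting hysteresis corrupts finite-difference line searches;
* boundary: estimates with log σ ≤ −4 (σ² ≲ 3e-4, ICC < 1e-4) are treated
  as a collapse to zero variance — the singular-fit convention — and the
  model is refitted as a pooled logistic regression with analytic standard
  errors, flagged on the result;
* standard errors: square roots of the diagonal of the inverse numerical
  Hessian over (β, log σ); if the log σ direction is too flat to invert
  stably, the β block is inverted instead (Wald SEs conditional on σ̂).

Inference follows the Laplace-GLMM conventions: Wald 95% intervals
exp(β ± 1.96·SE), normal-reference p-values for z = β/SE, ICC =
σ²/(σ² + π²/3) — reported for both the full and the intercept-only model,
since the two differ and published single values are ambiguous about which
model they describe (σ² = 1.54 corresponds to ICC 0.319) — and a
likelihood-ratio χ² with df = number of dropped fixed effects.

Two independent checks guard the implementation: an adaptive Gauss–Hermite
quadrature evaluator (15 nodes, centered and scaled at the per-group mode)
of the same marginal likelihood, which agrees with the Laplace
log-likelihood to ≲0.1 on ~500-row cohorts, and lme4's `glmer` (via
Rscript), which agrees to ~1e-3 on coefficients and ~2e-3 on σ².

## Synthetic cohort

The generator draws, per participant: country (13 countries with linearly
graded weights 0.5–1.5), age = 18 + lognormal(2.2257, 0.72) (mean ≈ 30 y),
ordinal education with probabilities (0.30, 0.51, 0.19), income =
100·Beta(1.6, 2.4) (mean ≈ 40, SD ≈ 22), essential worker ~ Bernoulli(0.22),
and a discount rate k ~ lognormal(−6.5, 1.6). The k defaults were chosen so
the implied AuC distribution matches published cohort descriptives for this
task (mean ≈ 0.40, SD ≈ 0.25). GAD-7/PHQ-9 items come from a one-factor
model: a latent distress factor feeds two scale latents (shared variance
0.8), each item loading 0.85 with thresholds (0.35, 1.1, 1.8). The
vaccination outcome is Bernoulli with

    logit p = −2.50 + 0.04·age + 0.27·education + 0.004·income
              + 0.58·essential + 0.001·distress + 0.53·AuC + u_country,

u_country ~ N(0, 1.54). These generator coefficients are the fixed-effect
estimates of the reference analysis, so recovery tests target realistic
effect sizes; the near-zero distress coefficient is kept deliberately, so
the expected "distress is not a unique predictor" outcome emerges honestly
rather than being forced. The AuC entering the linear predictor is the
staircase-measured one (the covariate the analysis sees); with the default
deterministic agents it deviates from the analytic curve AuC by at most
the lattice resolution and correlates with it > 0.99.

All randomness descends from one root seed through named `SeedSequence`
streams (demographics, task, items, outcome, epi), so regeneration is
byte-identical and stage-level reproducibility can be asserted on file
hashes (the CLI manifest does exactly that).

The epidemiological table gives each country a persistent severity level
plus a smooth random-walk severity wave; weekly cases and deaths are
rounded lognormal functions of that shared severity, cumulative columns are
exact running sums, and per-100k columns are cumulative counts scaled by
population. Two consequences are worth stating plainly: the cumulative
consistency identities hold exactly, and a dominant PC1 exists (checked
> 0.5 of variance), but the exact PC1 share of the realized table is
emergent rather than dialed — a count-valued series cannot simultaneously
be an exact equicorrelated factor draw and an exact cumsum of another
column. The exact factor algebra (population PC1 share (1+5a²)/6, equal to
0.635 at loading a = √0.562; share 1.0 at a = 1) lives in the latent
primitive `factor_model_matrix`, which the severity tests use directly.

**What the generator does not emulate:** correlated demographics (age,
income, and education are drawn independently, unlike any real cohort),
country-specific vaccine rollout calendars, panel-platform sampling quirks,
item-level response styles, or real epidemiological trajectories. Passing
tests therefore establish that the pipeline's arithmetic, filtering, and
estimation behave correctly under the assumed structure — not that the
substantive findings would replicate in new human data.

## Simulation sizes used by the test suite

Chosen as the package's own balance of statistical resolution against run
time, and stated here so results are interpretable:

* staircase bisection bound: 1,000 deterministic agents, uniform true values;
* GLMM recovery: 50 cohorts of n = 4,000 (13 countries) at the generator's
  default coefficients; the AuC coefficient must fall inside its 95% Wald
  interval in ≥ 90% of replicates;
* Wald coverage: 200 cohorts of n = 2,000; empirical coverage within ±4
  percentage points of 95%;
* null calibration: 200 cohorts of n = 800 with all coefficients and the
  random-intercept variance set to zero; the 6-df LRT statistic must pass a
  Kolmogorov–Smirnov test against the central χ²₆ at p > 0.01;
* end-to-end sign structure: 20 cohorts of n = 4,000; all five positive
  generator effects must be recovered with positive signs in ≥ 95% of runs.

## Known limitations

* The Laplace approximation biases σ² slightly downward for few, small
  groups; the AGQ evaluator quantifies the likelihood error but the fitter
  does not switch to quadrature automatically.
* Wald intervals are used throughout (their exp-transform matches the
  reference reporting convention); profile-likelihood intervals are not
  implemented.
* The exclusion precedence for multiply-disqualified participants is a
  package convention; published reports rarely state theirs.
* `verify_osf.py` requires the user to map the archived deposit to the
  documented schema; column names in such deposits vary and no automatic
  mapping is attempted.
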