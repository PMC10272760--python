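# Methods

This note documents the statistical model, the estimation machinery, the
synthetic-cohort generator, and the numerical and design choices behind
`neurotraj`, at the level of detail a maintainer or reviewer needs to judge
what the package's passing tests do and do not establish.

## The trajectory model

Each region is modeled independently (univariate models). Subject `i`'s
measurements follow the population curve after an affine time warp,

    y_ij = f( e^{ξ_i} (t_ij − τ_i) + t0 ) + ε_ij,

with Gaussian priors `ε ~ N(0, σ_ε²)`, `τ_i ~ N(t0, σ_τ²)`,
`ξ_i ~ N(0, σ_ξ²)`. The onset age `τ_i` is the age at which the subject
crosses the reference value `p0`; `e^{ξ_i}` is the progression pace. The
logistic family is

    f(u) = 1 / (1 + (1/p0 − 1) exp(−v0 (u − t0) / (p0 (1 − p0)))),

the unique logistic with asymptotes {0, 1}, `f(t0) = p0`, `f′(t0) = v0`;
the affine family is `p0 + v0 (u − t0)`. All ages are in years; feature
values are normalized units (after preprocessing, a bounded range
approximately [0, 1]).

### Identifiability and gauge structure

Two exact redundancies exist and are fixed by construction rather than left
to the priors:

* **(v0, ξ) rescaling.** `v0 → c·v0, ξ_i → ξ_i − log c` leaves every
  prediction unchanged. After each sampling sweep, `mean(ξ)` is absorbed
  into `v0`, keeping the sampled log-paces centered (the zero-mean prior
  then holds by construction).
* **p0 is pure gauge.** The three-parameter logistic above is a
  two-parameter family: `f(u) = sigmoid(a(u − t0) + logit p0)` with
  `a = v0/(p0(1−p0))`, so moving `p0` merely relabels which point of the
  curve is "the reference". After each M-step the model is re-expressed at
  `p0 = 0.5` with the exact prediction-preserving compensation
  `τ_i ← τ_i − Δ/(a e^{ξ_i})`, `Δ = logit p0 − logit 0.5` (analogously for
  the affine family). Without this, `t0` drifts ~1.5 y along the flat ridge
  and is no longer comparable to a generating value. With the gauge fixed,
  `τ` always means "age at crossing mid-range", which is the natural
  reference for min-max-normalized data.

The data-attachment term does not depend on `t0` at all (the warped
argument reduces to `e^{ξ}(t − τ)`); `t0` is identified solely as the prior
mean of the onset ages.

Hyperpriors on the fixed effects are weak Gaussians (sd 10 on `t0`, sd 1 on
`logit p0` / `log v0`, sd 1 on the log standard deviations), centered at the
data-driven initialization; they keep the MAP proper and otherwise act as
mild regularizers.

## Preprocessing

Fixed order: additive field-strength bias correction → single-pass
three-sigma outlier removal (plain mean/sd per region) → min-max
normalization (min/max taken after outlier removal, so the [0, 1] asymptotes
are not set by artifacts) → orientation flip `x ↦ 1 − x` for regions whose
pooled within-subject slope on age is negative (cortical thickness and
volumes decrease; the logistic family is increasing). The fitted parameters
are stored in a `NormalizationRecord` that re-applies to new data and
inverts exactly on retained points; the whole pipeline is idempotent.

The bias correction shifts 3T values within each diagnosis group so that
per-group per-region means match the 1.5T mean. Note its sampling error is
of order `value_sd · sqrt(2/n_scans)`: at a few hundred scans of a
high-variance feature it can exceed a small true offset and inject a common
within-subject field-strength jump. That is acceptable for association
analyses (it is covariate-independent) but contaminates fine model
comparisons, which is why the family-selection study below disables scanner
effects; cohorts at the scale of real multi-site studies (thousands of
scans) do not have this problem to the same degree.

## Calibration (MCMC-SAEM)

Per iteration:

* **S-step.** One Metropolis-within-Gibbs sweep: Gaussian random-walk
  proposals for every subject's `τ` then `ξ`, accepted against the complete
  log posterior. Proposal sds are per-subject and adapted every 25
  iterations toward 30% acceptance during burn-in, frozen afterwards.
* **SA-step.** Sufficient statistics `(mean τ, mean τ², mean ξ², mean sq.
  residual)` updated with step `ε_k = 1` during burn-in, then
  `(k − k_burn)^{−γ}` with `γ = 0.65` (Robbins–Monro condition
  `γ ∈ (0.5, 1]` enforced).
* **M-step.** Closed-form updates of `t0, σ_τ, σ_ξ, σ_ε` from the
  stochastic statistics, each blended with its hyperprior through a
  pseudo-count of weight 1 (there is no closed-form MAP under the
  half-Gaussian log-sd prior; with hundreds of subjects the blend is
  numerically indistinguishable from the ML update). `(p0, v0)` take a
  damped quasi-Newton step (three L-BFGS iterations from the current point,
  halved) on the penalized data attachment, followed by the gauge fixes
  above.

Initialization is data-driven: `t0` = mean visit age, `p0 = 0.5`,
`v0` = pooled within-subject slope (floored at 1e−4/y), `σ_ε` = pooled
residual sd, `σ_τ` = sd of visit ages, `σ_ξ = 0.5`; each subject's `τ`
starts at the age where its own mean-level line of slope `v0` crosses `p0`
(clipped to `t0 ± 3σ_τ`). Starting all onsets at `t0` instead leaves
far-onset subjects a ±14-year random walk to travel and some chains do not
arrive within the default run length.

Defaults: 2000 iterations, 1000 burn-in, seed mandatory. Convergence is
reported (not asserted) as the sd of each fixed-effect trace over the final
200 iterations; divergence raises with a trace dump.

### Individual parameters

After the chain finishes, the per-subject posterior means and variances of
`(τ, ξ)` under the fitted fixed effects are computed by **adaptive 2-D
quadrature**: a 141 × 81 grid spanning ±4 prior sd locates each subject's
posterior, then a second grid covering the located mean ±6 posterior sd
integrates it. The refinement matters when `σ_τ` is large and individual
posteriors are sharp (grid rounding otherwise dominates). These posterior
means replace the stochastic-approximation averages (kept as `*_sa`
columns): averaged correlated sampler states carry Monte-Carlo noise that
costs 0.03–0.06 of recovery correlation relative to the exact posterior
mean, which we verified against the minimum-MSE bound computed by the same
quadrature at the *generating* fixed effects.

`personalize` (new subjects, frozen fixed effects) is a deterministic
multi-start MAP: Nelder–Mead from the prior mode and its ±1-sd neighbors
(9 starts), ties broken toward the smaller `|ξ|`.

## Association analysis

Per region and parameter (`τ`, `ξ`): OLS on `[1, female, APOE-ε4 count,
education years]`, two-sided t-tests with `df = n − 4`. Education stays in
the design matrix even when sex/APOE maps are reported. The FDR family is
the set of regions for one (parameter, covariate) pair — one brain map per
correction family — with pooling available by flag. Signed maps show
`−log10 q` for `q ≤ 0.05`, positive when the covariate is a risk factor
(earlier onset: `β_τ < 0`; faster pace: `β_ξ > 0`).

**Disattenuation.** Posterior-mean estimates shrink toward the population
mode, so regressing them attenuates coefficients — classical
measurement-error bias, factor `λ = var(estimates)/(var(estimates) + mean
posterior variance)` (from `cov(E[τ|y], τ) = var(E[τ|y])`). When the
individual table carries posterior variances, `β` and its se are rescaled
by `1/λ` (regression calibration); `t` and `p` are untouched, so the
significance machinery and its calibration are unaffected. Under the
default study conditions `λ ≈ 0.85` for `τ` and `≈ 0.78` for `ξ`; on
synthetic cohorts the corrected `ξ` coefficients track the per-cohort
truth-table OLS closely, and the corrected `τ` coefficients recover most
but not all of the gap (subjects observed deep in the logistic's flat
regions have one-sided posteriors whose compression is nonlinear; a
per-subject-λ weighted variant proved unstable and was rejected). Raw
coefficients are available via `disattenuate=False`.

## Goodness of fit and family comparison

Test-retest noise is estimated from same-day duplicate scans: every pair
contributes `(y₁ − y₂)/√2`, whose sd is an unbiased estimate of the
single-measurement noise sd under i.i.d. Gaussian duplicates. The GoF
report compares quantiles of the model's reconstruction errors with the
test-retest sample; the overlap indicator intersects the interquartile
ranges of the **absolute** errors (signed IQRs of two zero-centered
distributions always intersect regardless of scale, which would make the
indicator vacuous). The residual-bias audit regresses per-subject mean
absolute residuals (signed mean by flag) on each covariate and acquisition
factor separately.

`compare_families` calibrates both families and selects the lower fitted
`σ_ε`; fits within 2% are reported as a tie and resolved toward the
logistic family, the natural bounded shape for normalized atrophy
features.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes:
region-specific logistic (or affine) decline with covariate-shifted random
effects, Gaussian measurement noise, two scanner field strengths with an
additive 3T offset applied before preprocessing (so bias correction is
exercised end-to-end), same-day duplicate acquisitions, and demographics
patterned on the AD arm of a large longitudinal aging cohort:

| parameter | default | note |
|---|---|---|
| regions | 10 | identical generating fixed effects per region |
| t0, p0, v0 | 74 y, 0.5, 0.05/y | trajectories traverse a visible fraction of [0,1] over follow-up |
| σ_τ, σ_ξ, σ_ε | 7 y, 0.5, 0.02 | normalized units |
| β_τ(APOE), β_ξ(female) | −1.5 y/allele, log 1.23 | onset earlier per ε4 allele; pace ×1.23 for women |
| β(education) | 0 | only a weak protective effect is reported in the field, no magnitude to emulate |
| female / APOE 2 / APOE 1 | 0.442 / 0.192 / 0.502 | cohort proportions |
| education, baseline age | 15.5 ± 2.8 y, 74.4 ± 7.4 y | |
| visits | 2–7, ~1.0 ± 0.5 y apart (floor 0.1 y) | visit count uniform |
| 3T share, offset | 0.49, +0.02 | additive, 3T − 1.5T |
| duplicate fraction | 0.24 | same-day repeat with fresh noise |

Ground truth (generating fixed effects, per-subject `(τ, ξ)` per region,
covariates) is retained for recovery testing. What the generator does *not*
emulate: informative dropout, diagnosis conversion, visit-schedule
irregularity beyond i.i.d. intervals, region-to-region correlation, or
non-Gaussian measurement noise. Passing recovery and calibration tests
therefore establish correctness of the machinery under the model's own
assumptions, not robustness to the ways real cohort data violate them.

## Validation experiments and problem sizes

The experiments behind `scripts/acceptance.py` and the acceptance tests,
with the sizes the package runs them at (chosen to give each statistic
meaningful precision at desk scale):

* **Recovery**: 1 region, 200 subjects × 5 visits, covariate effects
  zeroed (so the generating `t0` equals the population mean onset and the
  comparison is well-posed); bias correction and outlier filtering on,
  min-max rescaling off (generator output is already in [0, 1]; rescaling
  would change the noise scale and make the σ_ε comparison ill-posed).
* **Effect recovery**: 1 region, 500 subjects, default covariate effects;
  disattenuated coefficients compared with the injected values.
* **Null calibration**: 100 all-null regions × 150 subjects, pooled over
  three master seeds, so each of the six (parameter × covariate) families
  has 300 tests: the per-family binomial 95% band around 0.05 then has its
  intended precision (at 100 tests per family and six families, ~26% of
  seeds would show one family outside the band by chance alone).
* **Goodness of fit**: 250 subjects × 5 visits with every visit
  reacquired (1250 test-retest pairs).
* **Family selection**: 10 cohorts per generating family, 60 subjects
  each, scanner effects disabled (see preprocessing note).
* Many-region and repeated runs use 400 SAEM iterations (200 burn-in)
  rather than the 2000-iteration default; the quadrature E-step makes the
  individual estimates insensitive to the shorter chain, and fixed-effect
  differences are well within statistical error.

Per-region sampler seeds derive deterministically from the master seed and
region name (SHA-256, reduced below 2³¹), so multi-region runs are
reproducible and independent of execution order.

## Known limitations

* Onset ages of subjects observed entirely in a saturated part of the
  logistic are weakly identified; their posterior means compress toward
  the population mode, and the global-λ disattenuation only partly undoes
  the resulting coefficient bias for `τ`.
* The fitted `σ_ε` includes posterior spread of the random effects and so
  sits slightly above the generating noise on small cohorts; reconstruction
  residual sd (posterior-mean predictions) is the cleaner noise readout.
* The group-mean bias correction is noisy on small cohorts (see above).
* The two-stage design (calibrate, then regress) is inherited from the
  analysis it implements; covariates are not part of the generative model,
  so their effects are estimated a posteriori, not jointly.
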