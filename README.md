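# neurotraj

Nonlinear mixed-effects modeling of longitudinal regional brain atrophy:
region-wise logistic trajectory models with subject-specific onset age and
progression pace, MCMC-SAEM calibration, and covariance analysis of the
individual parameters against sex, APOE-ε4 allele count and education, with
Benjamini–Hochberg FDR-corrected significance maps.

The package is aimed at neuroimaging statisticians who have longitudinal
feature tables (cortical thicknesses or normalized subcortical volumes per
region, one row per scan) and want to ask: *does a covariate shift the age at
which a region starts to decline, or the pace at which it declines?* A
synthetic-cohort generator with retained ground truth makes every stage of
the pipeline testable at desk scale without access to a restricted cohort
such as ADNI.

## Model

For one region, observation `j` of subject `i` follows

    y_ij = f( e^{ξ_i} (t_ij − τ_i) + t0 ) + ε_ij,     ε_ij ~ N(0, σ_ε²)

where `f` is either affine, `f(u) = p0 + v0 (u − t0)`, or logistic with
asymptotes 0 and 1,

    f(u) = 1 / (1 + (1/p0 − 1) · exp( −v0 (u − t0) / (p0 (1 − p0)) ))

so that `f(t0) = p0` and `f′(t0) = v0` in both families. The random effects
are the **onset age** `τ_i ~ N(t0, σ_τ²)` — the age at which subject `i`
crosses the reference value `p0` — and the **log-pace** `ξ_i ~ N(0, σ_ξ²)`,
with `e^{ξ_i}` the subject's multiplicative time-scaling of the population
trajectory. Fixed effects `(t0, p0, v0, σ_ε, σ_τ, σ_ξ)` are estimated per
region by MAP with MCMC-SAEM (Metropolis-within-Gibbs over the random
effects, Robbins–Monro stochastic approximation of the sufficient
statistics); individual parameters are posterior means computed by adaptive
2-D quadrature under the fitted fixed effects.

Downstream, each region's `(τ̂_i, ξ̂_i)` are regressed by OLS on
`[1, female, APOE-ε4 count, education years]`; coefficients get two-sided
t-tests, BH-FDR correction across regions, and a signed `−log10 q` map
(positive = risk: earlier onset or faster pace). Because `ξ` is a log-pace,
a coefficient `β` on `ξ` is reported as a `(e^β − 1)·100` percent change in
pace.

## Worked example

Simulate a small two-region cohort, run the full pipeline, and read the
association table:

```bash
neurotraj simulate --seed 42 --n-subjects 80 --n-regions 2 --out cohort
# -> wrote 454 visits for 80 subjects (2 regions) to cohort

cat > config.yaml <<EOF
visits_path: cohort/visits.csv
covariates_path: cohort/covariates.csv
output_dir: results
seed: 42
family: logistic
saem: {n_iterations: 1000, n_burn_in: 500, seed: 42}
EOF
neurotraj run-all --config config.yaml
# -> pipeline complete; artifacts in results
```

`results/calibration.json` then holds the fitted fixed effects per region,
e.g. for `region_1` (generated with t0=74, v0=0.05, σ_τ=7, σ_ξ=0.5,
σ_ε=0.02):

```
{'t0': 74.038, 'p0': 0.5, 'v0': 0.0415, 'sigma_eps': 0.0217,
 'sigma_tau': 7.4915, 'sigma_xi': 0.5152}
```

and `results/associations.csv` the covariate effects, here for `region_1`:

```
parameter       covariate    beta       t      p      q  percent_pace
    onset      sex_female -0.0855 -0.0469 0.9627 0.9627           NaN
    onset     apoe4_count -1.4314 -1.1261 0.2637 0.2637           NaN
    onset education_years -0.0790 -0.2414 0.8099 0.8099           NaN
 log_pace      sex_female  0.1572  1.1680 0.2465 0.2465       17.0245
 log_pace     apoe4_count  0.0194  0.2073 0.8363 0.8363        1.9632
 log_pace education_years -0.0022 -0.0919 0.9271 0.9271       -0.2216
```

The generator's default covariate effects shift onset 1.5 years earlier per
ε4 allele and multiply the pace by 1.23 for women; at N=80 the point
estimates point the right way (−1.43 y per allele, +17% pace for women) but,
as the q-values show, a cohort this small has no power to declare them —
which is exactly what the significance map (empty here) is for. Other
artifacts: preprocessed visits, normalization record, individual-parameter
CSV, signed-map CSV, goodness-of-fit report, residual-bias audit, and a
run-metadata JSON that makes the run reproducible bit-for-bit.

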