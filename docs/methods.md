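# Methods

## Models

All estimators are exact OLS fits (QR decomposition; no iterative
optimization) of a posttest outcome on at most four regressors. With Y₀ the
pretest, Y₁ the posttest, X the 0/1 treatment indicator, Ȳ₀⁽ʲ⁾ the arm-j
mean of the pretest and c = Y₀ − Ȳ₀⁽ʲ⁾ its arm-mean-centered version:

| name | response | regressors |
|---|---|---|
| `anova` | Y₁ | 1, X |
| `differences` | Y₁ − Y₀ | 1, X |
| `ancova` | Y₁ | 1, X, Y₀ |
| `quasi_ancova` | Y₁ | 1, X, c |
| `dual_centered` | Y₁ − Ȳ₀⁽ʲ⁾ | 1, X, c |
| `dual_centered_interaction` | Y₁ − Y₀ | 1, X, c, X·c |
| `ancova_interaction` | Y₁ | 1, X, Y₀, X·Y₀ |

Unequal arm sizes are supported throughout; arm means are per-arm means and
none of the identities below require balance.

Because c sums to zero within each arm it is orthogonal to the intercept
and to X, so the intercept and treatment coefficients of `quasi_ancova`
equal ANOVA's exactly, and those of the two dual-centered models equal the
differences model's exactly (the arm-mean response shift and the change-score
response differ from the differences response only by arm-constant terms
and terms orthogonal to {1, X}).

### Response convention for the interaction model

The two dual-centered variants deliberately use different responses. The
non-interaction `dual_centered` model subtracts the *arm-mean* pretest, so
its centered-pretest slope is the same projection as quasi-ANCOVA's (and
estimates the ANCOVA slope α₂ directly). The `dual_centered_interaction`
model subtracts the *actual* pretest (a change-score response); under that
parameterization, and only that one, its slope and interaction coefficients
map onto the ANCOVA-with-interaction model through the exact identities

    α̂₂ = γ̂₂ + 1,   α̂₃ = γ̂₃,

which the test suite verifies to 1e-8 relative on random datasets. (With an
arm-mean response the first identity becomes α̂₂ = γ̂₂; the treatment
coefficient and its corrected SE are unaffected by the choice, since both
responses agree up to elements of span{1, X, c}.)

## The generated-regressor correction

The arm mean Ȳ₀⁽ʲ⁾ is the fitted value of the first-stage regression
Y₀ = φ₀ + φ₁X + τ, so c is that regression's residual — an estimated
quantity. Naive OLS conditions on it and reports an ANCOVA-sized residual
variance for coefficients whose sampling error is really ANOVA-sized. The
2SLS correction recomputes the residual variance substituting the actual
Y₀ for Ȳ₀⁽ʲ⁾ everywhere it appears:

* `quasi_ancova`: c → Y₀ − Y₀ = 0, leaving the residuals of Y₁ on {1, X} —
  exactly the ANOVA residuals;
* `dual_centered*`: additionally the response becomes Y₁ − Y₀, leaving the
  differences-model residuals.

The corrected covariance keeps the original fit's (X'X)⁻¹ — the design is
what it is; only the error-variance estimate attached to it was wrong — and
multiplies it by the corrected residual mean square. Coefficient flags:
`needs_2sls` for the intercept and treatment of the three centered models
(the intercept is corrected too: it rides on the same substituted residual
variance, though conventions could differ — the flag and the JSON
`substitution_note` make the choice auditable), `ols_valid` for the
centered-pretest and interaction slopes.

**Degrees of freedom.** The corrected residual mean square divides by
n − (number of coefficients whose regressors survive the substitution),
i.e. n − 2: that makes corrected quasi-ANCOVA SEs equal ANOVA's *exactly*,
and corrected dual-centered SEs equal the differences model's exactly,
which is the point of the correction. The textbook 2SLS divisor (the fitted
model's own n − k) is available with `divisor="model"` for sensitivity
analysis; the two differ by a factor √((n−2)/(n−3)), negligible except in
very small samples. No further small-sample df refinement is attempted.

p-values use the t distribution with `df_naive` for `ols_valid`
coefficients and `df_corrected` for `needs_2sls` ones, following the
variance estimate actually used.

### Group-mean centering in general (`hill_variant_analysis`)

For a generic grouped regression there are three ways to use group-mean
centering, with different SE validity per coefficient: (1) outcome on group
mean + demeaned predictor — the group-mean coefficient needs 2SLS; (2)
outcome on raw predictor + group mean — the group-mean coefficient needs
2SLS, the raw-predictor one is fine; (3) demeaned predictor only — OLS SEs
valid. Variants 1 and 2 span the same column space and give identical
residuals. The corrected SEs apply the same substitution principle
(group mean → actual predictor in the fitted equation); for these variants
the generated regressor does not vanish under substitution, so this is an
interpretation of the 2SLS rule rather than an exact reference-model
identity, and it is labelled as such in the substitution note. Grand-mean
centering, by contrast, is a fixed shift: it changes only the intercept,
which the suite checks to 1e-10.

### Limitations

Full-information maximum likelihood is not offered as an alternative fix:
with the treatment arm as the centering group, the first stage contains no
exogenous variable absent from the outcome equation, so the slope on the
centered pretest is not identified (order condition fails). Joint SUR
estimation of the two-equation system is likewise pointless — both
equations share the same regressors, so it collapses to equation-by-equation
OLS; its conclusion is embodied in the exact-equivalence tests instead.
Out of scope: more than two occasions or arms, multiple covariates,
clustered/robust errors, missing-data mechanisms beyond listwise deletion
at ingest.

## Monte Carlo design

`simulate_prepost` draws, per subject, pretest ~ N(μ₀, σ²) and

    posttest = μ₁ + α₂(pretest − μ₀) + e,   e ~ N(0, σ²(1 − α₂²)),

plus the treatment effect for treated subjects: the conditional-regression
parameterization of a bivariate normal, so both marginal SDs equal σ, the
pre/post correlation equals α₂, and the residual variances have closed
forms — σ² (ANOVA), σ²(1 − α₂²) (ANCOVA family), 2σ²(1 − α₂)
(differences).

Defaults are the null study conditions: μ₀ = μ₁ = 130, σ = 15, zero
treatment effect, 1,000 replications, and **500 subjects per arm** — the
arm size implied by the ANOVA theoretical SE 15·√(2/n) ≈ 0.948 that the
reference results report; it is configurable, as is arm imbalance.
Treatment assignment is by fixed margins (exactly n per arm). The RNG seeds
each replication from (master seed, replication index), so any single
replication can be regenerated in isolation. Each replication asserts the
quasi≡ANOVA and dual≡differences identities before aggregation; a violation
aborts with the replication index.

Aggregates per model: mean treatment estimate, mean reported naive SE, mean
corrected SE, empirical SD of the estimate across replications (ddof = 1;
undefined and reported as absent for a single replication), mean residual
mean square, mean pretest-slope estimate and its mean reported SE (the
latter is reported as the mean OLS SE; the across-replication SD of the
slope is recoverable from kept records), and empirical rejection rates of
the nominal-5% two-sided t-tests using naive and corrected SEs. Every mean
carries a Monte-Carlo standard error SD/√R; the empirical SD carries the
asymptotic-normal approximation SD/√(2(R−1)).

### What the generator does and does not emulate

It produces exactly the idealized null world the estimators assume:
bivariate-normal scores, homoskedastic errors, perfect randomization,
complete data, a common pretest slope. Passing tests therefore demonstrate
the algebraic identities and the calibration of the corrected tests *under
the model*; they say nothing about non-normal outcomes, heteroskedasticity,
attrition, or clustered data, none of which are simulated.

## Tolerance policy

Exact identities are asserted to 1e-10 relative on well-conditioned inputs
and 1e-8 on property-based random inputs (the interaction identities pass
through a raw-pretest parameterization whose conditioning is worse than the
centered one). Monte Carlo comparisons against the published reference
table use ±3·√2·σ̂_MC plus half an ulp of the printed precision, where
σ̂_MC is the study's own Monte-Carlo standard error for that cell: the
printed cell is itself one Monte-Carlo draw from the same design, so the
difference of the two independent estimates has standard deviation √2·σ_MC.
Comparisons against closed-form values (the residual-variance forms above)
use ±3·σ̂_MC, the analytic side being noise-free. Type-I-error rates are
compared at ±3 binomial standard errors of 0.05 on 1,000 replications.

The test suite runs the full 1,000-replication, 500-per-arm grid (a few
seconds) plus a 100-replication smoke profile; both scales must agree with
the reference values under the same rule, the smoke profile's wider MC
standard errors widening its band automatically.
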