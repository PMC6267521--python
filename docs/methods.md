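# Methods

## Analysis model

Two-wave linear growth curve for a competence score, time coded 0/1,
predictors reasoning (REAS) and mathematical self-concept (SC)
z-standardized across students, with nested zero-mean normal random
intercepts: person `u_i ~ N(0, σ_u²)`, school `v_s ~ N(0, σ_v²)`, residual
`e_tis ~ N(0, σ_e²)`, mutually independent. A common time effect is
assumed (no random slope), and random effects are strictly nested
person-in-school (no crossed effects). Estimation is maximum likelihood
(not REML) throughout, so that the MAR fits and the MNAR joint likelihoods
share one basis; Wald 95% intervals are reported for all parameters
(variance-component intervals via the log-sd scale for the dropout GLMM,
symmetric delta-method intervals in the growth model).

### Likelihood kernel

Schools are independent, so the marginal likelihood factors into school
blocks. Conditioning on `v_s`, persons are independent with a 2×2 (both
waves) or scalar (wave 0 only) covariance; each person's density is a
Gaussian kernel in `v_s`, and the scalar `v_s` integral is evaluated in
closed form by completing the square. This gives an O(n) exact
log-likelihood with no matrix assembly. Fixed effects are profiled out by
generalized least squares at each variance-parameter value; the three
variance components are optimized on the log-sd scale (soft bound at
log sd = −8, flagged as a boundary estimate when hit) by L-BFGS-B
(`ftol 1e-12`, `gtol 1e-6`, ≤500 iterations). Fixed-effect covariance is
the inverse GLS information at the ML variance estimates; variance
component SEs come from the numerical Hessian of the profile likelihood.
The kernel is validated against a dense joint multivariate-normal density
on small fixtures (agreement to 1e-8; property-tested).

### Weighted pseudo-likelihood (WE)

Each row's conditional Gaussian contribution — the wave-0 marginal and the
wave-1 density conditional on wave 0, random effects integrated
analytically — is raised to the power of its weight. With unit weights
this is algebraically the exact likelihood; rows are processed in
canonical (school, person, wave) order, so the result is invariant to the
input row order. The weighted fit uses complete persons only, with the
person's inverse-probability weight on both rows. Weights come from a
single-level logit of response on the selection variables (the multilevel
structure is deliberately ignored in the response model, mirroring common
practice and its documented failure mode), are floored at fitted response
probability 1e-3 (with a warning), optionally truncated at an upper
quantile, and normalized to mean 1 over respondent rows by default (raw
weights by flag). Weighted-fit SEs are model-based (no sandwich
correction); the sensitivity comparison reads point estimates, not
weighted-fit coverage.

## Missing-data schemes

* **LWD** — completers only; the MCAR benchmark.
* **FIML** — ML on all observed rows; valid under MAR; contains no
  selection information.
* **MI** — chained-equations imputation of the missing wave-1 outcome from
  a linear model with a *person-level* random intercept only; the school
  level is deliberately omitted from the imputation model (the standard
  two-level-software restriction) and restored in the analysis model fit
  to each completed dataset. Auxiliary covariates default to the
  selectivity-analysis variables. Imputation is proper: fixed effects are
  drawn from their asymptotic normal posterior and variance parameters
  from a log-normal approximation before each predictive draw; person
  intercepts are drawn from their conditional posterior given the wave-0
  outcome. Exactly one variable is incomplete, so the chained loop
  converges after a single pass (the cycle loop is retained for
  generality). Default m = 20 (the source analysis does not state m; 20
  balances cost and pooling stability). Rubin's rules with the standard
  small-sample df.
* **DK** — joint ML of the growth model and a logit dropout equation on
  the wave-0 (past) and wave-1 (current) outcome, optionally plus
  covariates. For dropouts the unobserved wave-1 outcome is integrated by
  Gauss–Hermite quadrature centered at its conditional mean with sd σ_e
  (21 nodes), nested inside exact analytic integration of `u_i` and
  adaptive quadrature over `v_s`.
* **WC** — joint ML with a probit dropout equation `Φ(ψ0 + λ·u_i + x'ψ)`.
  Because selection involves only `u_i`, the wave-1 outcome of dropouts
  and the probit expectation over `u_i` are both analytic; only the `v_s`
  integral is numeric.
* **PM** — two latent classes defined deterministically by the dropout
  pattern (with dropout dummies as the only membership covariates and
  K = 2, membership is degenerate). Class-specific intercept/REAS/SC with
  variance components constrained equal across classes; the dropout class
  has no wave-1 data, so its time-dependent terms are reported NA under
  `restriction="none"` (the default) or borrowed from the completer class
  under `restriction="equal_growth"`, which enables a mixture-averaged
  time effect (class-proportion weights, delta-method SEs treating the
  proportions as fixed). `equal_variances=False` fits the classes
  separately; the dropout class then folds the person variance into the
  residual (one row per person cannot separate them).

No school effect enters any selection or membership equation (enforced,
not configurable). Joint-model quadrature uses adaptive
(mode/curvature-rescaled) Gauss–Hermite with 15 nodes per dimension by
default; the adaptive centering comes from the Gaussian-part posterior of
`v_s`, which makes the rule exact when the selection part is disabled
(the shared-kernel identity checked in the tests). Starting values: growth
parameters from a FIML fit, selection parameters from a marginal
logit/probit of dropout. SEs from the numerical Hessian of the joint
likelihood. With dropout generated from outcome-driven selection, the
DK/WC intercept coincides with FIML's to optimizer precision in this
design — wave 0 is fully observed and the free selection intercept absorbs
any intercept shift in the dropout part — so the models' genuine
correction shows in the time effect, consistent with the published
observation that the MAR and selection models agree on the intercept while
complete-case analysis does not.

## Diagnostics

* **Little's MCAR test** — EM (ML) estimates of the mean and covariance
  under arbitrary missingness patterns; statistic
  `d² = Σ_j n_j (ȳ_obs,j − μ̂_obs,j)' Σ̂_obs,j⁻¹ (ȳ_obs,j − μ̂_obs,j)`
  with df `Σ_j k_j − k`; single-pattern input is an explicit error. Type-I
  error calibrated to [0.03, 0.07] over 500 null replicates in the
  acceptance suite.
* **Dropout GLMM** — logit of dropout (coded 1) on the selection
  variables with a school random intercept integrated by adaptive
  Gauss–Hermite quadrature (per-school Newton mode search, curvature
  rescaling; 15 nodes default). Without the random intercept the fit
  reduces to plain logistic ML (checked against statsmodels to 1e-6).
  Complete separation is detected and reported with the offending
  covariate named. With the extreme generating configuration (school-sd
  2.89, mode effect ~5) the per-school integrand is sharply skewed;
  7-node quadrature is visibly inexact there, so production fits use ≥15
  nodes (quadrature-refinement stability is asserted at moderate
  heterogeneity).

## Synthetic cohort generator

The generator emulates a two-wave school-cohort panel: students nested in
schools (defaults 538 schools × 25 students; school sizes equal by
default, optionally uniform in a range — the source reports totals but no
size distribution). Baseline covariates come from a Gaussian copula whose
latent correlations are set to the published pairwise values
(an approximation — printed values are observed-scale point-biserial where
binaries are involved): self-concept (2.522, 0.921), reasoning
(8.654, 2.457), age (14.92, 0.625) continuous; girls .497, migration .256,
home-testing .313 by thresholding. The home-testing indicator is coded
1 = tested at home so the dropout model applies directly (the descriptive
table codes the same variable 1 = school; its correlations are
sign-flipped accordingly). School type is a school-constant four-level
category drawn from a per-school latent normal at marginal rates
.238/.213/.200/.349; its correlations with student-level covariates are
not reproduced (limitation).

Outcomes follow the growth model with variance components
σ_u² = .32, σ_v² = .31, σ_e² = .37 — matching within-person and school
intraclass correlations of .63 and .31. Default fixed effects: γ0 = .037
(the published wave-0 mean), γ2 = .525 and γ3 = .299 solved jointly so
that corr(REAS, Y0) = .494 and corr(SC, Y0) = .347 given
corr(REAS, SC) = .222 and the unit-total variance components (implied
sd(Y0) ≈ 1.20 versus the printed 1.281 — the printed descriptives are not
exactly consistent with the unit-total calibration, and the correlation
targets were kept); γ1 = .65 (mid of the published .53–.78 time-effect
range), γ4 = −.10 (growth larger for lower reasoning), γ5 = .02
(self-concept moderation "very small to nonexistent").

Dropout mechanisms: MCAR; MAR on covariates (defaults: the
selectivity-table logit, including the wave-0 outcome and its square and
an independent school-level intercept of sd 2.89 — independent of the
outcome's school effect, so the mechanism stays ignorable given the
observed data); DK-type on the wave-0/wave-1 outcome; WC-type probit on
the realized `u_i`; and a two-class latent-class mechanism. Target
dropout rates are met by bisecting the intercept against the realized
fraction under fixed uniform draws (match within 1/n). Realized `u_i`,
`v_s` and masked outcomes live in a truth sidecar that is never written
into the analysis CSV.

The incidental-selection demonstration draws iid standard-normal (Y, X)
with correlation 0, builds U = a·Y + b·X + noise with var(U) = 1, and
retains the top fraction by U (deterministic threshold selection —
chosen because it reproduces the ∓.12 worked example, which the
closed-form Pearson–Lawley single-truncation oracle gives as ∓.1164;
Bernoulli-probability selection is provided as an option and attenuates
the effect). The generator produces idealized Gaussian data: no IRT
measurement error, no test linking, no sampling weights, no school-size
or school-type selection effects — passing tests show the estimators
behave correctly under the stated model, not that the model describes any
real cohort.

## Study sizes

Simulation studies are sized for a desk-scale run: MCAR cross-method
agreement, 20 replicates of 60 schools × 8 students; MAR recovery, 15
replicates of 100 × 10 (FIML/MI) and 15 replicates of 150 × 15 (dropout
GLMM coverage, mean coverage ≥ .90); DK and WC recovery, 20 replicates of
100 × 8 at ~40% dropout with 9-node quadrature (refinement to 25 nodes
moves estimates by <1e-3); Little's-test calibration, 500 replicates of
n = 200. Cross-method agreement is asserted pairwise on replicate-mean
differences with a Bonferroni-adjusted simultaneous bound (z < 3.5 over
90 comparisons) plus an absolute cap of 0.05. The analysis scripts use a
200 × 15 cohort with 61% dropout.

## Known limitations

* Two waves, monotone dropout, K = 2 pattern classes only; no Bayesian
  estimation; no random slopes.
* Cross-method information criteria are deliberately not computed — the
  dimensionality of the dependent variable differs across schemes, so
  AIC/BIC comparisons are not meaningful; the report is comparative only,
  and the three-level robustness verdict (robust / sign-robust /
  non-robust) is this package's own convention.
* MI omits the school level in the imputation model by design; its pooled
  person-level variance absorbs part of the school variance (visible in
  the σ_u²/σ_v² rows of the report), while fixed effects are unaffected.
* Pooled-SE stability in MI depends on the fraction of missing
  information: parameters identified mainly by wave-0 data stabilize to
  <2% between m = 20 and m = 50; the time-effect family at ~50–60% dropout
  fluctuates at the between-imputation noise scale (~√(2/(m−1)) of the B
  share).
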