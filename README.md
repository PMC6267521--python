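# growthsens

Sensitivity analysis of competence growth under panel attrition: the same
two-wave growth-curve model estimated under MCAR, MAR and MNAR
missing-data schemes, with a synthetic-cohort generator that emulates a
large school-based educational panel and its dropout process.

## The problem

Longitudinal competence assessments routinely lose over half of their
respondents between waves, and the students who drop out are not a random
subset — in school cohorts they tend to be the lower-performing ones, and
students tracked to home testing after leaving school barely return.
Because every missing-data correction rests on untestable assumptions
about that dropout process, a single estimate (for instance a
complete-case analysis) can be badly misleading. The defensible practice
is a *sensitivity analysis*: fit the same substantive model under several
missing-data models, from ignorable to outcome-dependent, and judge which
conclusions survive.

## The model

The analysis model is a linear growth curve for the competence score
`Y_tis` of student `i` in school `s` at wave `t ∈ {0, 1}`:

```
Y_tis = γ0 + γ1·TIME + γ2·REAS + γ3·SC + γ4·TIME·REAS + γ5·TIME·SC
        + u_i + v_s + e_tis
```

with `REAS` (reasoning) and `SC` (mathematical self-concept)
z-standardized, independent normal random intercepts `u_i` (person) and
`v_s` (school), and residual `e_tis`. Wave-0 outcomes are always observed;
wave-1 outcomes are missing for dropouts (monotone two-wave pattern).

The package estimates this model under seven schemes:

| scheme | assumption | implementation |
|--------|-----------|----------------|
| LWD  | MCAR | listwise deletion (completers only) |
| FIML | MAR  | ML on all observed rows |
| MI   | MAR  | two-level chained-equations imputation (person level), Rubin pooling |
| WE   | MAR  | inverse probability weighting from a single-level response logit |
| DK   | MNAR | Diggle–Kenward selection: logit dropout on past *and current* outcome |
| WC   | MNAR | Wu–Carroll shared parameter: probit dropout loading on `u_i` |
| PM   | MNAR | Little's two-class pattern mixture by dropout pattern |

All likelihoods share one kernel: the marginal Gaussian likelihood is
assembled school block by school block in closed form, and the MNAR joint
likelihoods integrate the school intercept by adaptive Gauss–Hermite
quadrature around its Gaussian-part posterior (person intercepts and the
unobserved wave-1 outcome integrate analytically or by nested quadrature).
Pre-analysis diagnostics include Little's MCAR test and a dropout logit
with a school random intercept.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (200 schools × 15 students, 61% wave-2 dropout driven by the
selectivity-table coefficients):

```bash
python analysis/01_selection_bias_demo.py
python analysis/02_simulate_cohort.py
python analysis/03_selectivity_diagnostics.py
python analysis/04_sensitivity_comparison.py
```

Script 01 prints the incidental-selection demonstration — two variables
with true correlation zero, retained by a propensity loading .50 on each:

```
 load_y  load_x  response_rate  observed_r_mean  oracle_r
    0.5     0.5            0.8          -0.1153   -0.1164
   -0.5     0.5            0.8           0.1184    0.1164
```

A 20% nonresponse rate alone manufactures a correlation of ∓.12 where none
exists; the closed-form truncated-normal value agrees with the simulation.

Script 03 rejects MCAR (`chi2(3) = 21.8, p = 7e-05`) and recovers the
generating dropout model (assessment-mode coefficient 4.73 ± 0.25 against
a generating value of 5.04; school-intercept sd 2.65, CI [2.30, 3.05],
against 2.89). Script 04 prints the cross-method coefficient table, e.g.
(γ0 truth 0.037, γ1 truth 0.65):

```
method       lwd   fiml     mi     we     dk     wc    pm1    pm0
intercept  0.051  0.027  0.027  0.022  0.027  0.027  0.063  0.004
time       0.642  0.655  0.666  0.663  0.613  0.643  0.642    NaN
```

Listwise deletion and the completer class PM1 sit above the other methods
on the intercept (dropouts scored lower at wave 0), the MAR and MNAR
likelihood methods cluster together, the dropout class PM0 has no
estimable time effect without a restriction, and the per-parameter
robustness verdicts flag the self-concept × time interaction as
non-robust — its sign is not stable across schemes.

A thin CLI wraps the same functions:
`python -m growthsens simulate|demo-fig1|diagnose|fit|sensitivity --help`.

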