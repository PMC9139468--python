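# Methods

## The model and the decomposition

`natmedint` studies the causal effect of an exposure $A$ on an outcome $Y$
transmitted through two mediators $M_1$ and $M_2$, conditional on a
covariate vector $C$, in the potential-outcomes framework. Two causal
structures are supported:

* **non-sequential** — no causal edge between the mediators;
* **sequential** — a direct edge $M_1 \to M_2$, so $M_2$'s structural
  equation takes $M_1$ as an input and nested counterfactuals such as
  $M_2(a^*, M_1(a))$ arise.

For an exposure contrast $a$ vs. $a^*$ and fixed mediator reference levels
$m_1^*, m_2^*$, the total effect $\mathrm{TE} = Y(a) - Y(a^*)$ decomposes
into ten components:

| component | interpretation |
| --- | --- |
| $\mathrm{CDE}(m_1^*, m_2^*)$ | neither mediation nor interaction |
| $\mathrm{INT_{ref}}\text{-}AM_1$, $\mathrm{INT_{ref}}\text{-}AM_2$, $\mathrm{INT_{ref}}\text{-}AM_1M_2$ | interaction only |
| $\mathrm{NatINT}\text{-}AM_1$, $\mathrm{NatINT}\text{-}AM_2$, $\mathrm{NatINT}\text{-}AM_1M_2$ | both mediation and interaction with the exposure |
| $\mathrm{NatINT}\text{-}M_1M_2$ | mediation through both mediators (their mutual interaction) |
| $\mathrm{PIE}\text{-}M_1$ | mediation through $M_1$ only |
| $\mathrm{PIE}\text{-}M_2$ (non-seq.) / $\mathrm{SNIE}\text{-}M_2$ (seq.) | mediation through $M_2$ only |

The *natural mediated interaction* components hold the co-mediator at its
natural potential value instead of a fixed level, which is what
distinguishes them from the comparison (Bellavia–Valeri) mediated effects
also implemented here (`bellavia_components`): those condition on
arbitrarily chosen values $M_1(a^*) = m_1^*$ and/or $M_2(a^*) = m_2^*$ and
exist only for non-sequential mediators — fixing $M_2$ at a constant would
sever a direct $M_1 \to M_2$ link.

In the sequential structure the part of $M_2$'s mediated effect routed
through $A \to M_1 \to M_2 \to Y$ is not non-parametrically identifiable
(a counterfactual that activates $M_1$ at two exposure values at once has
no observational counterpart — the Avin–Shpitser–Pearl recanting-witness
situation). The package therefore reports the *seminatural* indirect
effect through $M_2$ (path $A \to M_2 \to Y$ only) in that scenario, and
exposes the identifiability rule itself as `is_identifiable`, which
flags any assignment in which $M_1$ is activated at two distinct exposure
values, or in which a fixed $m_1$ for $Y$ coexists with a counterfactual
$M_1$ feeding $M_2$.

Traditional aggregates are pure sums of components: PDE (CDE + reference
interactions), TDE (PDE + exposure NatINTs), TIE = TE − PDE, PE = TE −
CDE, PAI (all seven interaction components), and NIE-M1 (NatINT-M1M2 +
PIE-M1).

## Closed forms under the linear SEM

With

$$E[Y \mid A, M_1, M_2, C] = \theta_0 + \theta_1 A + \theta_2 M_1
+ \theta_3 M_2 + \theta_4 AM_1 + \theta_5 AM_2 + \theta_6 M_1M_2
+ \theta_7 AM_1M_2 + \theta_8' C,$$
$$E[M_2 \mid A, M_1, C] = \beta_0 + \beta_1 A + \beta_2 M_1 + \beta_3 AM_1
+ \beta_4' C, \qquad
E[M_1 \mid A, C] = \gamma_0 + \gamma_1 A + \gamma_2' C,$$

every component has an exact polynomial expression in the coefficients,
evaluated at a point covariate profile $c$ (`decompose_linear`). The
sequential formulas additionally involve $\sigma^2_{M_1}$, the error
variance of the $M_1$ model, because interaction terms make $Y$ quadratic
in $M_1$ once $M_2$'s dependence on $M_1$ is substituted; the
non-sequential scenario is the exact special case $\beta_2 = \beta_3 = 0$,
in which all variance terms cancel. Covariate coefficients $\theta_8$
never appear in any component (they cancel in every contrast); the
Monte-Carlo oracle test verifies this.

`closed_form_te` implements the total effect a second way, as an explicit
quartic polynomial in $(a, a^*)$ derived by composing the three structural
equations and taking expectations. The derivation was done independently
of the per-component formulas, and the identity
"sum of ten components = TE polynomial" is enforced at $10^{-9}$ relative
tolerance on thousands of random coefficient vectors in the test suite —
a strong consistency check on both derivations. All identity checks use
tolerances $10^{-9}$ relative / $10^{-12}$ absolute; everything here is
polynomial arithmetic, so slack beyond rounding noise would hide bugs.

## Discrete g-formula estimators

For categorical mediators, each component's population mean is a finite
sum over the mediator supports weighted by the conditional laws
$\Pr(M_1 \mid a, c)$ and $\Pr(M_2 \mid a, m_1, c)$ and the conditional
outcome mean $p_{a m_1 m_2 c}$ (`empirical_decompose`). Covariates enter
as discrete strata; continuous covariates must be pre-stratified or
handled through the linear pathway (continuous-mediator integrals are out
of scope — the linear closed forms cover that case). The plug-in law
(`law_from_data`) uses raw within-cell means and frequencies with **no
smoothing**: an empty cell is a hard error naming the cell, because
silently shrinking cells would change the estimand. A deliberate escape
hatch (`allow_unreachable=True`) tolerates empty outcome cells whose
plug-in probability is exactly zero (e.g. a deterministic mediator), since
such cells receive zero weight in every mediator-averaged term.

Two algebraic facts are exploited as tests: the ten empirical components
sum *exactly* (machine precision) to the g-formula contrast
$E[Y(a)|c] - E[Y(a^*)|c]$ for any normalized law, and on binary structural
systems each component equals the exact counterfactual expectation
enumerated from the structural equations to $10^{-12}$.

## Estimation and the bootstrap

`fit_sem` fits the three models by ordinary least squares (equal to
maximum likelihood under Gaussian errors) via statsmodels; the outcome
model always carries all two-way and the three-way interaction.
$\hat\sigma_{M_1}$ is the square root of the unbiased residual-variance
estimate (denominator $n - p$). Rank-deficient designs raise immediately.
A per-column `log` transform directive supports right-skewed mediators;
reference levels are then interpreted on the transformed scale. Reference
levels may be given as numbers or as `"sample-mean"`.

`bootstrap_decomposition` produces percentile intervals from
nonparametric case resampling. Percentile intervals are the default
(BCa would require jackknife acceleration estimates and is not
implemented). Resampling is realized as multinomial case weights feeding
weighted normal equations — mathematically identical to row resampling
followed by OLS, and fast enough that 2,000 replicates at $n = 1{,}000$
take well under a second. Replicates with a singular weighted design are
dropped; more than 1% dropped is an error. When reference levels are
`"sample-mean"` they are re-estimated inside each replicate by default
(the reference level is then itself an estimate whose variability belongs
in the interval), with `freeze_reference_levels=True` to pin them. The
default $B = 2{,}000$ trades desk-scale runtime against Monte-Carlo error
of the interval endpoints; pass a larger `--bootstrap` for production
inference.

## The simulator and the counterfactual oracle

`simulate_linear` draws $C \sim N(0.2, 0.5^2)$ per coordinate,
$A \mid C \sim N(0.3 + 3\sum c, 0.5^2)$ (a strongly confounded exposure),
and $M_1, M_2, Y$ from the structural equations with independent Gaussian
errors. `default_study_sem()` returns the reference design used
throughout the tests: $\theta = (0.2, 0.3, 0.3, 0.4, 0.01, 0.02, 0.6,
0.7)$, $\theta_8 = 0.2$, both mediator models $0.2 + 0.3A + 0.2C$, all
error SDs $0.5$. Its true component values at $a=1, a^*=0, m_1^* = m_2^* =
0, c = 0.2$ (the covariate mean) are frozen in the test suite
(TE $= 0.8707$, PDE $= 0.3475$, NatINT-AM1 $= 0.0534$, ...). The
`sequential=True` variant adds $\beta_2 = 0.2, \beta_3 = 0.1$ so the
sequential-only formula terms (the $\sigma^2_{M_1}$ pieces) are exercised;
those two values were chosen once as moderate effects comparable to the
other coefficients.

The oracle evaluates any nested counterfactual directly from the
structural equations, including non-identifiable ones, since it owns the
model. For the linear SEM it is Monte-Carlo with **common random
numbers**: one pair of exogenous mediator errors per replicate is reused
across every term of a contrast, matching the individual-level definition
of each component as a within-unit difference and sharply reducing
variance (outcome noise is omitted entirely — it has mean zero and cannot
move an expectation). For the binary system the oracle is exact: the
shared uniforms $U_1, U_2$ are piecewise constant in effect, so cutting
$[0,1]$ at the Bernoulli success probabilities yields finitely many
rectangles on which every counterfactual is deterministic. Repeated calls
are bit-identical.

What the generators do *not* emulate: model misspecification (the fitted
models are exactly the generating models), missing data, measurement
error, survey weights, non-Gaussian errors, or effect heterogeneity in
$C$ beyond the linear terms. Passing tests therefore certify the
estimators under a correctly specified linear SEM, not robustness to
real-data violations.

## Numerical and design choices

* **Point covariate profile.** All effects are conditional on a vector
  $c$; population averaging over $C$ is not implemented (no component
  formula involves $\theta_8' c$, and conditional reporting matches the
  usual "males at the mean age" presentation).
* **Degenerate contrast.** $a = a^*$ is legal and returns exact zeros for
  every component — every formula carries a factor $(a^k - a^{*k})$.
* **Noiseless recovery check.** With all structural error SDs set to 0 the
  mediators are exact linear functions of $(A, C)$, making the outcome
  design rank-deficient and $\theta$ unidentifiable. The exact-recovery
  test therefore builds a deterministic dataset in which the mediators
  receive exogenous deviations orthogonal to their regression designs:
  all three regressions then interpolate, and every coefficient and
  component is recovered to machine precision.
* **Binary analogue.** Binary variables are coded 0/1 and handled by the
  same formulas; the all-binary displays are special cases of the general
  counterfactual definitions.
* **Problem sizes.** The test suite uses 1,000 random SEMs per scenario
  for the identity checks, 500,000 shared-noise draws for the
  Monte-Carlo/closed-form comparison (4 standard errors), and a
  200-repetition coverage study at $n = 1{,}000$, $B = 2{,}000$ with
  acceptance band $[0.92, 0.98]$ for nominal 95% intervals — sizes chosen
  so the whole suite runs on a laptop in a couple of minutes while keeping
  the Monte-Carlo error well below the effects being checked.

## Known limitations

* At most two mediators and one exposure; no interventional-analogue
  effects.
* Closed forms are for identity-link linear outcome models only (no
  logistic/Poisson analogues).
* The empirical pathway requires categorical mediators and discrete
  covariate strata; no continuous-mediator integration.
* No IPW or doubly-robust estimators; the plug-in estimators inherit the
  usual sensitivity to outcome/mediator model misspecification.
* Identification rests on the standard no-unmeasured-confounding and
  cross-world independence assumptions, which are untestable from data;
  the package checks only the structural (Avin-type) identifiability of
  each counterfactual expression.
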