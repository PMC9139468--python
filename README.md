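# natmedint

Decomposition of the total effect of an exposure on an outcome through
**two mediators** — causally sequential or non-sequential — into ten
counterfactual components via **natural mediated interaction (MI)
effects**, with exact linear-SEM closed forms, discrete g-formula
estimators, bootstrap inference, and a structural counterfactual oracle.

## Who this is for

Epidemiologists and biostatisticians running mediation analyses with two
intermediates — e.g. the effect of alcohol consumption on systolic blood
pressure mediated by BMI and (log) GGT, where BMI also affects GGT so the
mediators are causally ordered — who want to know how much of a total
effect is due to mediation only, interaction only, both, or neither.

## The decomposition

For exposure contrast $a$ vs. $a^*$ and mediator reference levels
$m_1^*, m_2^*$:

$$\mathrm{TE} = \mathrm{CDE}(m_1^*, m_2^*)
  + \mathrm{INT_{ref}}\text{-}AM_1 + \mathrm{INT_{ref}}\text{-}AM_2
  + \mathrm{INT_{ref}}\text{-}AM_1M_2
  + \mathrm{NatINT}_{AM_1} + \mathrm{NatINT}_{AM_2}
  + \mathrm{NatINT}_{AM_1M_2} + \mathrm{NatINT}_{M_1M_2}
  + \mathrm{PIE}_{M_1} + \mathrm{PIE}_{M_2},$$

with the seminatural indirect effect $\mathrm{SNIE}_{M_2}$ replacing
$\mathrm{PIE}_{M_2}$ when there is a direct $M_1 \to M_2$ link (the
$A \to M_1 \to M_2 \to Y$ path is then not non-parametrically
identifiable). The natural MI effects evaluate interactions with the
co-mediator at its *natural* potential value, e.g.

$$\mathrm{NatINT}_{AM_1} = Y(a, M_1(a), M_2(a^*)) - Y(a^*, M_1(a), M_2(a^*))
  - Y(a, M_1(a^*), M_2(a^*)) + Y(a^*, M_1(a^*), M_2(a^*)),$$

rather than at a fixed level as in the Bellavia–Valeri decomposition
(also implemented, for comparison). Traditional aggregates — PDE, TDE,
TIE, PE, PAI, NIE$_{M_1}$ — are recovered by summing components. Under a
linear structural equation model every component has an exact closed form
in the regression coefficients, e.g.
$E[\mathrm{NatINT}_{AM_1} \mid c] = [\theta_4 + \theta_7(\beta_0 +
\beta_1 a^* + \beta_4' c)]\,\gamma_1 (a - a^*)^2$.

See `docs/methods.md` for the full model, assumptions and design choices.

## Worked example

Closed-form evaluation of the built-in reference design (all three models
linear, outcome coefficients $\theta = (0.2, 0.3, 0.3, 0.4, 0.01, 0.02,
0.6, 0.7)$, both mediator models $0.2 + 0.3A + 0.2C$), conditional on
$c = 0.2$:

```python
from natmedint import (DecompositionRequest, decompose_linear,
                       compute_aggregates, default_study_sem)

sem = default_study_sem()
req = DecompositionRequest("nonsequential", a=1.0, a_star=0.0,
                           m1_star=0.0, m2_star=0.0,
                           covariate_profile=[0.2])
result = decompose_linear(sem, req)
print({k: round(v, 4) for k, v in result.labels().items()})
print({k: round(v, 4) for k, v in compute_aggregates(result).labels().items()})
```

```
{'CDE': 0.3, 'INTref-AM1': 0.0024, 'INTref-AM2': 0.0048,
 'INTref-AM1M2': 0.0403, 'NatINT-AM1': 0.0534, 'NatINT-AM2': 0.0564,
 'NatINT-AM1M2': 0.063, 'NatINT-M1M2': 0.054, 'PIE-M1': 0.1332,
 'PIE-M2': 0.1632, 'TE': 0.8707}
{'PDE': 0.3475, 'TDE': 0.5203, 'TIE': 0.5232, 'PE': 0.5707,
 'PAI': 0.2743, 'NIE-M1': 0.1872}
```

Reading: of the total effect 0.871, only 0.300 survives with both
mediators held at 0 (CDE); 0.274 is attributable to interactions (PAI),
the largest single interaction being the three-way natural MI (0.063)
and the two exposure–mediator natural MIs (0.053, 0.056); pure mediation
contributes 0.133 through $M_1$ and 0.163 through $M_2$.

The same workflow from data, with bootstrap intervals, via the CLI:

```bash
natmedint simulate --n 1000 --seed 1 --out data.csv
natmedint decompose --data data.csv --covariates c1 \
    --covariate-profile 0.2 --bootstrap 2000 --seed 7 --out report.json
```

`report.json` contains every component and aggregate with its point
estimate and percentile 95% CI; reports are deterministic given the seed.
For a sequential analysis pass `--scenario sequential` (the $M_2$ model
then regresses on $A, M_1, A{\cdot}M_1, C$), `--m1-ref sample-mean` to
use estimated means as reference levels, and `--transform m2=log` for a
log-normal mediator.

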