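# prucea

A Markov cohort cost-utility model of **prucalopride 2 mg once daily versus
continued laxative treatment** for adults with chronic constipation in whom
laxatives have failed to provide adequate relief, from the Dutch payer
perspective in 2011 euros. The package is aimed at health economists and
HTA analysts who want a transparent, fully configurable reimplementation of
this published model: every input is a plain-YAML config key, every analysis
(base case, tornado, scenario suite, probabilistic sensitivity analysis) is a
library call or a one-line shell command, and a synthetic-data layer lets the
whole pipeline be validated without any external data.

## The model

A treated cohort moves through nine health states in monthly cycles
(1-year horizon in the base case):

```
START_W1_4 ──r4──▶ START_W5_8 ──▶ START_W9_12 ──r12/r4──▶ MAINTENANCE (absorbing)
     │1−r4                             │1−r12/r4
     ▼                                 ▼
SWITCH_W1_4 ──s──▶ SWITCH_W5_8 ──▶ SWITCH_W9_12 ──▶ SWITCH_MAINTENANCE (absorbing)
     │1−s
     ▼
  DROPOUT (absorbing)
```

`r4` and `r12` are the week-4 and weeks-1-12 trial response probabilities
(27.8% and 23.6% for prucalopride; the pooled placebo response, 10.5% and
11.3%, proxies continued laxatives), and `s` = 65.4% is the elicited response
to a second-line laxative switch. A label stopping rule discontinues
prucalopride in week-4 non-responders. Monthly costs (drugs, consultations
and procedures, complication management, transport, and optionally
productivity losses) and utilities (0.78-0.89 per state) accrue on state
occupancy; results are summarized as the incremental cost-effectiveness
ratio, ICER = ΔC/ΔE in € per QALY.

Deterministic sensitivity varies the response bounds and the Dutch DBC
tariffs; the probabilistic analysis draws beta-distributed probabilities and
utilities and gamma-distributed resource quantities (5000 draws) and reports
the ratio-of-means ICER and a cost-effectiveness acceptability curve.
See `docs/methods.md` for the full model description, the calibration of the
under-determined costing layer, and known limitations.

## Worked example

```python
from prucea import default_parameters, run_base_case

result = run_base_case(default_parameters())
print(result.to_frame().to_string(index=False))
```

prints

```
         arm        cost    qalys icer
prucalopride 2511.330307 0.835479
    laxative 2445.468141 0.828684
  difference   65.862166 0.006795 9693
```

A year of the prucalopride strategy costs €2511 per patient and yields 0.835
QALYs, versus €2445 and 0.829 for staying on laxatives: prucalopride buys
0.0068 extra QALYs for €66, an ICER of €9693 per QALY — far below the
€20,000/QALY willingness-to-pay usually applied, so prucalopride is
cost-effective under these inputs. The same run from the shell, plus the
tornado and the probabilistic analysis:

```
$ prucea base-case --out-dir results
$ prucea tornado   --out-dir results
                           parameter     icer_low   icer_high   icer_base
        prucalopride_week12_response 17134.647058 7393.051781 9693.131294
         prucalopride_week4_response 14658.893667 6354.323531 9693.131294
     costs.units.dbc_specialist.cost 13215.913667 6170.348922 9693.131294
costs.units.dbc_hospitalization.cost 10021.308568 9364.954021 9693.131294
$ prucea psa --seed 1 --draws 1000 --out-dir results
ratio-of-means ICER: 9043 per QALY (1000 draws); P(cost-effective at 20,000) = 0.877
```

The tornado shows the model is most sensitive to the prucalopride response
probabilities (ICER range roughly €6400-17,100) and only moderately to the
DBC tariffs; the probabilistic run puts the probability that prucalopride is
cost-effective at €20,000/QALY near 88%. Scenario variants (women-only
population, PAC-QOL satisfaction endpoint, no stopping rule, 3-year horizon
with 4%/1.5% discounting, excluded complications or transport, included
productivity losses, 1.5 mg average dose, LOS-based hospital costs) run via
`run_scenario(params, name)` or `prucea scenario <name>`. Any input can be
overridden in a YAML file passed with `--config`; the shipped defaults are in
`src/prucea/data/default_config.yaml`.

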