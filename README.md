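# trustdelay

Analysis and simulation toolkit for a question in digital-health
epidemiology: **does trust in AI-generated health advice delay people from
seeking professional care, and can population-level interventions break the
trust–delay feedback loop?**

The package is aimed at biostatisticians and computational epidemiologists
studying technology-mediated health behaviour. It reimplements, end to end,
a study design that combines a cross-sectional survey of 2,460 adults with
an agent-based simulation: because the underlying questionnaire data are
not publicly deposited, the package ships a *calibrated synthetic survey
generator* whose marginals and effect sizes reproduce the published
summary statistics, and every downstream analysis runs identically on real
data supplied as a CSV with the same column schema.

## What it computes

**Survey model.** Each respondent carries trust in AI health advice
(ordinal 0–5, 0 = never used), usage frequency (0–5), chronic-disease
status, and a binary delay outcome. Delay follows a logistic model

&nbsp;&nbsp;logit P(delay) = β₀ + β_t·trust + β_f·frequency + β_c·chronic,

with generating odds ratios exp(β_t)=1.09, exp(β_f)=1.40, exp(β_c)=1.42
and the intercept calibrated by bisection so the population delay rate is
11.6%. Frequency follows trust linearly (slope 0.5754) with Gaussian noise,
rounded to the ordinal scale; never-users have frequency 0 by construction.

**Statistical analyses** (`regression`, `mediation`, `scenario`):
univariate screening, four hierarchical covariate blocks, stratified
models (calendar period, exposure, willingness), trust × moderator
interaction fits, Baron–Kenny mediation of trust → frequency → delay with
the Sobel test and a 500-replicate nonparametric bootstrap of the indirect
effect a·b, and six counterfactual scenario predictions.

**Agent-based model** (`abm`): one agent per respondent on a
Watts–Strogatz network (n = 2460, mean degree 4, rewiring probability
0.2). Each day every agent draws a delay decision from the logistic model
on its current trust/frequency (1–5 scale), then updates: delay ⇒ trust
−0.2, frequency −0.3; no delay ⇒ trust +0.1; attraction toward the mean
neighbour trust; a penalty when most neighbours delayed; a global daily
trust decay. Three interventions — *broadcast* (daily trust penalty),
*reward* (periodic bonus for timely care), *rewire* (edges redirected to
the highest-trust decile) — are compared against baseline by pooled
agent-day logistic regression. One-way sensitivity sweeps (`sensitivity`)
vary initial trust, penalty, reward magnitude and rewiring cadence.

## Worked example

```bash
trustdelay generate --n 2460 --seed 1 --out survey.csv
trustdelay mediate survey.csv --n-boot 500 --seed 11 --out mediation.json
trustdelay scenarios survey.csv --out scenarios.csv
trustdelay simulate survey.csv --strategy baseline --trials 100 --days 14 \
    --seed 0 --out trajectory.csv
```

prints

```
wrote 2460 records to survey.csv
indirect effect a*b = 0.1908 (boot p = 0); wrote mediation.json
                    scenario  mean_probability
                    baseline          0.171012
                  high_trust          0.132157
              high_frequency          0.289722
                     chronic          0.134706
        high_trust_frequency          0.328161
high_trust_frequency_chronic          0.368123
baseline: day-1 delay 10.83%, day-14 delay 9.44%, day-14 trust 1.478
```

Reading the numbers: the indirect effect 0.1908 is the product of the
trust→frequency slope (a ≈ 0.57) and the frequency→delay log-odds (b ≈
0.33) — higher trust raises delay odds mainly *through* more frequent AI
use (bootstrap p < .001). The scenario table averages model predictions
after overriding covariates: the fully specified baseline (trust 3,
frequency 3, no chronic disease) gives 17.1%, while single-override
scenarios keep the other covariates at their observed values (which is why
`high_trust` alone, with mostly low observed frequency, sits below that
baseline); the joint worst case reaches 36.8%. The simulation line shows
the feedback loop: the population delay rate erodes from 10.8% to 9.4%
over two weeks as delays suppress usage frequency, while mean trust decays
from ≈2.1 to 1.48. `trustdelay all --seed 1 --out results/` runs every
stage and writes a JSON bundle plus CSV tables.

Programmatic use mirrors the CLI:

```python
import trustdelay as td
records = td.generate_population(td.GeneratorConfig())
fit = td.fit_logistic(records, "delay", ["trust", "frequency", "chronic"])
result = td.bootstrap_indirect(records, n_boot=500, seed=11)
```

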