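# Methods

This note documents the models implemented in `trustdelay`, the choices
made where the design was genuinely open, and what the synthetic-data
pipeline can and cannot establish.

## Synthetic survey generator

The generator emulates a cross-sectional survey of adults (default
n = 2460) on AI health advice. Per respondent it draws:

| field | distribution | default |
|---|---|---|
| trust (0–5) | categorical | (.380, .130, .118, .114, .140, .118) |
| frequency (0–5) | round(clamp(0.5754·trust + N(0, σ), 0, 5)); ≡0 if trust = 0 | σ = 2.0 |
| chronic | Bernoulli, independent of trust | 0.301 |
| delay | Bernoulli(logit⁻¹(β₀ + ln 1.09·trust + ln 1.40·freq + ln 1.42·chronic)) | rate 0.116 |
| age | N(34.46, 11.62²) truncated to [18, 75] | — |
| sex | Bernoulli(female) | 0.547 |
| occupation | categorical (students/technology/other/healthcare) | (.335, .291, .260, .114) |
| exposure, willingness (1–5) | categorical | (.15, .25, .30, .20, .10) |
| submission date | uniform | 2024-12-01 … 2025-05-20 |

The delay intercept β₀ is found by bisection so that the *expected* delay
rate over the realised covariates equals the target (11.6%) to 1e-6; the
realised prevalence then fluctuates with binomial noise only.

**Mediator noise σ = 2.0.** The latent trust→frequency link is linear with
Gaussian noise before rounding/clamping. σ was fixed by matching the two
standard errors the survey reports for the mediation paths (SE(a) = 0.014,
SE(b) = 0.0455): because the 38% never-user block contributes zero
residual variance (frequency ≡ 0 there), a much larger latent σ is needed
than the observed residual spread suggests. At σ = 2.0 the refit
reproduces SE(a) ≈ 0.0136 and SE(b) ≈ 0.0454 at n = 2460, while the
adjusted OLS slope stays at ≈ 0.566–0.574 after rounding and clamping.
A side effect of the never-user constraint worth knowing: even with a
zero generating slope, frequency and trust remain associated through the
never-user block, so zero-slope null checks condition on users
(trust ≥ 1).

Age and sex are generated but carry no generating effect on delay; they
are retained as adjustment covariates because the analyses adjust for
them. Chronic status is generated independently of trust and frequency
(no joint distribution is published); its effect enters only through the
delay model.

**Cleaning rules.** `apply_exclusions` drops records that repeat an
earlier id (first occurrence kept), contain a missing value, were
completed in under 90 s, or report frequency > 0 with trust = 0. Records
are counted once, in that precedence order. `generate_raw_population`
produces an uncleaned submission set (default 11.7% invalid) so the
cleaning stage is exercised end to end.

## Regression engine

Logistic models are maximum-likelihood fits via statsmodels' binomial GLM
(IRLS, tolerance 1e-8, ≤100 iterations). Reporting is odds ratios with
Wald 95% intervals exp(β ± 1.96 SE) — the convention of the tables being
reproduced — rather than profile likelihood. Encoding: sex as male = 1,
occupation one-hot against a *students* reference, ordinal scores treated
as continuous; all recorded in fit metadata. Possible separation
(|β| > 15) or non-convergence flags the fit instead of raising. The four
hierarchical blocks are fixed as: (1) age + sex + chronic, (2) +exposure,
(3) +trust + frequency, (4) +willingness; only the fully adjusted model
has published anchors, so the intermediate assignments are a documented
package convention.

## Mediation

Paths: a from OLS of frequency on trust (+ age, sex, chronic); b and c′
from logistic delay on trust + frequency (+ adjusters); c from the same
model without the mediator. The indirect effect is the product a·b on the
log-odds scale, tested by the Sobel normal approximation and by a
nonparametric case-resampling bootstrap (default 500 replicates at full
n). The bootstrap p-value is defined as the doubled minority-side
proportion of replicates relative to zero; percentile CI endpoints are
order statistics (`closest_observation`), not interpolated. Replicates
with failed or non-converged fits are dropped and counted; > 20% losses
flag the result. Because the outcome model is logistic, the decomposition
is non-collapsible: c need not equal c′ + a·b exactly, and c > c′ is an
empirical (verified) rather than algebraic property.

## Scenario prediction

Scenarios override a subset of {trust, frequency, chronic} for every
respondent and average the fitted-model predictions. With the
three-predictor model and all covariates overridden this collapses to a
point prediction; the averaging form is kept so richer models work
unchanged. The published per-scenario probabilities are not reproducible
from the published coefficients by direct plug-in (the source evidently
used unrounded coefficients or a different baseline), so the package
asserts only the monotone orderings that follow from positive
coefficients, not the printed values.

## Agent-based model

One agent per respondent; trust and frequency operate on [1, 5] with
survey level 0 mapped to 1. The daily cycle is: predict delay probability
→ Bernoulli decision → record statistics (start-of-day state) → update →
clamp. Updates compose additively in a fixed order: personal outcome
(−0.2 trust / −0.3 frequency on delay, +0.1 trust otherwise), peer terms
(gain × (mean neighbour trust − own trust); penalty if the delayed
fraction of neighbours exceeds 0.5), global decay, intervention hook.
Peer statistics use start-of-day trust and same-day decisions
(synchronous update), keeping results order-independent. Networks are
Watts–Strogatz (n = 2460, k = 4, p = 0.2), rebuilt per trial; trial t
uses seed base_seed + t for all of its randomness.

**Delay model scale.** Agents use the published three-predictor
coefficients (ln 1.09, ln 1.40, ln 1.42) with the intercept recalibrated
on the *mapped* 1–5 covariates to the 11.6% survey rate. Evaluating a
0–5-scale fit on mapped values would inflate every agent's risk (the
never-user block shifts by a full unit on both scales); refitting per
sample would make the simulation inherit the refit's coefficient noise
(the trust coefficient varies several-fold across samples at n = 2460).
The published coefficients are the decision rule the simulation is meant
to embody, so they are used directly.

**Vulnerability initialisation.** Agents whose predicted baseline risk
strictly exceeds 0.20 receive a 1-point reduction on trust and frequency
(clamped at 1); ties receive none.

**Calibration of peer gain / peer penalty / decay.** The three magnitudes
are not identified by the survey. They were fixed once by grid search
against the three baseline trajectory anchors (day-1 delay 10.6%, day-14
delay 9.5%, day-14 mean trust 1.49) with all other parameters at their
defaults, minimising squared anchor error scaled by the reproduction
tolerances. The stated update rules make a substantial decay necessary:
~90% of agents gain +0.1 trust daily, so without decay ≥ ~0.1 the
population mean trust *rises*, contradicting the anchored decline. The
frozen values are peer_gain = 0.1, trust_decay = 0.125,
peer_delay_penalty = 0.05 (the penalty is unidentified by the anchors —
a >50% delayed neighbourhood is rare at ~10% delay rates — so the
conventional default is kept). After this one-off calibration every other
simulated quantity is an out-of-sample model output.

**Interventions.** Broadcast subtracts a fixed daily penalty (default
0.10) from trust. Reward grants +0.05 to trust and frequency every 2 days
to agents with no delay in the closing window (window-based, not
since-day-1, so the reward stays attainable at its cadence). Rewire, every
5 days, re-attaches one endpoint of 10% of randomly chosen edges to an
agent drawn uniformly from the top trust decile (ties broken by lowest
id), redrawing on self-loop/duplicate collisions up to 10 times and
keeping the original edge on failure, so the edge count is conserved.
Strategy effects are summarised as odds ratios from a logistic regression
of the pooled agent-day delay indicators (agent × day × trial) on strategy
dummies — computed on the aggregated binomial form, which is exactly the
individual-level fit for a saturated categorical design and explains the
very tight intervals (≈3.4M observations per arm).

**Reproduction limits.** Under these literal update rules the baseline
anchors are met, but the strategy odds ratios come out ≈0.97 (broadcast),
≈1.04 (reward), ≈1.00 (rewire) against the published 0.94 / 1.01 / 1.04.
The discrepancies are structural, not a matter of tuning: broadcast's
effect is attenuated because decay already holds much of the population
near the trust floor where the extra penalty cannot bind; the specified
reward (trust *and* frequency bonus for ~80% of agents every cycle) is
stronger than the published 1.01 implies; and rewiring influences delay
only through the mean-reverting peer-gain term, which is too weak to
reproduce the published amplification (and consequently the published
ordering reward < rewire is not reproduced either). These three
quantities are reported as computed; the corresponding reproduction test is
left failing rather than calibrated toward, since the peer/decay
parameters are frozen on the baseline anchors alone.

## Sensitivity sweeps

One-way sweeps over initial trust mean (location-shift of the mapped
trust distribution before risk assessment, clamped to [1, 5]), broadcast
penalty, reward magnitude and rewiring interval. All runs share per-trial
seeds so trajectories differ only through the swept parameter; the
default grids are the anchor values of the published ranges
({2.5, 3.0, 3.5}, {0.05, 0.1, 0.2}, {0.03, 0.05, 0.1}, {2, 5, 10} days).

## Problem sizes and numerics

Default analyses run at the survey scale (n = 2460; 100 trials × 14 days
for simulations; 500 bootstrap replicates; 50-sample averages for
recovery summaries). Property tests use reduced sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances (stated per test).
Numerical conventions: intercept bisection to 1e-6 on the rate; IRLS
tolerance 1e-8; Wald z at 1.96; trust/frequency clamping applied once per
day after all updates; empty neighbourhoods contribute zero peer terms.

## What the synthetic pipeline does and does not show

Passing tests demonstrate that the implementation recovers its own
generating parameters at the published precision and that the simulation
reproduces the anchored dynamics under the stated rules. They do not
validate the substantive claims on real populations: the generator makes
independence assumptions (chronic status independent of trust; no
age/sex effects on delay; no unmeasured confounding) that real survey
data would not satisfy, and the mediation decomposition remains a
cross-sectional, non-causal summary. Real data in the documented CSV
schema can be substituted for the generator throughout.

## Known limitations

- Mediation is on the log-odds scale with a logistic outcome;
  non-collapsibility caveats apply, and no counterfactual-scale or
  multiple-mediator decomposition is attempted.
- The published per-scenario probabilities and the published bootstrap
  mean (0.2152, above its own point estimate 0.1949) are internally
  inconsistent with the published coefficients and are not reproduction
  targets.
- Two published age SDs conflict (1.62 in a table, 11.62 in the text);
  the generator uses 11.62.
- The ABM has no learning, birth/death, geographic structure or
  continuous-time dynamics; whether personal and peer updates are
  additive is an implementation assumption, documented above.
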