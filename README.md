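# crmed

Bayesian continual-reassessment dose-finding for minimum-effective-dose
(MED) trials, built around a neonatal trial of omeprazole for pathological
acid reflux: five candidate doses (1–3 mg/kg/day), an efficacy target of
95%, cohorts of three, up to 30 patients per gestational-age stratum, and a
treatment-success endpoint defined on 24-hour esophageal pH monitoring
(reflux index < 5%).

The package is for biostatisticians and trialists who want to **replay,
audit and simulate** such designs: it re-runs a recorded trial cohort by
cohort and checks every allocation against the model's recommendation,
computes final recommendations with credibility intervals, pools results
across strata through an allocation-weight simulation, derives the
pH-metry endpoint from raw traces, and estimates the design's operating
characteristics by simulation.

## The model

Each dose $d_i$ carries an elicited prior success probability
$\alpha_i$ (the *skeleton*; here $0.50, 0.70, 0.85, 0.95, 0.99$). A
one-parameter power working model deforms the skeleton,

$$p_i(a) = \alpha_i^{\exp(a)}, \qquad a \sim \mathcal N(0, \sigma^2),$$

and patient outcomes are independent Bernoulli given dose, so after
$s_i$ successes and $f_i$ failures at each dose

$$\pi(a \mid \text{data}) \propto \pi(a)\prod_i p_i(a)^{s_i}\,\bigl(1-p_i(a)\bigr)^{f_i}.$$

All posterior quantities are computed by deterministic trapezoidal
quadrature. After each cohort the next one is allocated to the dose whose
estimated success probability is closest to the target $\theta = 0.95$
(ties to the lower dose — the minimum-effective-dose reading). Stage 1
stops at the patient cap, on credible futility at every dose, or when one
further cohort could no longer move the estimates (predictive gain); stage
2 then accrues at the MED until its 95% credibility interval is tight.

The original analysis program and its prior are not public; the prior
scale $\sigma$ and the point-estimator variant are *calibrated* so that the
posterior after the trial's first recorded cohort matches the first printed
posterior row as closely as the model family allows (the shipped default is
$\sigma \approx 3.46$ with the plug-in estimator
$\alpha_i^{\exp(\mathbb E[a])}$). See `docs/methods.md` for why a small
residual deviation is irreducible and how large it is.

## Worked example

Replay the packaged under-32-week cohort history (the `crmed` console
script is installed with the package):

```sh
crmed replay src/crmed/data/lt32_history.tsv
```

prints one row per cohort (dose given, successes, per-dose posterior means,
running MED estimate), ending with

```
cohort  dose  success  p(1)   p(1.5) p(2)   p(2.5) p(3)   med  discrepancy
1       2.0   3/3      0.945  0.971  0.987  0.996  0.999  1.0  False
2       1.0   2/3      0.803  0.893  0.95   0.984  0.997  2.0  False
...
11      2.0   1/1      0.683  0.822  0.915  0.972  0.994  2.5  False
allocation check: 1 discrepant non-forced cohort(s): [6]
final MED 2.5 mg/kg/day, mean 0.972, 95% CI (0.924, 0.993)
```

Reading: after cohort 1 (three successes at 2 mg/kg) every dose's estimate
rises and the dose closest to the 95% target is 1 mg/kg, which is exactly
where the trial sent cohort 2. The trial ends at the patient cap with MED
2.5 mg/kg/day and posterior success probability 0.972 (95% credibility
interval 0.924–0.993). The single flagged discrepancy is the one step where
the recorded trial stayed at 2 mg/kg while the reconstructed posterior puts
2.5 mg/kg marginally closer to target.

Pooling the over-32-week outcomes (18 neonates at 1 mg/kg with one failure,
6 at 2 mg/kg with none) through the allocation-weight simulation:

```python
import crmed
from crmed import datasets
from crmed.pooling import allocation_weights, pooled_recommendation

config, prior = crmed.default_design(), crmed.default_prior()
pooled = datasets.ge32_pooled_counts()
w = allocation_weights(pooled, config, prior, n_sims=5000, seed=1)
print(w.weights.round(3))          # [0.447 0.256 0.203 0.059 0.035]
print(config.grid.doses[pooled_recommendation(w, pooled, config)])  # 1.0
```

The observed frequency at 1 mg/kg (17/18 ≈ 0.944) sits closest to the 0.95
target, so simulated CRM trials concentrate allocation there and the pooled
recommendation is 1 mg/kg/day.

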