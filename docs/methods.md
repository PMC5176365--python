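# Methods

## The design being modelled

An efficacy-targeted continual reassessment method (CRM) for finding the
minimum effective dose (MED) of omeprazole in neonates with pathological
acid reflux. Five doses (1, 1.5, 2, 2.5, 3 mg/kg/day) carry elicited prior
success probabilities (the skeleton: 0.50, 0.70, 0.85, 0.95, 0.99 — the
highest dose was elicited at 100% and enters the model clipped to 0.99,
since a success probability of exactly 1 can never be revised by failures
under a power-type model). Success is a reflux index below 5% on 24-hour
esophageal pH monitoring after treatment. Cohorts of three are allocated
sequentially to the dose whose estimated success probability is closest to
the 95% target, up to 30 patients per gestational-age stratum.

## Working model, prior, estimators

The one-parameter power model `p_i(a) = alpha_i ** exp(a)` with a
zero-centred normal prior on `a` (Laplace and Cauchy families are also
available). The model is monotone in dose for every `a` and reduces to the
skeleton at `a = 0`; the exponential link keeps the deformation exponent
positive. Outcomes are independent Bernoulli given dose.

Two per-dose point estimators are implemented:

- **plug-in** (default): `alpha_i ** exp(E[a | data])`;
- **full posterior mean**: `E[alpha_i ** exp(a) | data]`.

The plug-in variant is the default because it reproduces the skeleton
exactly at zero data (a consistency property the package treats as a
contract: the reported "prior" row must be the elicited one) and because
it anchors the first recorded posterior update more closely (maximum
deviation 0.0138 vs 0.0172 for the posterior-mean variant). The
posterior-mean variant remains available and is exercised throughout the
tests.

### Prior-scale calibration and its irreducible residual

The trial's analysis program and prior are not public. The prior scale is
therefore calibrated: `calibrate_prior_scale` minimises the maximum
absolute deviation between the model's posterior row after the first
recorded cohort (3/3 successes at 2 mg/kg) and the first printed posterior
row (0.931, 0.985, 0.997, 1, 1), and `calibrate` additionally selects the
estimator variant by the same criterion. The shipped default is
`sigma = 3.4599`, plug-in.

No member of this model family can match that anchor row exactly. Along
the power-model curve, the probability at one dose determines the
probability at every other: `p_2 = p_1 ** c` with
`c = ln(0.7)/ln(0.5) < 1`, which is concave, so for *any* prior on the
exponent, Jensen's inequality caps `E[p_2] <= E[p_1] ** c`. With
`E[p_1] = 0.931` that cap is 0.964, while the printed row has 0.985. The
best attainable minimax deviation on the anchor is about 0.014, and the
calibration reports its achieved value rather than hiding it. Replaying
the full recorded trial with the calibrated prior reproduces the
near-target (highlighted) entries of the printed sequential trace to about
0.01 and the final summary to well under 0.01 of probability, while
low-dose entries — far from where data accrue and irrelevant to
allocation — deviate by up to about 0.12. One allocation step differs: the
recorded trial kept 2 mg/kg for cohort 7 where every reconstructed
posterior puts 2.5 mg/kg marginally closer to target (the printed table is
itself equivocal at the neighbouring step: its highlighted MED there
contradicts the dose the trial gave next, so no closest-to-target rule can
reproduce both). The replayed credibility interval at the MED,
(0.924, 0.993), is somewhat narrower than the printed (0.903, 0.997) —
consistent with the reconstructed posterior family being tighter than the
original's.

Calibration is identifiable for scales roughly in 0.05–30: beyond that the
anchor row saturates at 1 (the plug-in exponent collapses to 0) and all
large scales fit equally well; the round-trip recovery tests therefore
span 0.1–10.

## Allocation, stopping, stage 2

- **Allocation / MED estimate**: argmin over doses of
  `|estimate - target|`; exact ties break to the lower dose. No
  dose-skipping constraint (the recorded trial moved 2 -> 1 -> 2 -> 2.5).
- **Stage-1 stop rules** (checked in order after each cohort):
  1. cap reached (`max_n = 30` per stratum, detected at exactly 30);
  2. futility: posterior probability that even the highest dose's success
     probability lies below `target - stop_low_margin` exceeds
     `stop_low_confidence` (defaults 0.10 and 0.90 — the quantitative
     forms are not published; these conventional magnitudes are
     config-overridable and the recorded trial never triggers them);
  3. predictive gain: the posterior-predictive expected maximum change in
     any dose's estimate from one further cohort at the recommended dose
     falls below `predictive_gain_eps` (default 0.01). The expectation
     enumerates all `cohort_size + 1` outcomes exactly; a brute-force
     oracle test recomputes every hypothetical posterior from scratch.
- **Stage 2**: fixed-dose cohorts at the MED until the credibility
  interval half-width is at most `stage2_ci_halfwidth` (default 0.05) or
  the cap is reached. If the updated recommendation moves off the MED,
  accrual stops, the shift is reported, and control returns to stage-1
  logic — the published design does not specify this case; stopping and
  re-entering is the conservative reading of the closest-to-target
  contract. For interval-reliability simulations the shift exit can be
  disabled (`stop_on_shift=False`) so accrual runs to the width criterion.

Measured at 10 000 replicates with the truth equal to the target at the
MED, the stage-2 interval's frequentist coverage is ≈ 0.98, not 0.95: the
prior is centred on the truth and accrual stops on a width criterion, so
the equal-tailed credibility interval is conservative (a miss essentially
requires the posterior 2.5% quantile to exceed the truth, which even
all-success runs do not produce). The defaults were fixed before this
measurement and left alone.

## Cross-stratum pooling

Per-dose success/failure counts from the strata are summed. The observed
marginal frequencies define a simulation truth; doses never allocated take
the model-smoothed estimate (posterior point estimate under the calibrated
prior given the pooled counts). `n_sims` (default 5000) stage-1 CRM trials
are simulated under that truth — starting dose drawn uniformly, all stop
rules active — and each dose is weighted by its share of all simulated
patient allocations. The pooled recommendation is the maximal-weight dose,
ties to the lower dose. Rationale: CRM allocation concentrates at the dose
it would recommend, so allocation share is a Monte-Carlo vote under the
observed frequencies; with the recorded over-32-week outcomes (17/18 at
1 mg/kg, 6/6 at 2 mg/kg) the weight concentrates at 1 mg/kg and the
recommendation is stable across seeds.

## pH endpoint

Traces are step functions (hold-last-value, matching clinical recorders;
linear interpolation is an option). Reflux requires pH strictly below 4 —
a sample at exactly 4.0 is not reflux. Episodes are maximal contiguous
sub-threshold intervals; the default minimum episode duration is 0 s (the
endpoint is defined without a filter; clinical software often uses 15 s,
so it is configurable). Reflux index = 100 × time below 4 / record
duration; success is RI < 5 strictly (the inclusion threshold was
RI ≥ 5%). With no duration filter, episode time and the per-sample
fraction-of-time computation agree identically (tested as an oracle
identity).

## Synthetic data

`simulate_trial` draws independent Bernoulli responses given dose — the
design's own assumption; no within-patient correlation, covariates,
drop-out or response drift are modelled, so passing simulations validate
the *design logic*, not clinical realism. `synth_ph_trace` builds regular
step traces (default 4 s sampling, typical of antimony probes) hitting a
prescribed reflux index within one sample's worth of percentage, with an
exact episode count; it does not emulate recorder noise, meals or probe
drift. All generators are deterministic per seed (replicates use spawned
child seeds).

## Numerical choices

- Posterior quadrature: symmetric trapezoidal grid in `a`, 6001 points
  (1501 inside simulation loops), initial half-width 12 prior scales,
  widened ×1.5 until the relative mass of the outermost cells is below
  1e-8; sequential updates reuse the grid (density times the cohort's
  likelihood factor) and fall back to full recomputation if boundary mass
  reappears. Agreement with a 10×-resolution Riemann oracle is at machine
  precision on all recorded-trial datasets (tested at 1e-4).
- Credibility intervals are equal-tailed and exploit monotonicity:
  `p_i(a)` is strictly decreasing in `a`, so interval ends are the
  skeleton raised at interpolated CDF quantiles of `a`.
- Ties in every argmin/argmax rule break toward the lower dose.
- Reports round half-up to 3 decimals; all comparisons in code use
  unrounded values.

## Problem sizes

The shipped tests replay the 11-cohort recorded history in seconds; the
pooling check runs 3 × 5000 simulated trials (about a minute each batch);
operating characteristics use 1000 replicates and the coverage study 2000
(10 000 when measured offline). These sizes give Monte-Carlo standard
errors comfortably below the margins being asserted.

## Known limitations

- The original analysis software is unavailable; the calibrated power
  model is a declared reconstruction whose residual deviations from the
  printed trace are quantified above, not eliminated.
- Stage-1 futility and predictive-gain thresholds and the stage-2 width
  rule are declared substitutes for unpublished rules.
- The pooling weight simulation reconstructs a published procedure from a
  prose description; its starting-dose distribution (uniform) is a choice.
- Printed posterior values of "1" are treated as ≥ 0.995 where exactness
  matters.
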