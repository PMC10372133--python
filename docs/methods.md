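# Methods

## The burden model

Intraoperative hypotension is summarized per patient by the time-weighted
average (TWA) of mean arterial pressure (MAP) beyond a threshold:

    AUC = ∫ max(0, threshold − MAP(t)) dt        (mmHg·min, "below")
    TWA = AUC / monitoring time                   (mmHg)

and the analogous quantity above hypertension thresholds. The trace is
treated as piecewise linear between the monitor's 20-s samples; episode
boundaries are the linearly interpolated threshold crossings, and the AUC
is the exact trapezoid integral of the clipped deficit, so on piecewise-
linear fixtures the implementation agrees with closed-form areas to
machine precision.

Two definitional choices interact here and are reconciled as follows:

* **Events** require strictly more than 60 s beyond the threshold (a
  literal reading of "for > 1 min"); MAP exactly at the threshold counts
  as the non-excursion side because the clinical definitions are strict
  inequalities.
* **Areas** integrate *every* excursion, including sub-minute ones,
  because the area is defined purely by threshold crossing. A flag
  (`auc_qualifying_only`) restricts the AUC to qualifying events for
  sensitivity analyses.

The TWA denominator is the elapsed time between the first and last
measurement in the analysis window. Recording gaps (inter-sample interval
greater than 1.5× the nominal 20 s) contribute neither area nor
time-below-threshold; they stay in the denominator unless they exceed
`max_gap_s` (default 300 s), in which case they are excluded from it. No
excursion is interpolated across a gap, so a dip interrupted by a dropout
is split in two. Samples are never imputed.

Two analysis windows are supported: the full monitoring span and the
first 20 min after induction of general anesthesia, `[t_ind, t_ind +
1200 s]`, truncated at end of monitoring; a truncated window uses its
truncated duration as the TWA denominator (the alternative — a fixed
20-min denominator — would understate the induction burden of short
records).

## Alarm episodes

The predictive risk index (0–100) is only defined at sample times, so the
alarm automaton runs on the sample grid: an alarm opens after the index
has sat at or above 85 for at least 60 s of consecutive samples
(⌈60/dt⌉ = 3 samples at 20 s) and closes only after 60 s of consecutive
normalized samples, so two high spells separated by a shorter dip merge
into a single alarm. The alarm spans from the first sample of the opening
run to the last at-or-above-trigger sample.

## Protocol engines

Both treatment algorithms are pure functions from a hemodynamic state
snapshot to a recommendation.

**Intervention arm.** No action below the index trigger (85). Above it,
branches are evaluated in the order hypovolemia → contractility →
vasoplegia: SVV > 13% recommends a 250-ml fluid bolus (plus
norepinephrine when Ea_dyn is simultaneously low); otherwise dP/dt_max
below its low bound recommends dobutamine starting at 2.5 mcg·kg⁻¹·min⁻¹;
otherwise low Ea_dyn recommends norepinephrine starting at
0.1 mcg·kg⁻¹·min⁻¹. If no mechanism is flagged the engine falls back to
pressure support (tag `pressure_only`). Only the SVV cutoff is a protocol
constant; the dP/dt_max bound (400 mmHg/s) and Ea_dyn bound (0.9) are
configurable implementation defaults chosen from conventional clinical
reference values, not trial parameters.

**Control arm.** During initial optimization, fluid loading continues up
to a 500-ml cap. Afterwards a 250-ml challenge is recommended iff SVI has
fallen strictly more than 10% from the running maximal-SVI reference or
SVV > 13%; a vasopressor is recommended — independently — iff MAP < 65;
both conditions give fluids plus vasopressor. The control engine can
never emit an inotrope. Optimization is declared complete when the most
recent challenge produced no ≥10% SVI rise sustained for more than
10 min (evaluated on sample timestamps).

**Latencies.** Each alarm (intervention arm) or hypotensive-episode onset
(control arm) is paired with the first treatment in `[onset, next
onset)`; untreated events contribute no latency. This matches a
first-intervention-per-event rule without double counting, at the cost of
a mild downward censoring when latencies exceed the inter-event spacing —
visible in the synthetic control arm, whose measured median latency
(~165 s) sits slightly below the generating median (190 s).

## Synthetic cohorts

The generator emulates the *data structure* of a 30 + 30 two-arm trial,
not individual physiology. Per patient:

* monitoring duration is log-normal (medians 253 / 325 min, log-SDs
  0.354 / 0.419 chosen so the quartiles match the reported 201–324 /
  220–387 min ranges);
* MAP is a plateau (mean 78, SD 3 mmHg between patients) plus a slow
  AR(1) wander (SD 2 mmHg, 10-min time constant) and white measurement
  noise (SD 0.8 mmHg);
* hypotensive episodes are raised-cosine dips. Counts are negative
  binomial (means 2.2 / 7.0, dispersions 1.4 / 3.0 — over-dispersed
  because the reported count IQRs, 1–5 and 5–13, are wide relative to
  their medians), with an additional induction-window dip with
  probability 0.67 / 0.94. Nadir depth below 65 mmHg is gamma(3, 4.2)
  (mean ≈ 12.6 mmHg) and per-episode below-threshold time is log-normal
  (medians 2.6 / 4.4 min). The cosine window width is solved in closed
  form from the plateau-to-threshold gap so that the time below threshold
  equals the sampled duration, which keeps the dip areas analytically
  known and lets the burden oracles use exact references;
* hypertensive excursions are upward cosine bumps at Poisson rates 0.7 /
  0.13 per patient;
* the intervention arm carries a synthetic risk-index channel: a logistic
  transform of the forward-looking (120-s lead) minimum of the latent MAP
  plus noise, plus occasional false-alarm bumps (0.2/h). This reproduces
  "index crosses 85 shortly before a dip" behaviour and nothing more;
* mechanism channels (SVV, SVI, dP/dt_max, Ea_dyn) deviate from their
  baselines around each dip according to the dip's sampled mechanism
  (hypovolemia 45%, vasoplegia 35%, low contractility 20%);
* treatments are placed at alarm onset (intervention arm) or episode
  onset (control arm) plus a log-normal latency (medians 60 / 190 s,
  log-SDs 1.44 / 1.27 matched to the reported 20–140 / 78–431 s
  quartiles), with kind chosen by dip mechanism (intervention) or a
  fixed clinical mix (control).

All randomness derives from one seed; per-patient substreams come from a
CRC-32 hash of the patient id, so generation is order-independent and
cohorts serialize byte-identically for a fixed config.

The dip parameters were derived from the closed-form cosine-area algebra
targeting the arm-level medians (TWA ≈ 0.14 / 0.77 mmHg, 2 / 7 events,
7 / 35 min below threshold) and then verified against the pipeline's own
medians over seeds before being frozen; the calibration test asserts that
per-arm medians fall inside the reported interquartile bands for at least
80% of 20 seeds. Because only arm-level medians/IQRs are targeted, the
generator makes no claim of distributional fidelity beyond those
summaries: passing calibration shows the pipeline behaves correctly on
trial-shaped data, not that the generator reproduces real intraoperative
physiology (no surgical covariates, no autocorrelated treatment effects,
no artifacts).

A closed-loop mode (`generate_cohort(..., engine_blunting=f)`) runs the
intervention-arm rule engine at each dip's alarm and multiplies treated
dip depths by `f` (durations by 0.7), which demonstrates that engine-
guided intervention strictly lowers the arm's median TWA on paired seeds.

## Statistics

Continuous outcomes: median (25th–75th percentile, linear-interpolation
quantiles) per arm; two-sample Wilcoxon rank-sum (exact by enumeration
when the pooled sample is ≤ 12 without ties, otherwise normal
approximation with tie and continuity correction — the continuity
correction is a flag, default on); Hodges-Lehmann location shift = median
of all m×n pairwise differences, with asymptotic 95% CI taken at the
k-th/(mn+1−k)-th ordered differences, k from the normal approximation to
the null Mann-Whitney distribution. Categorical outcomes: Pearson
chi-square without continuity correction, switching to Fisher's exact
test (two-sided, sum-of-small-p) when any expected cell is below 5.
Identical constant samples are reported as p = 1 rather than undefined.

Planning: two-sided two-sample t-test power is evaluated exactly from the
noncentral t distribution (df = 2n−2, noncentrality d·√(n/2)) and
inverted by bisection for the required per-group n. Reported effect sizes
use two-decimal round-half-to-even. Note a fine point of the planning
arithmetic: the exact 75% reduction of a 0.5 mmHg control mean (d =
0.375/0.51 = 0.735, which prints as 0.74) gives power 0.7997 at n = 30,
whereas the rounded planning means (0.5 vs 0.12 mmHg, d = 0.745) give
power 0.810 at n = 30 and 0.796 at n = 29 — so n = 30 per group follows
from the printed planning means, and that is the chain this package
reproduces.

## Problem sizes and numerical choices

The test suite and the acceptance script generate cohorts of 60 patients
(~250–330 min at 20-s sampling, ≈ 900 samples per patient); calibration
uses 20 seeds and the Hodges-Lehmann coverage property 200 seeded
replicates of 30 + 30 samples — sizes chosen to make the Monte-Carlo
assertions stable while keeping a full run in seconds. Dense-grid oracles
use 1-s (burden) or 0.05-s (crossing) resolution. Ties in MAP at exactly
the threshold are resolved to the non-excursion side everywhere.
Degenerate inputs (series with < 2 samples, empty analysis windows,
zero-margin contingency tables, empty samples) raise validation errors
rather than returning NaNs.

## Known limitations

* The risk-index channel is a phenomenological stand-in for a proprietary
  waveform-based predictor; sensitivity/specificity of real predictors is
  not modelled, only lead-time behaviour with a small false-alarm rate.
* The secondary-screen cutoffs for dP/dt_max and Ea_dyn are defaults, not
  trial values; analyses that depend on them should treat them as tunable.
* Latency pairing censors treatments that arrive after the next event
  onset; with dense events and long latencies this biases medians down.
* Patient-level trial data are not public, so arm-level medians/IQRs are
  the only calibration targets available; individual-trace realism is out
  of scope.
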