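# Methods

## The model

`icpforecast` treats ICP forecasting as six independent binary
classification problems, one per 10-minute interval of the coming hour. The
response of interval *t + k* is class 1 (mean ICP < 20 mmHg) or class 2
(mean ≥ 20 mmHg); the predictors are the three-level third-quartile codes of
the six intervals ending at the present time *t*. For each horizon the
posterior is Bayes' rule on a class prior and a class-conditional history
distribution, both estimated by (optionally Laplace-smoothed) maximum
likelihood. No trend, seasonality or cross-patient random effect is
modelled: the working assumptions are that the discretized series is
approximately stationary over a recording and that one hour of history
carries the predictable signal.

Two factorizations of P(history | class) are implemented:

* **`per_lag`** (default): conditional independence of the six lag codes
  given the class — one categorical distribution per lag position and class
  (36 free parameters per horizon). This is the robust choice at clinical
  data sizes and is the model the synthetic interval generator samples from.
* **`joint`**: one table over all 3⁶ = 729 histories per class. Exact but
  sparse; it exists mainly so the posterior can be checked against
  brute-force contingency counting, and for users with very long recordings.

Missing lag levels are marginalized out of the likelihood (drop the factor
per-lag; sum the axis jointly), so prediction degrades gracefully rather
than failing. A history that is entirely missing, or that has zero
probability under both classes (possible with smoothing 0), falls back to
the class prior and is flagged.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `d1` | 6 intervals | history length (one hour) |
| `m` | 6 intervals | horizons predicted (one hour ahead) |
| level thresholds | 15, 20 mmHg | Q3 discretization boundaries; boundary values go to the upper level |
| response threshold | 20 mmHg | class-2 boundary on the interval mean (≥ 20 is severe) |
| `smoothing` (λ) | 1.0 | Laplace pseudo-count; 0 reproduces pure ML for exactness checks |
| `alpha` (α) | 0.60 | balancing factor of the decision rule; 1 = MAP |
| `w` | 2.0 | weight of class-2 accuracy gain in the T criterion |
| α grid | 0.50–0.85, step 0.05 | search grid for `select_alpha` |
| `min_samples` | 8 of 10 min | minutes required for a valid interval |
| `max_gap_minutes` | 2 | longest missing run repaired by linear interpolation |
| `B`, `level` | 1000, 0.95 | bootstrap replicates and CI level |

## Preprocessing choices

Intervals are anchored at each patient's first recorded minute (no calendar
alignment); the interval count is ⌊span/10⌋. The third quartile uses linear
interpolation between order statistics (numpy's default, the "type 7"
convention) — with only 10 samples per interval the convention matters, so
it is configurable (`quantile_method`). Intervals with fewer than 8 observed
minutes are invalid: short dropouts are tolerated without biasing the mean,
longer ones invalidate the interval. Prediction windows require `d1`
consecutive valid intervals and a valid response interval, and never span a
patient boundary — the model conditions on one contiguous hour. Waveform
artifact detection is out of scope; input is assumed to be minute-resolution
with artifacts already removed or marked missing, and gap interpolation (≤ 2
min, linear, interior gaps only) stands in for residual dropouts.

## Decision rule and α selection

MAP and enhancement ties resolve to class 2, the clinically conservative
alert. `select_alpha` computes class-wise accuracies at every grid α and at
the α = 1 baseline on a validation window set, forms
T = A·f₁ + w·(1−A)·f₂ per horizon and pooled, and picks the pooled maximizer
subject to T > 0, taking the *largest* α among maximizers (least
intervention); if no grid point achieves T > 0, α stays at 1. One α is
shared across horizons by default (per-horizon winners are reported in the
result). In `evaluate_split`, α is selected on the training anchors only,
never on the test split, to avoid leakage.

Because lowering α can only flip predictions from class 1 to class 2,
sensitivity is non-decreasing and specificity non-increasing as α decreases
on any fixed model and test set — this monotone trade-off is asserted as a
property test, as is the identity of the α = 1 rule with MAP.

## Evaluation designs

* **Random split** — within each patient, window anchors (with all six of
  their horizon rows attached, so the same future interval never lands on
  both sides) are split 80/20, train share rounded half-up. Specificity is
  the accuracy on true class-1 rows, sensitivity on true class-2 rows, per
  horizon and per decision rule. Percentile-bootstrap CIs resample
  prediction rows within each (class, horizon) cell; the percentile
  interval of a mean of 0/1 rows is exactly Binomial(n, p̂)/n, which the test
  suite exploits as a closed-form oracle.
* **Leave-one-patient-out** — the model is fitted on all other patients'
  windows and evaluated on the held-out patient's full continuous window
  stream. Per-patient class-wise accuracies are combined into a weighted
  mean, each patient weighted by its own proportion of the relevant response
  class (normalized over patients), with the min–max range reported
  alongside; a patient with no truths of a class contributes nothing to that
  class's mean.

## The synthetic cohort

`generate_cohort` draws a two-state (normal/elevated) first-order Markov
regime chain at minute resolution with Gaussian emission noise, clipped at
0 mmHg, plus geometric-length missing gaps. Defaults: normal regime
13 ± 2 mmHg, elevated 24 ± 3 mmHg, mean dwell 90 min normal / 20 min
elevated — stationary elevated fraction 2/11 ≈ 0.18, matching the ~82/18
class imbalance of real monitoring data and giving a unimodal ICP density
with a right tail; missingness ≈ 2.5% of minutes in gaps of mean 5 min. The
chain's stationary distribution is closed form, which the tests compare
against realized marginals.

What the generator does **not** emulate: pulse/respiratory waveform
morphology, B-waves, plateau-wave ramps, treatment feedback (real elevated
episodes end because clinicians intervene), or between-patient
heterogeneity in baseline ICP. Consequently, passing tests demonstrate the
pipeline's correctness and the qualitative accuracy patterns (horizon
degradation, the sensitivity/specificity direction of the balancing rule),
not clinical-grade accuracy numbers. Note also that with the default 20-min
mean elevated dwell, most episodes are over within the hour being predicted,
so sensitivity at far horizons is intrinsically low on default cohorts; with
persistence raised to the hour scale (e.g. transition rates 1/540 and 1/120,
same 0.18 stationary fraction) the evaluated accuracies take the familiar
shape of clinical reports — high specificity throughout, sensitivity
decaying from ~0.88 at 10 min to ~0.58 at 60 min. `generate_interval_windows`
samples directly from a fully specified per-lag model and is the basis of
the parameter-recovery checks (±0.02 at 20,000 windows, several binomial
standard errors at the balanced prior used there).

## Numerical choices and degenerate inputs

Posteriors are products of at most seven probabilities, so computation is in
plain probability space (no log-space needed); normalization is exact to
1e-12 and asserted. Unsmoothed fits may contain zero cells; a query that
zeroes both classes returns the prior with a flag rather than 0/0. Interval
tables serialize to CSV with 0-based indices; models serialize to JSON
(priors, tables, mode, λ, α, w, d1, m) and round-trip exactly. All
randomness (cohort simulation, splits, bootstrap) flows through seeded
`numpy` generators; CLI runs log their fully resolved configuration.

Problem sizes in the test suite were chosen to exercise every code path at
comfortable statistical power: hand-countable fixtures (8 rows) for exact
arithmetic, ≤ 200-row random datasets for the brute-force Bayes oracle,
20,000 windows for parameter recovery, ten 5-patient cohorts for the
directional properties, and one 10-patient × 200-hour cohort for the
end-to-end pipeline.

## Known limitations

* Single-signal model: arterial pressure, CPP and static covariates are not
  ingested (the Bayes factorization extends to them, but no such hooks are
  implemented).
* The α search optimizes mean accuracy gains; it ignores the temporal
  clustering of errors (false alarms near true episode boundaries are
  counted the same as isolated ones).
* LOOCV weighting follows the class-proportion convention described above;
  other weightings (e.g. by monitoring time) would change the summary but
  not the per-patient rows, which are always reported.
* The bootstrap resamples rows independently within cells and therefore
  understates uncertainty if consecutive windows of one patient are strongly
  dependent, as they are in continuous recordings.
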