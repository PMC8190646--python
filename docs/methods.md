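# Methods

## The estimand and the pipeline

The package compares fever exposure between cases treated with one
antipyretic ingredient (single) and more than one (combination) in
caregiver-logged home data. The unit of analysis is the **case**: all
antipyretic administrations within 72 hours of a child's first unassigned
dose, windowed greedily left-to-right with half-open intervals
`[start, start + 72 h)` — so a dose at exactly +72 h opens the next case,
every dose belongs to exactly one case, and a child can contribute several
cases.

Fever exposure is the area under the temperature-change curve. With
baseline *B* (the temperature at the first administration of the case) and
T(t) the linearly imputed temperature,

    AUC(h) = ∫₀ʰ (T(t₀+t) − B) dt      h ∈ {6, 8, 10, 12} hours,

evaluated as a trapezoidal sum on the hourly grid t₀ + 0, 1, …, h. Negative
values mean net defervescence. Two analysis populations are formed by
baseline ≥ 38.0 ℃ and ≥ 39.0 ℃ (non-strict, nested). Groups are compared
per horizon with the pooled-variance Student *t* test; frequency rows use
Pearson chi-square without continuity correction; standardized mean
differences use Cohen *d*; "Total" columns are exact two-component mixture
moments.

### Assumptions

- **Local linearity.** Between two neighboring readings the temperature is
  assumed to progress linearly. All imputation, crossing placement and
  hourly resampling follow from this one assumption; no extrapolation is
  ever performed outside a child's observation span.
- **Fever definition.** Febrile = interpolated temperature ≥ 38.0 ℃
  regardless of age or measurement site. Ties at exactly 38.0 count as
  febrile; the threshold is configurable.
- **Case independence.** Cases are treated as independent observations in
  the t tests, as is conventional for this design, even though one child
  can contribute several cases.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| fever threshold | 38.0 ℃ | episode onset/offset and eligibility |
| AUC thresholds | 38.0, 39.0 ℃ | baseline populations for the comparison |
| horizons | 6, 8, 10, 12 h | AUC integration spans |
| case window | 72 h | dose-anchored analysis unit |
| baseline tolerance | 1 h | nearest-reading fallback when the window start is outside the observation span; beyond it the case is flagged baseline-missing and excluded from AUC analyses |
| max imputation gap | off (suggest 12 h) | optional refusal to impute across long silent gaps when segmenting episodes |
| Cohen d pooling | equal-weight | √((s₁²+s₂²)/2); n-weighted pooling available |

Weight bounds [2, 50] kg and age bounds [0, 7000] days are closed
intervals; age is measured at the child's first record, the deterministic
choice closest to screening at enrollment. A "fever record" for
eligibility means at least one reading at or above the fever threshold,
not merely any temperature row.

## Design choices that were genuinely open

- **Crossing placement.** Episode onset/offset are the analytic crossing
  times of the interpolant, not the first supra-threshold reading. This is
  the only choice consistent with the linearity assumption and makes
  durations well defined between sparse readings. A degenerate episode
  (single febrile reading between sub-threshold neighbors) has zero
  duration; an episode still febrile at the last reading is **unresolved**
  and reported without offset/duration — resolved and unresolved durations
  are never pooled.
- **Truncated AUC grids.** When a child's series ends before
  t₀ + horizon, the grid is truncated, flagged, and the case excluded from
  that horizon's comparison (and counted). Including partial integrals
  would mix horizons.
- **"Onset temperature" bins.** The bin is taken from the baseline at
  first administration (the two notions coincide in this design's framing;
  both quantities are computed).
- **Statistics from summaries.** `student_t`, `cohens_d` and
  `mixture_total` operate on (mean, SD, n) summaries so that published
  summary tables can be fed through the exact estimators used on raw data;
  the equal-weight Cohen *d* variant is the default because it is the one
  that reproduces published pediatric-cohort effect sizes exactly at two
  decimals.
- **No multiplicity correction** is applied; p < .05 is reported as-is, as
  is standard for this design.

## The synthetic cohort generator

Real PGHD of this kind is proprietary, so the generator emulates its
structure with known ground truth. Per child:

- **Demographics.** Sex ~ Bernoulli(0.5044); age ~ lognormal
  (μ = 6.55881, σ = 0.58145; mean ≈ 835, SD ≈ 530 days) truncated to
  [0, 7000]; weight from a monotone weight-for-age curve plus N(0, 1 kg)
  noise.
- **Latent fever course.** Baseline ~ N(36.8, 0.2) ℃ plus a logistic rise
  (time scale 0.8 h) to a gamma-distributed peak increment
  (shape 4, scale 0.58; mean ≈ 2.3 ℃) that decays exponentially
  (τ = 12 h). One illness bout per child over a 96 h window; no circadian
  rhythm (config extension point).
- **Drug response.** Additive, piecewise-linear kernel per dose: zero for
  a 1 h lag, linear descent to a nadir of 0.9/1.1/1.0 ℃ (ACE/IBU/DEX) at
  2 h, linear recovery to zero at 6 h. The lag and nadir sit on whole
  hours so a dose-anchored hourly grid represents the kernel exactly, and
  the kernel integral has a closed form used by the tests.
- **Dosing policy.** Each caregiver has a personal threshold from
  N(38.3, 0.3) truncated to ≥ 38 ℃ and doses when the latent temperature
  crosses it, after an exponential reaction delay (mean 1.2 h, capped at
  3 h) — so doses land near local temperature peaks, as they do in real
  fever management. Among children who would dose at all, 5.5% are
  relabelled as under-38 "early dosers" (threshold ~ U(37, 38) ℃, short
  delay); conditioning on being a doser is what makes the realized
  under-38 share of first doses match the configured fraction instead of
  being inflated by selection. At the first dose the caregiver becomes a
  combination user with a probability that rises with the onset band
  (13% → 18.93% → 23.81% → 34.48% → 41.40%); combination caregivers draw a
  pattern (ACE-DEX 51.17%, ACE-IBU 40.62%, IBU-DEX 6.01%, triple 2.20%)
  and alternate ingredients at U(4, 6) h intervals, with the second
  (committed) alternating dose scheduled rather than threshold-gated;
  single caregivers redose the same ingredient (ACE 40.08%, DEX 36.74%,
  IBU 23.18%) after ≥ 4 h.
- **Measurements.** An inhomogeneous sampling process with rate
  0.10 + 0.8·max(0, T − 37.5) per hour (capped at 3/h), plus one reading
  at every dose and jittered post-dose response checks at +1…+6 h (each
  kept with probability 0.85). Observed values are latent + N(0, 0.15 ℃),
  rounded to 0.1 ℃, at minute resolution. The post-dose checks mirror app
  behaviour (caregivers re-measure to see whether the fever broke) and are
  what keeps linear imputation approximately unbiased through the
  post-dose trough; without them, temperature-dependent sampling alone
  systematically under-samples the trough and biases AUC toward zero.
- **Ground truth.** A sidecar frame with, per dosing-anchored case, the
  true group, the true (noise-free) baseline, and the exact latent
  delta-fever AUC at each horizon computed by 1-minute quadrature of the
  latent course (exact to ~10⁻⁴ ℃·h for this piecewise-smooth model). The
  recovery contract compares the pipeline's per-group mean AUC against the
  ground-truth mean of the same cases.

A dedicated **exchangeable null configuration** (`null_config`) gives all
ingredients identical kernels, applies one shared dosing policy to
everyone, and assigns the combination label with a band-independent 50%
probability — group labels become pure relabelings, so the two-group
*t* test's rejection rate must sit at the nominal α = 0.05.

### What the generator does *not* emulate

Multi-day relapsing fevers (one smooth bout per child, so simulated
episode durations are shorter than real ones), pharmacokinetic dose-size
effects (the kernel is phenomenological and dose-amount-free), circadian
rhythm, measurement-site differences, and any adverse-event structure.
Passing tests therefore demonstrate that the pipeline recovers what the
data contain under local linearity — not that real fever courses are
linear between readings.

## Numerical choices

- Internal clocks are float hours since a fixed epoch (float64 keeps
  sub-second precision across the study span); emitted timestamps are
  minute-resolution ISO-8601.
- Duplicate (child, time) temperature rows keep the last entry, counted.
- Hourly grids anchored at the window start make horizon additivity
  AUC(0→12) = AUC(0→6) + AUC(6→12) exact; tests assert it to 1e−9.
- The hourly-grid discretization error against the exact integral of the
  interpolant is bounded by the total slope change at interior knots times
  h²/8; the integration oracle asserts that bound per case.
- Zero pooled variance in the t test returns t = 0 (equal means) or a
  signed infinity (unequal); chi-square refuses zero marginals;
  `mixture_total` with an empty component returns the other component.
- Report rounding is 2 dp for means/SDs/percentages/effect sizes;
  machine-readable outputs keep unrounded values, and the mixture
  identities are asserted on the unrounded values to 1e−9.

## Problem sizes used by the test suite

The statistical acceptance checks run at sizes chosen to make their
tolerances informative: null calibration uses 500 replicates of 80
children under the exchangeable configuration (rejection rate within
±2 SE of 0.05); parameter recovery uses 10,000 children (≥ 5,000 cases;
per-group mean 6-h AUC within 3 SE of ground truth). Per-bin combination
shares are asserted within ±2 percentage points only for bins holding at
least 500 eligible cases — below that, binomial sampling error alone
exceeds the tolerance, so the check would be uninformative; the monotone
rise of the share across febrile bins is asserted alongside.

## Known limitations

- Linear imputation is the design's stated assumption, not a validated
  model of fever physiology; long gaps make it biologically implausible,
  hence the optional max-imputation-gap guard.
- The Cohen *d* pooling variant matters at the third decimal; both
  variants are provided.
- Unresolved episodes (series ends febrile) contribute no duration; if
  caregivers systematically stop logging after defervescence, resolved
  durations underestimate true fever duration.
- The pipeline reports its own counts; it does not attempt to reconcile
  internally inconsistent counts in external sources.
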