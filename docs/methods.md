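# Methods

This note records the models, the tunable parameters, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Minute-level cleaning

Three triggers mark a minute missing: the −0.01 sentinel in the MIMS
value, a non-wear wear-prediction, and a quality-flag count above zero.
Wear predictions of "unknown" are treated as wear; only "non-wear" is a
missing trigger.  This is one of two readings of the wear codes and is the
sensitivity axis we would probe first on real data.

Thresholds (all configurable, defaults are the analysis convention):

| parameter | default | meaning |
|---|---|---|
| `min_interval` | 60 min | shortest missing run that is imputed; shorter runs contribute 0 |
| `wear_min` | 960 min | a day is valid iff non-missing wear minutes **strictly exceed** this ("more than 16 h" read literally; 960 itself is invalid, 961 valid) |
| `min_valid_days` | 4 | subjects below this are dropped before scoring |

The interaction between "missing is zero" and "missing is imputed" is
resolved by run length: runs ≥ 60 min are imputed, runs < 60 min are
zeroed.  Imputation never touches non-missing minutes and is idempotent on
clean data.

Two imputation methods are provided.  `minute_profile` (default,
deterministic) fills a missing minute with the subject's mean non-missing
value at the same minute-of-day across their valid days, falling back to
the subject's overall mean when no same-minute donor exists (logged).
`zip_model` draws from a per-subject zero-inflated log-normal fitted in
30-minute bins of the day (seeded).  The original zero-inflated-Poisson
imputation software for accelerometer data is not reproduced here; the
deterministic profile keeps the default pipeline reproducible bit-for-bit
and the regression tests show its downstream bias on duration is on the
order of a minute at default missingness rates.

## Sleep/wake HMM

One two-state HMM per subject on the concatenated series (about
T = 10 080 minutes for a week), on y = log(1 + MIMS), with Gaussian
emissions per state.  The emission family and decoding rule are this
package's own specification: the upstream literature applies an HMM to
summary counts but leaves these internals to its accompanying code, so
equivalence with any particular implementation is not claimed.

* Baum–Welch EM with scaled (normalized) forward–backward recursions;
  stable at week length with no underflow (emission densities floored at
  1e−300, emission SDs at 0.01 — the floor prevents variance collapse on
  long runs of identical imputed zeros).
* Initialization: `quantile_split` (state means at the 25th/75th
  percentiles — deterministic default) or seeded 1-d k-means.
* Convergence: relative log-likelihood increase < 1e−6 (default) or 200
  iterations; the log-likelihood path is asserted non-decreasing each
  iteration (tolerance 1e−6·|ll| for the SD floor).
* The lower-mean state is sleep, which resolves EM's label ambiguity
  deterministically.
* Decoding: posterior (local) decoding by default — sleep iff smoothed
  P(sleep) > 0.5, ties to wake; Viterbi available.  Posterior decoding is
  the natural match for minute-wise sleep-fraction scoring.
* Constant series are flagged degenerate and the subject is skipped rather
  than force-fitted.

Correctness is anchored by a brute-force oracle (exact enumeration of all
2^T paths, T ≤ 16) and by an independent HMM library's likelihood under
fixed parameters; agreement is at 1e−10 or better.

## SPT window and sleep parameters

Nights are noon-to-noon windows, half-open, anchored on the day whose noon
starts them.  The SPT window is the longest block of sleep after merging
sleep runs separated by wake gaps shorter than `merge_gap_max` (default
60 min, the same scale as the missing-interval rule; the published
description says the SPT window contains wake bouts but not how runs are
merged, so the merge tolerance is an explicit, configurable choice).
Ties go to the earliest block; the block starts and ends in sleep, so no
wake bout touches the SPT boundary and each internal bout is shorter than
the merge gap by construction.

Derived exactly as defined: CTSO = 12 + start/60 on the continuous 12–36 h
clock (1 am → 25 h); duration = SPT − Σ bouts; efficiency =
duration / SPT.  Identities `duration = SPT − bouts` and
`efficiency·SPT = duration` hold to 1e−12 on every scored night by
construction and are regression-tested.  SPT < 3 h or > 15 h marks a night
invalid; subjects need ≥ 3 valid nights.  Partial first/last windows are
scored only if the SPT does not touch the recorded edge — a truncated
sleep period must not masquerade as a short night.  A night with no sleep
minutes is invalid, not a zero-duration observation.

Weekend nights are those anchored on Friday or Saturday noon (day-of-week
coded 1 = Sunday), i.e. the sleep episode precedes a work/school-free
morning.

## Survey estimation

* 4-year weights: 2-year exam weight / 2 when two cycles are present; a
  single-cycle table passes weights through unhalved behind an explicit
  flag.
* Means are Horvitz–Thompson ratio estimates; variances are Taylor
  linearized under the stratified with-replacement-PSU approximation
  (between-PSU variation of influence totals within strata).  A stratum
  reduced to one PSU contributes its deviation from the grand PSU mean
  (the common survey-software default), with a warning.
* Weighted quantiles use inverse-CDF inversion (smallest observed value
  whose cumulative weight share reaches p); the rule is frozen and
  oracle-tested against direct CDF inversion.
* Trend regression: weighted least squares of each parameter on intercept,
  four age powers, female, and three race dummies (reference male,
  NH White), optionally with sex×age and race×age interaction blocks.
  Age is centred and scaled as (age − 40)/20 before powers are taken —
  age⁴ on raw years conditions the normal equations terribly — with fixed
  constants so coefficients are comparable across fits.  Covariance is the
  design-based sandwich (bread = (XᵀWX)⁻¹, meat = stratified between-PSU
  covariance of w·x·e).
* Wald tests use the adjusted F, F = (d − q + 1)/(d·q) · W on
  F(q, d − q + 1) with d = n_PSU − n_strata, matching the major survey
  packages; significance at 0.05.
* Efficiency, being left-skewed, also gets a proportional-odds model on
  its weighted quartiles: pseudo-maximum-likelihood with
  weight-multiplied per-observation log-likelihoods, sandwich covariance
  from the weighted scores.  Positive coefficients shift mass toward
  higher efficiency quartiles, so signs are directly comparable with the
  linear model.

## Synthetic cohort

The generator emits what the pipeline assumes the world looks like: one
main sleep period per noon-to-noon night, with

* quartic age curves for onset and duration (package defaults fitted
  through landmark ages: onset latest near age 20, duration shortest near
  ages 40–50, duration within (3, 15) h across ages 6–85 — the generator
  refuses configurations whose curve would systematically trip the SPT
  filter);
* group shifts: female onset +5 min and duration +4 min; vs NH White,
  NH Black onset +10 min and duration −15 min, Mexican American onset
  −11 min, Other onset +10 min and duration −8 min, and an efficiency
  penalty ordering White > Other > Mexican American > Black realized
  through the wake-bout rate;
* night-level Normal jitter (onset SD 0.5 h, duration SD 0.4 h) plus
  subject-level random effects (0.75 h / 0.5 h) for realistic
  between-person variance;
* weekend nights delayed 45 min at onset and 75 min at wake;
* Poisson(2) wake bouts per night, mean length 8 min, each capped at
  45 min — below the SPT merge gap, so the true sleep period forms a
  single merged block and true efficiency averages ≈ 0.96;
* log-normal activity per state on the log(1+MIMS) scale (sleep
  N(0.3, 0.3), wake N(2.5, 0.8), truncated at 0 — the truncation gives a
  realistic point mass of zero-activity minutes);
* injected non-wear blocks (per-day probability 0.15, 120 min, placed in
  wake), per-minute quality flags (10⁻³) and −0.01 sentinels (5·10⁻⁴);
* a stratified two-PSU-per-stratum design (8 strata by default) with
  weights inversely related to an age-band sampling rate.

What the generator does **not** emulate: naps and split sleep, circadian
process dynamics, covariate-dependent HMM transitions, device-specific
emission quirks, within-week schedule autocorrelation, non-response
structure in the weights, and NHANES's top-coding of age at 80 (ages are
uniform on 6–85).  Passing recovery tests therefore demonstrates the
pipeline is correct under its own model assumptions — near-perfect
decoding at the default emission separation, onset/duration MAE ≈ 1 min —
not that real wrist actigraphy is this clean.  On real data the binding
uncertainties are the HMM emission family and the SPT merge tolerance, not
the estimator stack.

## Validation simulations and problem sizes

The estimator-calibration checks run at the subject level, where the
quantities being tested live: 200 replicates of a known
quartic-age + sex-shift generator for 2-SE coefficient coverage, and 500
replicates of a no-interaction generator for the type-I error of the
interaction Wald test.  Both use n = 1000 subjects over 50 strata × 2
PSUs: enough design degrees of freedom that the nominal-level check
measures the linearized variance itself rather than the small-df error of
the F approximation (at 15 strata the same test rejects at ~9% purely
from variance-estimation noise — a property of the approximation, shared
with standard survey software, not of this implementation).

The end-to-end recovery check runs the full pipeline once on a
300-subject, 7-day default-configuration cohort (≈ 3 million subject
minutes, about half a minute on one CPU).  Full-pipeline Monte-Carlo over
hundreds of replicates is intentionally left to the subject-level
simulations.

## Known limitations

* The HMM internals (Gaussian-on-log emissions, posterior decoding) are a
  reasonable specification, not a reproduction of any published code; on
  real NHANES data results will differ in detail from the published
  national estimates.
* Replicate-weight variance methods are out of scope; weights are treated
  as fixed (no imputation-aware variance).
* Single main sleep period per night by design: nap detection and
  sleep-onset latency are not estimable from this pipeline.
* Reading SAS transport (.XPT) files directly is not supported; convert
  to CSV/parquet first.
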