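# Methods

## The interchangeability model

The unit of analysis is the *triad*: one patient's test measurement `t`
(typically an AI-automated LVEF) and two human reference measurements
`r1`, `r2` of the same echocardiographic parameter. With

    Q_RR = mean_i (r1_i − r2_i)²
    Q_TR = mean_i [(t_i − r1_i)² + (t_i − r2_i)²] / 2

the individual equivalence coefficient is

    IEC = (Q_TR − Q_RR) / (Q_RR / 2).

`Q_TR` averages the two squared test–reference differences *within* each
patient first and across patients second; this makes the patient the exchangeable
unit, which in turn makes patient-level resampling the natural bootstrap. The
statistic is symmetric in the two references, invariant to rescaling all
measurements by a common factor, and bounded below by −2 (attained only as
`Q_TR → 0`; a test equal to one reference gives exactly −1, a test at the
reference midpoint −1.5). Interchangeability is declared when the upper bound
of the IEC's 95% CI is strictly below 0.25.

Only complete triads enter the analysis: a patient missing any of the three
values is excluded, and the triad count is always reported next to the
estimate. No imputation is performed.

### Confidence intervals

The CI is a nonparametric patient-level bootstrap (default 2,000 resamples,
seeded and fully reproducible). The percentile interval is the default: the
IEC is a smooth ratio of means, for which percentile intervals are close to
nominal at moderate n, and the construction is transparent. A
bias-corrected-and-accelerated (BCa) interval, with jackknife acceleration,
is available via `method="bca"`. Resamples in which the two references agree
exactly for every patient (`Q_RR = 0`) leave the IEC undefined; they are
skipped and counted, a warning flag is set when they exceed 10% of resamples,
and an all-degenerate bootstrap is an error rather than a number. The
acceptance suite checks calibration directly: over 1,000 simulated datasets
of 200 triads at a known population IEC, the 95% percentile interval covers
the truth 93–97% of the time.

### Degenerate inputs

Fewer than two triads, or references identical across all patients, raise
typed errors (`InsufficientDataError`, `DegenerateDataError`) rather than
returning infinities. Quality strata with fewer than two triads are reported
as `NotEstimable` objects, never silently dropped.

## Diagnostic accuracy

Classification at an LVEF cutoff uses `value ≤ cutoff` for the primary 40%
rule and strict `<` for a 50%-type rule; the convention is explicit in every
call. The reference method's classification defines truth. Proportion CIs use
the Wilson score interval by default — chosen for its behaviour at boundary
counts (it never escapes [0, 1] and needs no continuity fudge) — with
Clopper–Pearson exact intervals behind `ci_method="beta"`. The AUC is the
Mann–Whitney statistic with midrank tie handling, computed from the
continuous test measurement against the binary reference label with risk
score −LVEF (lower ejection fraction ⇒ higher risk); its CI is Hanley–McNeil
by default and DeLong behind a flag. The test suite verifies the AUC exactly
against exhaustive pairwise enumeration and against scikit-learn's
implementation.

`metric_consistent_counts` exhaustively enumerates all integer 2×2 tables of
a given total whose requested metrics round (half-up, at the stated decimal
precision) to a published metric set. It exists because published reports
often print rounded metrics without the underlying confusion matrix; the
solutions are consistency candidates, never asserted to be the true counts.
Printed CIs can be used as further filters — exact binomial intervals turn
out to discriminate far better than point metrics alone.

Half-up decimal rounding (`round_half_up`) is used wherever values are
compared against printed presentation, because banker's rounding disagrees
with how clinical journals print (e.g. 76.5% → 77%).

The margin-of-error sample size is `n = z² p(1−p)/m²`, rounded half-up; with
prevalence 0.10, margin 0.02 and 95% confidence it gives 864.

## Agreement

Bland–Altman differences are always **test − reference** (AI − human) — the
direction is fixed and stated in output headers rather than inferred. Limits
of agreement use the conventional 1.96 multiplier on the SD (n−1) of the
differences; the mean difference gets a t-based CI. A proportional-bias slope
(difference regressed on pair mean) is computed as an advisory diagnostic
only. Pearson's r uses the product-moment formula with a two-sided p from the
t transform on n−2 df.

## The synthetic cohort generator

The generator emulates the statistical structure of a prospective
suspected-heart-failure cohort measured by six methods (handheld and
cart-based scans; AI, usual-care clinical and core-laboratory analysts; two
core-lab reads of handheld scans, one of cart scans):

- **Truth.** True LVEF is a two-component mixture: with probability 0.10
  (the reduced-EF prevalence) a truncated normal N(32, 6²) on [10, 40] %,
  otherwise N(60, 7²) on (40, 85] %. These defaults reproduce a realistic
  preserved-EF median near 60% with quartiles in the mid-50s to mid-60s and
  a ~10% reduced-EF fraction.
- **Measurement.** Each method observes
  `truth + bias + N(0, noise_sd × quality multiplier)`, clipped to the
  parameter's plausibility window. Default biases are +5.2 (handheld AI),
  +4.2 (cart AI) and +6.5 (usual-care clinical) percentage points relative to
  the core laboratory, matching observed mean differences between such
  methods; the second handheld core-lab reader carries the same +6.5-point
  offset, reflecting that systematic differences of this size occur *between
  human readers*, not only between AI and humans. Default noise SDs are 6
  (AI) and 5 (human) points. Under the closed form below these defaults put
  the population IEC of every AI-vs-two-humans arm near −0.4: the AI sits
  between two humans who disagree with each other.
- **Reporting.** Each method reports with probability
  `report_prob × quality penalty`, independently across methods given
  quality. Base probabilities are calibrated so the *marginal* reporting
  rates under the default quality mix equal 61/83/69% (handheld AI and the
  two core-lab readers) and 77/72/81% (cart AI, clinical, core lab).
- **Image quality.** One five-level grade (excellent … technically difficult)
  per (patient, device), with default mix (0.10, 0.30, 0.30, 0.20, 0.10),
  noise multipliers (1, 1, 1.25, 1.5, 2) and reporting penalties
  (1, 1, 0.9, 0.75, 0.5) — the worst grade doubles noise and halves
  reporting.
- **Randomness.** Every draw type (labels, truth, per-device quality,
  per-method noise and reporting) has its own named substream derived from
  the seed, so adding a method never perturbs the other draws, and an
  identical spec yields a byte-identical cohort.

Because errors are additive and independent, the population IEC of any arm
has the closed form

    Q_RR = (b_R1 − b_R2)² + σ_R1² + σ_R2²
    Q_TR = σ_T² + (σ_R1² + σ_R2²)/2 + [(b_T − b_R1)² + (b_T − b_R2)²]/2

which `closed_form_iec` implements; it is the oracle against which the
estimator is validated on simulated triads across a grid of test-method noise
levels (Monte-Carlo tolerance 0.08 + 0.05·|IEC| at 20,000 triads, from the
observed sampling error of the estimator).

### What the generator does *not* emulate

Missingness is independent across methods given quality; in real cohorts
unreadable scans are missing for *every* analyst at once, so real complete-triad
counts run higher than the product of marginal rates. Reader errors are
independent given truth: there is no shared-image error term, so
between-human correlation is driven entirely by shared truth. Values are
clipped to plausibility windows, which at the default noise levels affects
well under 1% of draws. Passing tests on generated cohorts therefore
demonstrate estimator correctness under the additive model, not the field
behaviour of any particular AI product.

## Orchestration

`run_study` executes reporting rates, the primary endpoint (AI-handheld vs.
clinical cart at ≤ 40%), three IEC arms (AI-handheld vs. two cart humans;
AI-cart vs. two cart humans; AI-handheld vs. two handheld core-lab reads),
agreement summaries, and quality-stratified IEC, writing one CSV/JSON pair
per section plus a `run_log.json` with seed, version and stage failures. Arms
are configuration, not code. Each stage and each arm is isolated: a failure
(e.g. a method absent from the data, or a zero-noise cohort making `Q_RR = 0`
and the IEC undefined) is recorded and everything else continues; the CLI
returns a non-zero exit status when any stage failed. Outputs contain no
timestamps, so a re-run with the same seed is byte-identical. Quality
stratification uses the test device's quality grade by default, with a
`quality_device` switch.

## Problem sizes used in the test and acceptance suites

Generator recovery checks run at 20,000 patients; triad-fraction and
agreement recovery at 5,000–10,000; the closed-form grid at 20,000 triads per
noise level; bootstrap calibration at 1,000 replicates of 200 triads with
2,000 resamples each (vectorised, a few seconds in total); the full simulated
study at the default 867 patients. All statistical assertions use 3-standard-
error bands around the configured values, except the coverage band (93–97%)
and the Monte-Carlo tolerance stated above.

## Known limitations

- One test against exactly two references; no multi-test generalisations or
  variance-components decompositions.
- The bootstrap treats triads as i.i.d.; clustering (e.g. by site) is not
  modelled.
- Only one parameter is simulated per cohort (LVEF by default); other
  parameters reuse the same additive model with user-supplied settings.
- Proportional bias is flagged but not modelled; no regression-based limits
  of agreement.
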