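# Methods

## The estimation problem

A wrist-worn logger produces a bradykinesia score (BKS; higher = slower
movement) and a tremor amplitude for every 2-minute epoch over a ~6-day
recording, together with medication-reminder and acknowledgement times.  The
goal is to reproduce, from that stream alone, the outcome of a levodopa
challenge test: whether the subject's motor improvement after a levodopa dose
is clinically meaningful.  The pipeline assumes that motor function at the
first morning dose approximates the practically defined OFF state and that
the post-dose trough of bradykinesia approximates the ON state.

## Epoch usability

Epochs are labeled on a three-way partition:

* **off-wrist** — flagged by the device; unavailable, never enters any
  window or statistic (windows shrink around them rather than impute);
* **inactive** — linearly weighted moving median of BKS over a 15-epoch
  (30-min) centered window strictly above 40; attributed to sleep or
  inactivity and excluded;
* **active** — everything else.

The device glossary's alternative "active ⇔ weighted moving median ≤ 0"
formulation would exclude nearly all data and is treated as an erratum; the
`> 40` inactivity rule governs, with *active = not inactive, on wrist*.

## Features

For each epoch, 30-min (15-epoch) moving percentiles of BKS at q ∈
{10, 25, 50, 75, 90}, both unweighted and with a triangular kernel (maximal
at the window center, declining linearly to zero one step past each edge);
the moving and weighted-moving tremor medians; and
`TA_WM50P_Log = log10(1 + TA_WM50P)`, which brings tremor onto the same
logarithmic scaling as BKS (the +1 keeps the transform finite and
non-negative for tremor-free epochs, which are scored 0).

Percentile convention: the *nearest-rank* (inverted CDF) percentile for the
unweighted statistic, and for the weighted one the smallest value whose
normalized cumulative weight (values ascending) reaches q/100.  These two
conventions were chosen jointly so that uniform weights reproduce the
unweighted statistic *exactly* — a property the test suite exploits.
Cumulative-weight comparisons carry a 1e-9 relative tolerance so that exact
rational thresholds (e.g. q = 10 over 10 equal weights) land on the
mathematically intended rank despite binary floating point.

Feature relevance is scored by mutual information between each continuous
feature and the 6 severity classes, with the mixed continuous/discrete
k-nearest-neighbor estimator (k = 6, Chebyshev distances, neighbor radii
taken within the sample's own class), reported in nats and clipped at 0.
Joint MI of feature pairs uses the same estimator over the 2-D max-norm, so
marginal and joint values are directly comparable.  Percentile features are
heavily tied, which breaks neighbor ranks; a seeded jitter of 1e-10 of each
dimension's range is added before estimation.  JMIM then ranks the refined
candidate set greedily: first the feature with maximal marginal MI, then
repeatedly the candidate maximizing the minimum joint MI with any selected
feature (ties break by input order).  The selected trio used downstream is
`BKS_M10P`, `BKS_M25P`, `TA_WM50P_Log`.

## Severity model

UPDRS III totals are placed on a common scale by adding 7 points to
older-scale totals (MDS-scale totals pass through).  The 6 motor function
severity levels (MFSL) are: level 0 below 10 points, levels 1–4 in
12.5-point steps, level 5 at ≥ 60; boundary scores are assigned upward.  The
6-class problem is decomposed into 5 binary threshold classifiers at
(10, 22.5, 35, 47.5, 60); an epoch's MFSL estimate is the plain sum of the
five 0/1 votes (no monotonicity repair — non-monotone vote patterns simply
sum).  Hard 0.5-probability votes, not probabilities, enter the sum.

Training samples are the usable DT epochs (labeled with the subject's
adjusted UPDRS_OFF), the usable ET epochs (UPDRS_ON) and control epochs at a
nominal 07:00 dose time (UPDRS III defined as 0).  The default classifier
family is L2-regularized logistic regression on standardized features, with
the regularization strength tuned by grouped 10-fold cross-validation;
alternatives (first-PC PCA of the two collinear BKS percentiles + logistic,
RBF-kernel SVC, gradient boosting) are available behind the same interface.
Train/test splits are *subject-grouped*: for each classifier, subjects are
stratified by their (has-positive, has-negative) sample pattern and 30% of
each stratum goes to test, giving ≈30% of each binary class's samples in
test with no subject on both sides.  The CV fold count is clamped to the
number of subjects carrying the minority class so that every fold is
two-class.

## Dose windows and the weekly series

DT is the 5 grid epochs centered on the epoch containing the day's first
acknowledgement.  The weekly BKS series is the across-day median of usable
BKS at each 2-min offset from the acknowledgement, smoothed with a 5-point
centered moving average (the smoothing operator is a package choice; the
across-day median makes the series robust to one aberrant day).  ET is the
offset of the series *minimum* within the closed [46, 90] min window —
"peak effect" means least bradykinesia — with ties broken toward the
earliest offset; the same offset anchors every day's 5-epoch ET window.
Pooled over days, up to 30 epochs per window kind feed the weekly aggregate
mean and sample SD (n−1).  For response estimation, controls use a nominal
10:00 dose time (07:00 is used only when building the model, matching
early-morning sleep structure); the 46 min lower bound is kept as the single
default where the alternative 45 appears in a control-processing context.

## Response and exclusion flags

`MFSL_DT` and `MFSL_ET` are means of per-epoch MFSL predictions over the
pooled usable window epochs; `absΔ_PKG = MFSL_DT − MFSL_ET`,
`%Δ_PKG = absΔ_PKG / MFSL_DT × 100` (undefined when `MFSL_DT = 0`; such
subjects are excluded from %Δ analyses rather than given an infinity).

* **Uncertain**: `11 ≤ absΔ_UPDRS ≤ 14` — a 4-point band centered on one
  MFSL increment between clearly insignificant (≤ 10) and clearly
  meaningful (> 14) improvements.
* **Already ON**: `MFSL_DT < 3` (treated range) *and* the daytime severity
  estimate — mean + 1 SD of per-epoch MFSL from 46 min post-dose to 18:00,
  pooled over days — exceeds `MFSL_DT + 1`.
* **Variable amplitude**: SD of per-epoch MFSL > 1 in *both* the pooled DT
  and pooled ET windows.
* **Variable latency**: SD of per-day trough latencies (argmin of each
  day's own smoothed dose-aligned BKS in [46, 90] min) above 11 min, a
  quarter of the search window.  The published description of the latency
  criterion is ambiguous (it repeats the amplitude wording); this
  operationalization is the package's choice and is configurable.  Latency
  is a dose-response property, so the flag is undefined for controls.

Evaluation computes ROC AUC (trapezoid = pairwise concordance with ties at
½) and class-averaged PR AUC (mean of the two one-vs-rest average
precisions, class 0 on negated scores) of the sensor response against the
binary meaningful-improvement label, with controls augmenting class 0.
Scenario columns apply the exclusions cumulatively; uncertain subjects are
retained (counted with class 1, since their improvement exceeds the
insignificance bound) in the non-excluding scenarios.

## Synthetic cohort generator

The generator emulates the salient structure of multi-day wrist recordings;
its defaults are the published cohort conditions wherever those are stated:

| parameter | default | origin |
|---|---|---|
| cohort | 151 PwP / 174 controls, 6 days, 2-min epochs | study cohort sizes |
| UPDRS_OFF | N(48, 13), clipped [20, 80] | cohort mean ± SD |
| improvement absΔ | N(22, 11), clipped ≥ 4 | cohort mean ± SD |
| first dose | N(164, 79) mg, clipped [50, 400] | cohort mean ± SD |
| already-ON fraction | 0.19 (among subjects with ON < 35) | flagged share |
| latency to peak | N(45, 19) truncated to [46, 90] min | reported 45 ± 19 |
| scale mix | 2/3 older UPDRS (raw = adjusted − 7) | two of three clinics |

Free parameters the source never states are package choices: an affine
UPDRS→BKS link (slope 0.4, intercept 4 — keeping the severest subjects
below the BKS-40 inactivity band), epoch noise SD 4 BKS, per-subject offset
SD 1.5, day-to-day baseline SD 2 BKS, daytime inactivity occupancy 0.15 and
off-wrist occupancy 0.05 as two-state Markov bouts (geometric lengths, mean
10 and 15 epochs — bouts, not i.i.d. epochs, because the inactivity
detector is a moving median), sleep from 23:00 to a per-day wake time
~N(06:30, 20 min) with sleep-range BKS N(55, 5), a Gaussian-bump dose
response (width 22 min) whose amplitude is anchored to the gap between the
severity at acknowledgement and the ON level, day amplitude ~N(1, 0.25),
and tremor bursts in 60% of PwP with severity-scaled lognormal amplitude.
A 15% high-variability subgroup triples the day-to-day latency SD,
amplitude CV and baseline SD.  "Already ON" subjects draw their morning
severity from the ON level, ramping to the OFF level between 11:00 and
13:00, so their dose-locked dip vanishes while their daytime severity
rises — exactly the pattern the flag tests for.

Because latencies are truncated to the effect-time search support, the
generator's calibration is checked against the truncated-normal moments of
the configured (45, 19) parameters, not the raw values.

What the generator does **not** emulate — and hence what passing tests do
not show about clinical data: raw accelerometry and the device's scoring
algorithm, dyskinesia, pharmacokinetic dose stacking across the day,
circadian severity drift, rater noise in UPDRS III beyond an additive
day-to-day term, medication schedules beyond one first daily dose, and any
real covariance between tremor, bradykinesia and severity.  Absolute AUC
values on synthetic cohorts are therefore not comparable to clinical
performance; only the qualitative recoveries (monotone severity link, flag
sensitivity/specificity, AUC gains under exclusions) transfer.

## Numerical and engineering choices

* All timestamps are integer minutes on a 2-min grid aligned to midnight;
  an epoch covers [t, t+2); calendar days are multiples of 1440 min.
* Window ties: ET argmin takes the earliest offset; JMIM ties take input
  order; grouped-split strata are shuffled with seeds derived per
  classifier.
* One global seed fans out to stage seeds via
  `SeedSequence(seed).generate_state(n) % 2^31`; identical configurations
  reproduce byte-identical CSV outputs (checked in the suite).
* Degenerate inputs: empty DT/ET pools yield a reason-coded result, not an
  exception; single-epoch SDs are undefined (flags unavailable); MI
  estimation refuses classes with fewer than k+1 samples (the pipeline
  stage sets such classes aside with a warning).
* CSVs are read back with round-trip float parsing so write→read is exact.

## Known limitations

* The latency-variability criterion is this package's reading of an
  ambiguous description; rates on synthetic data (~half of PwP flagged, vs
  roughly a third reported clinically) depend on the 11-min threshold and
  the per-day trough detectability.
* The amplitude-variability flag requires both windows to be noisy and
  rarely fires under the generator's day-to-day model.
* Boundary UPDRS scores are binned upward by convention; the source did not
  state its tie direction.
* Control %Δ is undefined (MFSL_DT = 0 almost surely), so %Δ scenario
  tables carry few class-0 controls; this is inherent to the definition.
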