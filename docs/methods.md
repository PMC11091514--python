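# Methods

`ortime` implements, end to end, the evaluation framework for real-time
intraoperative duration prediction: a synthetic operating-room feed, a
latency-respecting minute-by-minute replay, a probabilistic duration model
with a bias-corrected scheduled-duration benchmark, CRPS scoring with
stratified aggregation, and performance-drift monitoring with a retraining
comparison. This note records the model assumptions, the knobs that matter,
and the design choices made where the design was genuinely open.

## The prediction problem

During an anaesthetic, the quantity of interest is the *total anaesthesia
time* — the interval from anaesthesia start to anaesthesia stop. At every
elapsed minute `t` of an ongoing case, the predictor emits a probability
distribution over the total duration, using only information that has been
*ingested* by the pipeline by minute `t` (charting-to-ingestion latency
means the feed runs a few minutes behind the record). Forecasts are scored
with the continuous ranked probability score,

    CRPS(F, y) = ∫ (F(x) − 1{x ≥ y})² dx ,

in minutes; for a deterministic forecast it reduces to absolute error. The
benchmark is the *bias-corrected scheduled duration*: ordinary least
squares of actual on scheduled duration fitted on the training window,
applied to each case's scheduled duration and scored as a constant point
forecast over the whole case.

## The synthetic operating-room generator

No public data exists for this problem, so the generator is a first-class,
tested component; it defines the study conditions under which every claim
in the test suite is evaluated.

**Case population.** Cases arrive on a weekday-weighted calendar (weekend
volume 18% of weekday volume) across four hospitals with volume shares
58/15/20/6% and ten surgical services. Service durations are log-normal
(right-skewed, strictly positive); the mixture's medians (35–250 min,
dispersions 0.45–0.62) were set so the population median lands near 80 min
and the mean near 110 min, the shape typical of mixed surgical case mixes.
Durations are floored at 20 min so the end-of-case signature window always
fits inside the case.

**Schedule link.** A base duration is drawn from the service's log-normal;
the scheduled duration is the rounded inverse of a linear link
(`slope=0.99`, `intercept=−4.4` by default), and the realised duration is
the link applied forward plus Gaussian noise, `actual = slope·scheduled +
intercept + ε`. The noise standard deviation defaults to 30 min scaled by
`(scheduled/100)^0.5`, so longer cases are noisier — this is what makes the
benchmark's error grow with scheduled duration and makes the per-prediction
mean CRPS exceed the equal-weight per-case mean (long cases contribute more
minutes *and* larger errors). Because the noise enters in the regression
direction, OLS of actual on scheduled recovers the link without
attenuation; this recoverability is deliberate and is verified by a
parameter-recovery test. Note the interaction between the 20-min floor and
the noise: for case mixes with many short cases the floor truncates the
noise distribution and biases OLS slightly, so exact-recovery checks use a
long-case mix for which the linear model is the true, untruncated process.

**Intraoperative streams.** Six flowsheet channels are charted at whole
elapsed minutes: heart rate (bounded random walk, complete coverage),
inspired oxygen fraction (high at induction and emergence), bispectral
index (monitored in ~70% of cases, absent pre-induction, rising at
emergence), one expired volatile agent per case (sevoflurane 70% /
desflurane 25% / none 5%) with an onset ramp and an exponential washout
over the final 8 min, and nitrous oxide in 20% of cases. Events include
induction and intubation in the first minutes and sporadic intraoperative
events; medications include induction agents and intraoperative boluses.
The *end-of-case signatures* — a neuromuscular reversal agent, an
antiemetic, and an emergence event — are charted a uniform 5–15 min before
anaesthesia stop in every case. These signatures are the learnable signal:
conditioned on a reversal token, the remaining duration is nearly pinned
down (sd ≈ 2.9 min versus a marginal sd an order of magnitude larger),
which is exactly why a streaming model can beat any preoperative forecast
near the end of a case.

**Latency and operating window.** Ingestion time is charting time plus a
truncated-at-zero Gaussian delay per stream type; the defaults (3.22 ± 1.13
min medications, 3.26 ± 1.17 events, 2.72 ± 1.08 flowsheet) are the
observed latencies of a production minute-cadence feed. The pipeline is
live weekdays 07:00–19:00 with hour blocks dropped independently with
probability 0.10 (sporadic downtime). A case is *captured* when the feed is
live at anaesthesia start — downtime or an off-hours start loses the whole
case, which reproduces a ~74% capture fraction; predictions are only made
at live minutes.

**What the generator does not emulate.** Real procedure-name text (a
template grammar stands in for free text), surgeon identity (deliberately
absent, matching the feed being emulated), pharmacokinetic realism beyond
coarse onset/steady/washout shapes, correlated multi-channel physiology,
case cancellations, and charting errors. Passing tests therefore
demonstrate that the *pipeline machinery* is correct and that the model
exploits end-of-case structure when it exists — not that any particular
CRPS level would transfer to real theatre data.

## Replay and tokenization

The unit of prediction is the snapshot: the view of one case at elapsed
minute `t`, containing exactly the observations with ingestion time ≤
start + t. Visibility is by ingestion, never by charting — the property
that prevents information leaks in offline backtesting — and is verified
against brute-force filtering of the raw stream. Names are tokenized
through a frequency-built vocabulary (padding id 0, unknown id 1, rare
names below `min_count` collapse to unknown) built from the training
window only and frozen thereafter. Flowsheet series carry a 120-min
lookback; older history is summarized by the last value per channel.
Missing channels are represented by an explicit presence mask, never
imputed. Predictions are made from the first minute even before any
intraoperative datum has arrived (preoperative fields only).

## The duration model

The network consumes a fixed-length feature vector per snapshot:
scheduled-duration and elapsed-time terms, one-hot hospital and service,
urgency, counts and recency clocks for the signature tokens (time since
reversal / antiemetic / emergence / induction, capped at 60 min), and
per-channel flowsheet summaries (last value, recency, 10-min mean and
trend, and the washout ratio last/peak for the agent channels). A
fully-connected ReLU network (two hidden layers of 96 by default) ends in
a softmax over K = 128 geometric bins spanning [0, 1440] min of
*remaining* duration; shifting the bin edges by `t` yields the
total-duration forecast, which therefore never places mass below the time
already elapsed. Training minimizes the discretized CRPS of the histogram
against the observed remaining duration — the evaluation metric itself,
with a simple closed-form gradient through the softmax — or optionally
cross-entropy on the label's bin. Optimisation is Adam (lr 1e-3, batch
512, 10 epochs) with strong L2 weight decay (0.2): per-minute snapshots
repeat each case ~100 times and idiosyncratic flowsheet levels (e.g. a
case's heart-rate baseline) act as case fingerprints, so an
under-regularized network memorizes training cases and its held-out CRPS
*worsens* with continued training; heavy decay suppresses this and also
stabilizes the trained model across seeds and training windows. Everything
is seeded and single-threaded, so training is bit-for-bit reproducible.
Summarizing the sequences into recency/level/
trend features rather than encoding them recurrently keeps the model small
enough to train in about a minute on one CPU at the desk scale used here
while preserving the signals that carry remaining-duration information.

A property worth knowing when testing with the CRPS loss: on a fixed bin
grid the CRPS-optimal forecast for a constant target that falls between
bin centres *splits* mass across the adjacent centres rather than
concentrating in one bin (the closed-form optimum of the discrete score);
single-bin concentration is only the optimum of the cross-entropy loss.

## Scoring and aggregation

Forecast histograms are scored as point masses at bin midpoints; the CRPS
integral of the resulting step CDF has the exact discrete (energy) form
`Σ pᵢ|xᵢ−y| − ½ Σᵢⱼ pᵢpⱼ|xᵢ−xⱼ|`, cross-checked in the tests against
trapezoidal numeric integration on a discontinuity-aligned 0.01-min grid.
Since CRPS is translation invariant, scoring on the remaining scale at
`y − t` equals scoring the shifted total-duration forecast at `y`.
Aggregation reports per-stratum prediction counts, mean CRPS, the naive
standard error sd/√n (within-case correlation acknowledged, not
corrected — matching the convention being emulated), and the
model/benchmark ratio, stratified by month, hospital, service, scheduled
duration (0–60/60–120/120–240/240+ min) or percentage elapsed (5% bins),
with an optional minimum-n exclusion.

## Drift monitoring and retraining comparison

Scores are batched by ISO week (calendar Mondays; gap weeks advance the
index) to damp outliers; the weekly ratio of mean model CRPS to mean
benchmark CRPS (< 1 means the model wins; this orientation is fixed and
documented because both orientations appear in common usage) is regressed
on week index by OLS, reporting the slope with a 95% t-interval. The
retraining comparison trains a secondary model with the identical
hyper-parameters on a later, disjoint (proximal) window — building its own
vocabulary and benchmark, as a retrained deployment would — and compares
primary and secondary on a subsequent window via the paired per-prediction
CRPS difference with its naive standard error.

## Numerical and degenerate-input choices

Baseline predictions and all duration labels are floored at 1 min; bin
edges are strictly increasing with bin 0 starting at 0 remaining minutes;
training rejects labels beyond the last bin edge; probabilities must sum
to 1 within 1e-6; the OLS baseline rejects constant scheduled durations
(degenerate design) and fewer than two cases; the drift regression
requires at least three ISO weeks; latency draws are truncated at zero;
snapshot minutes run t = 1..floor(duration) (closed at case start).

## Problem sizes

The test suite and the acceptance script run the study at desk scale:
roughly 2000 captured training cases and 1000 captured test cases
(~300 000 minute-level predictions), 20 seeded replicates for the
null-drift check, and a few hundred cases per window for the retraining
comparisons. These sizes were chosen so the full study runs in minutes on
a single CPU while leaving every statistical check well-powered.

## Known limitations

* The network is a feed-forward summarizer, not a sequence encoder; signals
  that live in fine temporal patterns across channels would be invisible
  to it (the generator does not produce such signals).
* The naive sd/√n standard errors understate uncertainty because the
  minutes of one case share its outcome.
* CRPS mass beyond the last bin edge is truncated into the final bin; with
  a 1440-min maximum this is negligible for realistic case mixes.
* The capture mechanism (registration at start) is one of several
  plausible censoring models; capture fractions other than ~74% require
  retuning `downtime_prob`.
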