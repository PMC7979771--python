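# Methods

This note records the model conventions, estimation procedures, numerical
choices and known limitations behind `flysleep`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The two-phase rest-duration law

A rest bout's duration X has survival function P(t) = P(X > t) with

* a power-law branch P(t) = (t/xmin)^(−β) on [xmin, K], and
* an exponential branch P(t) = P(K)·exp(−(t − K)/λ) for t > K,

joined continuously at the sleep latency K. The survival function is
continuous; its density has a kink at K (the density drops from the
power-law value to the exponential one). We adopt this convention — the
literal reading of the two fitted branches — as the generative model in
`synthetic_data.sample_two_phase` because it preserves the three properties
the analysis relies on exactly rather than approximately: log P is linear
in log t on the whole head, the hazard is exactly β/t below K, and the
excesses X − K above the true changepoint are exactly exponential. The
alternative glue (density continuous at K, survival only asymptotically
power-law on the head) is available as `tail_mode="density"`; under it the
excess distribution above any candidate below K is so close to exponential
that no changepoint scan can localise K usefully, which is why it is not
the default.

Under the default convention the probability of a bout being a sleep bout
is P(X > K) = (K/xmin)^(−β); with day-like parameters (β = 0.8, K = 200 s,
xmin = 1 s) that is ≈ 1.4% of bouts, rising to ≈ 3.5% when sampling only
above the 3 s power-law floor.

### Parameters, units, defaults

| symbol | meaning | unit | typical / default |
|---|---|---|---|
| β | survival exponent of the latency phase (active index) | — | 0.7–1 |
| K | changepoint, sleep latency | s | 200 day / 300 night |
| λ | mean exponential excess, sleep duration | s | 300–2000 |
| xmin | lower support bound of the law | s | 1 (detection floor); fits use 3 |
| N | bouts longer than K | count | — |
| Total | N·λ, sleep time excluding latency | s | — |

β is everywhere the **survival** exponent. Continuous power-law fitters
conventionally report the density exponent α = β + 1; `fit_active_index`
converts and returns β.

## Estimation

**Active index.** Continuous maximum likelihood at xmin = 3 s. When the
changepoint is known (the default pipeline order: K first, then β), the
head sample is restricted to [xmin, K] and the likelihood of the
*truncated* power law is maximised numerically (bounded scalar
minimisation of the negative log-likelihood, stable near α = 1 via
`expm1`). The untruncated closed-form (Hill) estimator is used only when
no K is supplied; applied to a truncated head it is biased upward by an
amount that grows as K/xmin shrinks (≈ +0.13 at K/xmin ≈ 67, β ≈ 0.73),
which is why the truncated MLE is the default. The reported standard error
is the large-sample β/√n.

**Sleep latency.** Ascending changepoint scan from `scan_start` = 50 s at
10% significance. At each candidate K the excesses X − K of the durations
above K are tested against an exponential whose mean λ̂ = mean(X − K) is
estimated from those same excesses; the smallest accepted K wins, and its
λ̂ becomes the sleep-duration parameter. Two procedural choices matter and
were fixed by measuring the pipeline's own parameter-recovery behaviour on
synthetic data (the test suite pins the numbers):

1. *Test variant.* The plain asymptotic one-sample KS p-value ignores that
   λ was estimated and is therefore strongly conservative (the Lilliefors
   effect). A conservative test in a stop-at-first-acceptance scan is not
   harmless: it accepts too early and drags K̂ (and with it λ̂) well below
   the truth. The default is therefore the Lilliefors-corrected exponential
   test (`statsmodels`), which has proper size; the naive variant remains
   as `method="asymptotic"`.
2. *Candidate grid.* Scanning every unique observed duration multiplies
   the number of acceptance opportunities below the true K and amplifies
   the same early-stopping bias. The default grid steps in 5 s increments
   from `scan_start`; the exhaustive data-driven grid remains as
   `step=None`.

Even so, the first-accepted-candidate rule biases K̂ mildly downward
(median ≈ −10% at n = 5000 with day/night-like parameters; the acceptance
suite quantifies this), because candidates just below K carry only a few
percent of power-law contamination — statistically invisible at realistic
tail sizes. λ̂ inherits a small downward bias from the same source. N and
Total = N·λ follow from the accepted K; Total deliberately excludes
latency-phase time.

**Tail model comparison.** ΔAIC = AIC(half-gaussian) − AIC(exponential) on
the excesses beyond K, both one-parameter families fit by ML (σ̂² is the
mean squared excess for the half-gaussian). Positive values favour the
memoryless exponential sleep phase.

**Frame-grid dequantization.** Durations measured from video are multiples
of 1/fps; ties break the continuous MLE/KS machinery. `sleep_parameters`
adds U(0, 1/fps) noise when `dequantize_fps` is given (pass the recording
frame rate); the option is off for already-continuous data.

## Tracking and bout extraction

Backgrounds are reconstructed per light phase as the pixel-wise mean of the
hourly first frames. For recordings shorter than a few hours (test videos)
that rule has too few samples, so up to 25 evenly spaced frames are
combined by a per-pixel 10th-percentile projection instead: the fly only
ever brightens a pixel, so a near-minimum statistic recovers the unoccupied
background at every pixel the fly vacates in a few samples (a mean leaves
ghost blobs that bias centroids by 1–3 px; a median fails wherever the fly
rested through half the samples). A fly parked at one location for
essentially the entire recording is indistinguishable from background by
construction; the missing-detection policy (below) then still accumulates
its rest time correctly.

The chamber interior is segmented from the background by morphological
opening (disk radius 2 px by default) followed by Otsu thresholding of the
dark region and keeping the largest connected component. Detection takes,
among in-mask pixels whose positive difference from the background exceeds
a 5-grey-level noise floor, the 100 largest differences (ties at the 100th
value all included, for order-independence), binarizes them, and returns
the centroid of the largest 8-connected component. Frames whose maximum
difference is below the floor are flagged missing and filled by carrying
the last known location forward — a stationary, undetectable fly must
accumulate rest time, not gaps.

Rest bouts are maximal frame runs staying within `tol_px` (default 1.0) of
the run's **anchor** (its first frame), lasting at least 1 s; duration is
the time between first and last stationary frame, so bouts are quantized to
the frame grid. Anchored tolerance — rather than frame-to-frame
displacement — prevents slow drift from scoring as rest. One consequence
is handled explicitly: a candidate run too short to be a bout releases its
frames one by one instead of consuming them, so a rest whose first frames
fall inside the tolerance disk of a final walking step still anchors its
own run. Extraction is exact (bit-identical to the planted ground truth)
when jitter and tolerance are both zero. Bouts spanning a light transition
are assigned to the phase of their onset, not split. Under constant
darkness, day/night labels follow the hypothetical entrained schedule.

The virtual beam sits at the midpoint of the chamber's long (y) axis;
crossings are sign changes of y − midline, with on-beam frames inheriting
the previous side. Counts are binned in 30-minute Zeitgeber-time bins.

## The brain-state random walk

Each hemisphere occupies one of L (default 50) quietness states; the joint
state (i, j) performs a continuous-time random walk with exponential dwell
of mean θ = (i² + j²)^(a/2) — deeper states are quieter and slower to
leave — and uniform jumps to admissible von Neumann neighbours, reflecting
at L. A bout ends when either hemisphere reaches state 0; its duration is
the first-passage time, whose distribution has a power-law-like head. Past
a distance threshold w from the origin the fly is asleep and an independent
constant-rate wake clock ε competes with the walk; the clock runs only
while the walker is beyond the threshold (the walk may re-cross inward,
pausing it). This competition truncates the first-passage tail into an
exponential with mean ≈ 1/ε.

Interpretation choices the model description leaves open, with our
defaults: the walk starts at (1, 1), adjacent to the wake boundary (state 0
is wake, so the origin itself cannot be the start); the threshold is
Euclidean distance (`threshold_metric="manhattan"` available); the sleep
region is not absorbing (`sleep_dynamics="absorb"` gives the simpler
variant where crossing ends the walk and appends an Exp(1/ε) wake time).
θ carries seconds via `theta_scale` (default 1 s); no further calibration
of model time to fly time is attempted.

`mean_first_passage_oracle` solves the exact expected first-passage time
E(s) = θ(s) + mean of E over neighbours on the interior lattice by a dense
linear solve (L ≤ 12), and the test suite checks the simulator against it
to 3 standard errors at n = 10⁵. The (a, w) sweep simulates each grid cell,
runs the standard fitting pipeline on the simulated durations, and flags
cells whose fitted latency lands in the observed 80–300 s range; with
a ∈ [0, 1], w ∈ [6, 18], ε = 10⁻³/s the feasible set includes cells with
the active index in the observed 0.7–1 band (a controls β̂, w controls K̂,
ε sets 1/λ̂).

## Summary statistics

Sleep profiles count minutes per 30-min ZT bin covered by bouts longer than
a threshold — the per-fly fitted K by default; 300 s reproduces the legacy
5-minute convention — with bouts split proportionally across bins and
multi-day recordings averaged per day before any averaging across flies.
Parameter structure uses tie-corrected Spearman ρ and average-linkage
hierarchical clustering on 1 − ρ (linkage is a convention choice; constant
columns yield flagged NaN correlations and are placed at maximal distance
for clustering only). Group comparisons are two-tailed two-sample t tests,
Welch by default, Student via `equal_var=True`. The sleep-history check
correlates each sleep bout's duration with the sleep accumulated before its
onset, plus consecutive day/night total correlations when phase labels are
present.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the pipeline assumes:
two-phase rest durations, alternating move/rest trajectories in 1D
(5 × 78 mm) and 2D elliptic (50 × 30 mm) chambers at 25 fps with sub-pixel
stationary jitter (0.5 px default), 12h:12h light/dark labelling, and
rendered stacks with a bright fly disk in a dark chamber on a brighter
surround. Movement is waypoint-directed at constant speed with waypoints an
integer number of steps away (so walking frames are always a full step
apart — a property real approach trajectories do not have; real data can
place the last walking frame arbitrarily close to the rest spot, where the
anchored extractor may shift a bout edge by a frame or two). Active-bout
durations are log-normal spacers, not a modelled quantity. Not emulated:
realistic fly appearance and posture, occlusion, multi-fly scenes,
walking-on-ceiling, food-patch geometry, sensor noise and illumination
drift. Passing round-trip tests therefore demonstrates the pipeline's
internal consistency at realistic geometry and noise scales, not
performance on real video.

## Problem sizes used by the checks

Recovery checks run at n = 5000 bouts per sample (50 seeded replicates for
the latency criterion), the switch-rate check at n = 10⁶, the
simulator-vs-oracle check at n = 10⁵ per configuration, the sweep at
n = 8000 bouts per cell on a 5 × 4 grid, and the imaging round trip on a
10-minute 25 fps tube recording at 1.5 px/mm. These sizes were chosen to
hold the statistical tolerances of the assertions with comfortable margin.

## Known limitations

* K̂ from the first-accepted-candidate scan is mildly biased low (see
  above); comparisons between groups fit with the same settings are
  unaffected, absolute latencies should be read with that bias in mind.
* The KS scan needs ≥ 10 tail samples (configurable); flies with very
  little sleep in a phase fail the scan loudly rather than silently.
* The tracker is single-fly by design and assumes the fly is the only
  moving bright object in its chamber.
* Whether rest durations below the 3 s fitting floor follow the same power
  law is untestable from bout statistics alone; the generator supports
  xmin down to the 1 s detection floor, and the law below 3 s is simply
  extrapolated.
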