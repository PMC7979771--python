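# flysleep

Quantitative rest/sleep analysis for *Drosophila* locomotion recordings.

Fly sleep has traditionally been scored with a single fixed rule — any rest
bout longer than 5 minutes counts as sleep — which confounds animals that
fall asleep slowly with animals that sleep briefly. `flysleep` implements a
two-phase statistical description of rest that separates those axes and
yields five interpretable parameters per fly and circadian phase. It is
aimed at groups doing fly sleep behaviour with video tracking (or beam
monitors), and at modellers interested in the generative dynamics behind
heavy-tailed bout statistics.

## The model

Let X be the duration of a rest bout and P(t) = P(X > t) its survival
function. Rest durations follow a two-phase law:

```
P(t) ∝ t^(−β)            xmin ≤ t ≤ K     (sleep-latency phase)
P(t) ∝ exp(−t/λ)         t > K            (sleep phase)
```

equivalently a switch rate (hazard) w(t) = β/t below K and 1/λ above it.
The five parameters per fly and phase are:

| parameter | name | meaning |
|---|---|---|
| β | active index | power-law exponent of short rests; larger β = resumes moving sooner |
| K | sleep latency (s) | changepoint where the power law hands over to the exponential |
| λ | sleep duration (s) | mean exponential excess beyond K |
| N | sleep bouts | number of rest bouts longer than K |
| Total | total sleep (s) | N × λ, sleep time excluding latency time |

β is fit by continuous maximum likelihood on [xmin, K] (xmin = 3 s) and is
reported as the *survival* exponent — one less than the density exponent
that off-the-shelf power-law fitters return. K is located by scanning
candidate changepoints upward from 50 s and keeping the smallest K whose
excesses X − K pass a Kolmogorov–Smirnov test against an exponential with
mean estimated from those same excesses (Lilliefors-corrected, 10%
significance).

The package covers the full chain:

* `flysleep.tracking` — background-difference tracking of a bright fly in a
  dark chamber (per-phase background, morphological chamber segmentation,
  top-100-difference centroid detection) and a virtual midline beam that
  emulates the classic infrared activity monitor;
* `flysleep.bouts` — rest-bout extraction (anchored 1-px stationarity,
  1 s minimum) and day/night labelling in Zeitgeber time;
* `flysleep.sleep_fit` — the five-parameter fit with diagnostics (KS
  p-value, gaussian-vs-exponential tail ΔAIC);
* `flysleep.brainstate_sim` — a two-hemisphere brain-state random walk whose
  first-passage times reproduce the two-phase pattern, with an exact
  Markov-chain oracle and an (a, w) parameter sweep;
* `flysleep.synthetic_data` — generators for bout samples, trajectories and
  rendered frame stacks with planted ground truth;
* `flysleep.summary_stats` — activity/sleep profiles in 30-min bins,
  Spearman correlation structure with clustering, group t tests, and a
  sleep-history independence check.

## Worked example

Fit the five parameters to synthetic rest durations generated at the male
light-phase parameters:

```python
import numpy as np
from flysleep import TwoPhaseSpec, sample_two_phase, sleep_parameters

spec = TwoPhaseSpec(beta=0.73, K=200.0, lam=1000.0, xmin=1.0,
                    n_bouts=5000, seed=42)
durations = sample_two_phase(spec)
p = sleep_parameters(durations, xmin=3.0, scan_start=50.0, alpha=0.10)
print(f"beta  = {p.beta:.3f}   (active index)")
print(f"K     = {p.K:.0f} s    (sleep latency)")
print(f"lam   = {p.lam:.0f} s   (sleep duration)")
print(f"N     = {p.N}      (sleep bouts)")
print(f"Total = {p.total/3600:.2f} h  (N x lam)")
print(f"dAIC  = {p.delta_aic_gauss_minus_exp:.1f}  (gaussian - exponential tail)")
```

prints

```
beta  = 0.754   (active index)
K     = 175 s    (sleep latency)
lam   = 897 s   (sleep duration)
N     = 105      (sleep bouts)
Total = 26.16 h  (N x lam)
dAIC  = 19.0  (gaussian - exponential tail)
```

The fitted active index (0.754) sits within two standard errors of the
generating value 0.73; the latency lands near the generating 200 s (the
first-accepted-candidate scan has a known mild downward bias, documented in
`docs/methods.md`); the strongly positive ΔAIC says the sleep tail is
exponential rather than gaussian — sleeping flies wake at a constant rate,
with no memory of how long they have slept.

The same fit runs from the shell on a bouts table:

```sh
flysleep synth bouts --spec spec.json -o bouts.csv
flysleep fit run --bouts bouts.csv --xmin 3 --scan-start 50 --alpha 0.10 -o params.csv
```

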