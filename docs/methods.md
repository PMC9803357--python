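# Methods

This note documents the models, algorithms, and numerical choices behind
`stoprace`, and what the synthetic-data generators do and do not emulate.

## The race model with trigger failures and censoring

Behavior in the stop-signal task is modelled as an independent horse race.
On every trial a *go* runner is launched at the go stimulus; on stop trials
a *stop* runner is launched SSD ms later. A response is emitted iff the go
finishing time beats both `SSD + stop finishing time` and the response
deadline (1000 ms by default). Both finishing-time distributions are
ex-Gaussian — Normal(µ, σ) convolved with Exponential(τ) — so each runner
has mean µ + τ and variance σ² + τ². With probability `p_tf` (a *trigger
failure*) the stop runner is never launched and the stop trial behaves like
a go trial. The trial-level likelihood has three components:

* go response at RT t: `f_go(t)`; censored go trial (omission or response
  past the deadline D): `1 − F_go(D)`;
* failed stop (signal-respond RT t at delay d):
  `f_go(t) · [p_tf + (1 − p_tf)(1 − F_stop(t − d))]`;
* successful stop at delay d:
  `1 − p_tf·F_go(D) − (1 − p_tf) ∫^D f_go(t)(1 − F_stop(t − d)) dt`.

Responses faster than 200 ms (anticipations) and incorrect responses are
removed before fitting; the likelihood is *not* renormalised for this lower
truncation (the excluded mass is a fraction of a percent at realistic
parameters, which `tests/test_nonparam.py` checks). A "successful stop" is
simply the absence of a response before the deadline, so deadline censoring
is part of the inhibition probability rather than a separate term.

### Units

All quantities are in milliseconds throughout the package — parameters,
trial tables, priors, and likelihood internals. A single unit removes an
entire class of conversion bugs; the log-space density evaluation makes the
choice numerically immaterial.

### Numerical evaluation

The ex-Gaussian density and survival function are evaluated in log space
via `log Φ` (`scipy.special.log_ndtr`), stable for σ/τ from 0.01 to 100 and
far into both tails (`stoprace.exgauss`). The reference implementations of
the likelihood components (`stoprace.race`, scalar API) evaluate the
successful-stop integral with adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`, absolute tolerance 1e−10) and raise
`RaceNumericalError` rather than returning silent NaNs. The vectorised
sampler path groups successful-stop trials by unique SSD and splits the
integral into an exact go-CDF "head" below the point where the stop
survival starts to fall, plus a 64-node Gauss–Legendre rule across the
transition region `[d + µ_s − σ_s − 8(σ_s + τ_s), d + µ_s + 8σ_s + 15τ_s]`.
The split keeps the rule accurate for arbitrarily small stop-runner scales
(worst case ~1e−3 absolute against adaptive quadrature over a random
stress grid including near-degenerate scales; ≤1e−6 at realistic
parameters). The likelihood-closure property (response density plus
censoring and inhibition masses summing to 1 within 1e−4) is tested.

## Hierarchical Bayesian estimation (DE-MCMC)

Each participant has seven parameters (`µ_go, σ_go, τ_go, µ_stop, σ_stop,
τ_stop, p_tf`), with `p_tf` sampled on the probit scale. Participant-level
parameters follow truncated-normal population distributions parameterised
by location and scale; locations and scales carry truncated-normal
hyperpriors. For inference, population locations/scales are transformed to
the population **means** and SDs of the truncated distributions, and the
probit-scale trigger-failure distribution to the population mean of `p_tf`
via `E[Φ(Z)] = Φ(loc/√(1 + scale²))`.

Sampling is Differential-Evolution MCMC: 21 chains (three per participant
parameter), crossover proposals `θ' = θ + γ(θ_{r1} − θ_{r2}) + ε` with
`γ = 2.38/√(2d)` and a small uniform jitter scaled to each dimension's
span, migration steps (probability 0.05, ring-swap of a random chain
subset) during burn-in only, and thinning (keep every 15th sweep) of the
retained draws. Updates alternate participant blocks (7-dim, two passes
per sweep, vectorised across chains and participants) and population
blocks. Population updates are per-parameter (location, scale) pairs —
the conditional posterior factorises across parameters, and small 2-dim
DE moves mix far better than one 14-dim joint move; three passes per sweep
cost little next to the data likelihood. Defaults: 1000 burn-in sweeps,
500 retained thinned draws per chain; all settings in `SamplerConfig`.

Start values default to a moments-based heuristic (ex-Gaussian moment
matching on the go RTs, plus generic stop-runner values, jittered per
chain); short non-hierarchical individual fits are available as start
values via `start="individual"`.

### Priors and the funnel degeneracy

Priors are weakly informative truncated normals covering a wide but
realistic range (ms): locations µ ~ TN(500, 1000) on (0, 2000), σ and τ
locations ~ TN(100, 1000) on (1, 1000), probit-`p_tf` location ~
TN(−1.5, 1) on (−6, 6); scales ~ TN(100, 1000) on (1, 1000) (probit scale
~ TN(0.5, 1) on (0.01, 3)). Two aspects matter and were chosen
deliberately:

* **Scales are bounded away from zero.** σ_stop is nearly unidentified at
  realistic stop-trial counts (the profile likelihood is flat across
  (0, 60) ms at 160 stop trials; identification emerges only at ~100× the
  data). If the scale prior reaches 0, the joint posterior contains the
  hierarchical funnel's coalescence spike (all participants equal,
  scale → 0, density → ∞), which a correct sampler will find and which
  destroys recovery of the population location. A 1 ms lower bound keeps
  the posterior proper and recoverable.
* **Location supports match the participant-level truncation bounds.** A
  location below the participants' lower bound turns the truncated-normal
  population into a boundary spike with unbounded density as the scale
  shrinks.

All priors are config-exposed (`HierPriors`) so alternative settings can be
dropped in.

### Convergence

`rhat` implements the classic Gelman–Rubin potential scale reduction
factor (between- vs within-chain variance), with the usual < 1.1
convergence rule, plus the Brooks–Gelman multivariate variant. In the
recovery configuration shipped in the acceptance tests (8 participants ×
480 trials, 21 chains, 1000 burn-in, 500 × 15-thinned retained draws) all
population-level R̂ values are ≤ ~1.02 and the seven population-location
95% CIs cover the generating values.

## Group inference

Group comparisons use the folded Bayesian p: pair the two groups' posterior
samples by (chain, iteration) index after transformation to inference
scales, form the per-draw difference, and report `min(p, 1 − p)` where `p`
is the fraction of draws with A > B. The two-sided reporting threshold is
0.05 (one-sided 0.025). Posterior predictive checks simulate replicate
staircase sessions from ≥100 posterior draws and compare go-RT and
signal-respond-RT decile curves, the inhibition function over observed
SSDs, and median signal-respond RT by SSD; the reported p-value per
statistic is replicate exceedance, with per-SSD inhibition-rate exceedance
as the default misfit probe. `mix_posteriors` concatenates retained draws
across refits (e.g. full data plus SSD-subset refits) with equal weight.

## Non-parametric SSRT (integration method)

`P(respond | stop)` is computed from the analyzable stop trials; go
omissions (and censored responses) are replaced by the deadline value;
SSRT = the `ceil(p · n_go)`-th order statistic of the replaced go-RT
distribution minus the mean SSD. The estimator is undefined at p ∈ {0, 1}
and returns a flagged NaN. On trigger-failure-free simulated data it
converges to the generating µ_stop + τ_stop (±15 ms at 10,000 stop
trials); generating trigger failures inflate it monotonically — the
confound the hierarchical model exists to remove.

## Beta-burst detection and quantification

Each channel is convolved with complex Morlet wavelets
`w(t,f) = A exp(−t²/2σ_t²) exp(2iπft)`, `σ_t = m/(2πf)`, `A = 1/(σ_t√2π)`,
`m = 7` cycles, at 15 evenly spaced frequencies spanning 15–29 Hz; power is
the squared magnitude. Edge zones of 3σ_t of the lowest frequency are
flagged invalid; maxima are located on the full time axis and then filtered
to the valid region (locating them on a pre-trimmed slice would
manufacture spurious border maxima). A burst is a regional maximum of the
trial's frequency × time power matrix exceeding 2× the median of the
electrode's entire valid power matrix pooled over trials. Plateau maxima
are reduced to one representative (earliest time, then lowest frequency).
Because the threshold is relative to the median, burst counts are invariant
under global amplitude scaling.

Burst rates: stop trials count frontal (FCz) events in `[SSD, SSD + SSRT)`
relative to go onset; go trials in `[SSD_current, SSD_current + SSRT)`
using the staircase's held SSD for the trial's side; counts are divided by
SSRT (s) and baseline-normalised by subtracting the same trial type's
pre-go ([−500, 0) ms) rate. The SSRT entering these windows is the
participant-level posterior mean of µ_stop + τ_stop from the hierarchical
fit. The sensorimotor (C3/C4) analysis time-locks Successful-stop trials
to the first detected frontal burst in the critical window (trials without
one form the random-time-locked control), computes the sensorimotor burst
rate in ±25 ms sliding windows at 2 ms steps over lags −100..+100 ms, and
converts to percent change against the pre-go sensorimotor baseline.
Rates are averaged across trials before the percent-change conversion:
per-trial baselines are frequently zero bursts, so a per-trial ratio is
undefined; the participant-level ratio is the stable alternative. Window
edges are half-open `[start, end)`; event times are at sample resolution
(2 ms at 500 Hz).

## Synthetic data: what is emulated, and what is not

### Behavior

`simulate_participant` draws go and (triggered) stop finishing times from
the generating ex-Gaussian distributions (negative draws are rejected and
redrawn — immaterial at realistic parameters), applies the deadline, and
tracks SSD with ±50 ms staircases per response side starting at 200 ms
(floored at 0, capped 50 ms below the deadline). Defaults follow the task
that motivated the package: 480 trials, 1/3 stop, 1000 ms deadline. Go
omissions arise only from deadline censoring; optional lapse and
choice-error knobs (default 0) exist for robustness tests. One integer
seed expands into independent per-participant streams
(`numpy.random.SeedSequence`), making runs bit-reproducible.

### EEG

`synthesize_eeg` produces artifact-free epochs at virtual electrodes
(FCz, C3, C4), aligned to go onset, default window −700..+1200 ms — padded
beyond the −500..+1000 ms analysis span so wavelet edge-trimming never
eats into the baseline or the counting windows. Each epoch contains:

* 1/f background noise (FFT-shaped, exponent 1), optionally modulated by a
  slow lognormal envelope (off by default);
* a dense stream of weak, untracked *background* beta bursts on every
  channel (10/s, lognormal amplitudes, ~3 cycles). Real beta-band activity
  is quasi-continuous burst-like idling; this occupancy puts the
  electrode's median time-frequency power in the burst regime, so the
  2×-median cutoff behaves as it does on real data rather than passing a
  fifth of the Gaussian noise maxima;
* tracked task bursts: condition-specific frontal bursts inside an event
  window opening at the (would-be) stop signal (defaults: 2.0/s on stop
  trials, 0.5/s on go trials, 300 ms window), optional spontaneous tracked
  bursts (`baseline_rate`), and frontal→sensorimotor coupling: each
  tracked frontal burst is followed with configurable probability and
  latency (mean ± jitter) by a burst on C3 or C4. Tracked bursts are
  ~3 cycles (~150 ms at 20 Hz, the duration seen in real recordings) at
  amplitude 3× the noise RMS, placed with a minimum one-burst gap, and
  recorded as ground truth (trial, channel, time, frequency).

What passing tests on this world do **not** show about real data: the
detector's event floor here (~5/s at the 2×-median threshold) is a
property of quasi-Gaussian synthetic backgrounds — any dense stationary
superposition is driven Gaussian by the central limit theorem, and the
median-relative threshold then passes a stable fraction of its local
maxima. Real recordings appear to have sparser supra-threshold floors, so
absolute burst rates and the attenuation of injected effects (detected
stop-minus-go differences recover the injected contrast only partially)
are generator-specific; the *directions* and the additivity of the
analyses are what the tests establish. Similarly, the burst-locked
sensorimotor time course shows a small negative offset at pre-burst lags —
a window-position artifact of first-event locking in a floor-heavy world —
while the post-burst elevation that the analysis targets is reproduced
cleanly. No ocular/muscle artifacts, volume conduction, re-referencing, or
current-source-density behavior is emulated.

## Pipeline problem sizes

The shipped demo configuration (`RunConfig` defaults) runs 4 participants
per group at 480 trials with a reduced sampler (300 burn-in, 100 × 3
thinned draws); the acceptance tests use 8 participants × 480 trials with
the full sampler settings (1000 burn-in, 500 × 15) for parameter recovery,
16-participant cohorts for the behavioral calibration checks, and
8–12-participant groups at 480 trials for the EEG chain. Monte-Carlo
likelihood validation uses 10⁶ races per parameter-set × SSD cell.

## Known limitations

* σ_stop and τ_stop are weakly identified at single-session trial counts;
  their participant-level posteriors are prior-dominated, and only the
  population level carries usable information. This mirrors the model's
  behavior on real data, not a sampler deficiency.
* The integration SSRT's omission-replacement step assumes omissions are
  censored slow responses; generator lapses (if enabled) violate that
  reading.
* The mixed ANOVA applies no sphericity correction (uncorrected degrees of
  freedom, as in the analyses the package reproduces) and the sample-wise
  time-course tests are deliberately uncorrected for multiple comparisons;
  both facts are recorded in the result objects.
* `bayesian_p` pairs independently fitted groups by draw index; any pairing
  is valid for independent fits, and the fixed pairing is reproducible.
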