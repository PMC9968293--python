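# Methods

`coreg` analyses how the pace of perceptual decisions and of the movements
reporting them co-vary when time constraints apply to only one of the two.
It implements the full computational chain for a two-banana Tokens task —
stimulus generation, a generative cohort simulator, behavioral endpoint
statistics, drift-diffusion modelling, and psychophysical kernels — so that
the analyses run end-to-end on synthetic data with known ground truth.

## Stimulus model

A trial presents 179 binary evidence frames at 60 Hz; each frame extends
either the left (−1) or right (+1) banana by 2°, so the winning growth path
covers 358° and the odd frame count guarantees a strict winner.  The
*success probability* of a lead of `delta` frames with `r` frames remaining
treats every remaining frame as an independent fair Bernoulli draw:

    P(win) = P(delta + 2K − r > 0),  K ~ Binomial(r, 1/2),

with a tied finish counting as a loss (ties cannot occur on full trials).
An exhaustive-enumeration oracle (all `2^r` assignments, refusing `r > 20`)
pins this definition down in tests to 1e−12.

Trial types are operationalised on the running success probability
`p_w(t)` of the eventual winner, with fixed constants stored in
`TaskDesign` (burn-in 30 frames, "early" = first 90 frames, band 0.4/0.6):

- **obvious** — `p_w(t) ≥ 0.6` on every frame after the burn-in;
- **misleading** — `p_w(t) ≤ 0.4` on some early frame (winner still wins);
- **ambiguous** — `p_w(t)` strictly inside (0.4, 0.6) on every early frame;
- **random** — anything else; as a *requested* type it accepts any draw.

Sequences are rejection-sampled from uniform ±1 draws against this
classifier.  One deliberate design choice: the ambiguous band is a
~90-step corridor constraint that uniform proposals hit with probability
~2e−5, so the ambiguous proposal reflects early steps at the band edges
before the classifier arbitrates.  This changes per-frame marginals
slightly but keeps the accepted set identical to uniform rejection
sampling.  Trial lists realise the 30/30/20/20 type mixture exactly
(requiring multiples of 10 trials) and counterbalance winning sides to
within one trial by mirror-imaging, under which all type labels are
invariant.

## Cohort generator

Each simulated participant is an evidence-integrating agent, not a
diffusion model: on frame `k` the accumulator gains `gain·step_k + ε_k`,
`ε_k ~ N(0, σ)`, and commits when it reaches a **linearly collapsing
bound** `B·(1 − k/179)`.  The collapse is required: with a fixed bound the
slow conditions either produce 25–45% non-responses or cannot reach ~1.8-s
median decision durations.  Because the agent integrates the actual frame
sequence, psychophysical kernels computed from its choices have the
characteristic rise-peak-fall shape; data from a plain diffusion process
would yield flat kernels.

Reaction time = commit-frame end time + a truncated-normal motor delay
(≥ 50 ms); responses later than the 3000-ms deadline become no-response
trials.  Tap intervals are truncated normal (floor 60 ms).  Movement
correctness follows the task rules: in the decision session the four taps
must finish within 3000 ms; in the movement session the caterpillar head
(advancing 36° per tap) must additionally beat a chasing snake at 85% of
the maximum tapping speed (fast) or stay behind a retreating snake at
59.5% of it (slow), checked tap by tap.  Simple-reaction-time (SRT) trials
are a constant detection latency (default 180 ms) plus the same motor
delay, so reaction time ≈ decision time + SRT holds in expectation.
Nuisance processes: attentional lapses (no response) and anticipations
(uniform 1–140 ms guesses) at `lapse_prob/2` each, pre-phase premature
presses at 1%, and 2% of trials flagged for frame-rate deviations.

Default condition effects are the *study conditions*: they were calibrated
once against the published condition magnitudes and then frozen.

| session  | parameter          | slow   | fast diff | targets reproduced |
|----------|--------------------|--------|-----------|--------------------|
| decision | bound              | 25     | −11       | decision-duration medians ~1774/1006 ms |
| decision | motor delay (ms)   | 480    | −300      | kernel peak-latency gap ≥ 300 ms; DDM Δt0 |
| decision | tap interval (ms)  | 186    | −16       | tap medians 186/174 ms |
| movement | bound              | 22.5   | −2.5      | decision-duration gap ~89 ms |
| movement | motor delay (ms)   | 360    | −30       | small, mostly undetectable Δt0 |
| movement | tap interval (ms)  | 263    | −117      | tap medians 263/146 ms |

Accumulator noise σ = 0.4 and gain 1 set the speed/accuracy regime
(accuracies ~0.84 slow / 0.76 fast in the decision session; the published
contrast is somewhat larger, ~86%/71% — a known approximation of this
generator).  Between-participant spread applies to intercepts (bound ± 2.5,
motor delay ± 60 ms, taps ± 25 ms) and, more tightly, to the condition
differences, making planted effects directionally consistent across most
participants, as in the study this emulates.  Per-participant streams
derive deterministically from `seed + participant index`.

What the generator does **not** emulate: learning and fatigue across
blocks, trial-history dependencies, non-stationary lapse rates, keyboard
hardware jitter, and any genuine coupling between decision and movement
systems beyond the planted parameter differences.  Passing recovery tests
therefore shows the *analysis chain* is correct and sensitive at the
planted magnitudes, not that real behavior satisfies the generator's
assumptions.

## Endpoint analysis

Exclusions mirror the behavioral rules: no-response trials, pre-phase
presses, frame-rate-flagged trials, main-task anticipations (decision
duration — reaction time minus the participant's mean SRT in the matching
condition — below 150 ms) and SRT trials faster than 50 ms.  The
anticipation rule uses participant-and-condition-matched SRT means; the
decision session has a single snake-free SRT block shared by both
conditions.  Decision duration and success probability are computed over
movement-correct trials; movement accuracy over decision-correct trials;
cells with < 5 usable trials per measure are set missing.  Success
probability evaluates the evidence state at the frame containing the key
press (ceiling convention: frame k covers ((k−1)/60, k/60] s).

Paired condition contrasts default to the **exact sign test** (statistic S
= number of positive differences, zeros dropped, exact binomial two-sided
p) with the Wilcoxon signed-rank test available as an alternative; both are
reported by the pipeline and the choice is a config switch.  Median
differences carry order-statistic (distribution-free) CIs.  Monotonic
relationships use Spearman's rho with `t = rho·sqrt((n−2)/(1−rho²))`, plus
a robustness pass that removes bivariate outliers flagged by the
reweighted fast-MCD estimator (support fraction ⌊(n+3)/2⌋/n, chi-square(2)
0.975 cutoff) and re-estimates; CIs via the Fisher transform.  Condition
means are displayed with Cousineau-centred, Morey-corrected
(`sqrt(C/(C−1))`) within-subject 95% CIs.  Families of tests are corrected
with Holm's step-down procedure.

## Drift-diffusion model

Unit-noise Wiener process on {0, a}, start `z·a` with z fixed at 0.5,
drift v, non-decision shift t0; correct/error responses map to the
upper/lower boundary.  The first-passage density uses the dual
(small-time / large-time) series representation with the standard
truncation criterion at absolute error 1e−7; it is validated by quadrature
normalisation (1e−6) and against a simulation histogram.  The likelihood
is the 0.95·WFPT + 0.05·uniform mixture (uniform over (0, max rt], half
weight per boundary), the standard contaminant assumption.  Reaction times
below 150 ms are discarded before fitting.

Five condition structures are compared: all-fixed, a, t0, a+t0, a+t0+v,
parameterised as a slow-condition intercept plus a fast-condition
difference.  Two fitting routes:

- **Per-subject maximum likelihood** (default): multi-start (≥ 5)
  Nelder-Mead within bounds a ∈ [0.3, 8], v ∈ [−10, 10], t0 ∈ (0, 2.5];
  model comparison by summed BIC (AIC also reported).
- **Hierarchical Bayes**: subject parameters Normal around group means;
  priors — group means a ~ N(2, 2) truncated > 0.1, v ~ N(0, 5),
  t0 ~ N(0.4, 1) truncated ≥ 0, differences ~ N(0, 1); group sds
  Half-Normal(1).  Sampling is adaptive Metropolis-within-Gibbs: blocked
  random-walk subject updates (scales tuned to ~25% acceptance during
  burn-in, frozen afterwards), conjugate Gibbs for group means, log-scale
  Metropolis for group sds.  The default schedule is two chains, 5000
  burn-in, every third of 6000 kept (4000 retained samples per parameter);
  analyses on a time budget run a proportionally shortened schedule and a
  participant subset, stated where used.  Convergence: split-chain
  Gelman-Rubin for every group-level parameter, < 1.1 considered
  satisfactory; larger values attach a warning and flag the fit rather
  than aborting.

Model comparison uses BPIC = D̄ + 2·p_D with p_D = D̄ − D(posterior mean);
DIC is reported alongside.  Condition-effect evidence is the fraction of
posterior samples of the group-level difference below zero, with 97% as
the existence threshold; a fraction of exactly 1 is reported as bounded by
the sample resolution (e.g. "> 99.975%" at 4000 samples).  Posterior
predictive checks simulate replicate datasets from the fitted parameters
and flag observed accuracy or RT quantiles (0.1–0.9, correct and error
separately) outside the simulated 95% intervals.  The Euler-Maruyama
simulator (dt = 1e−4 s) applies the standard inward boundary shift
(0.5826·σ·√dt) that corrects discrete-monitoring bias, and matches the
closed forms P(upper) = 1/(1+e^(−av)) and E[DT] = (a/2v)·tanh(va/2) within
Monte-Carlo error.  Inter-trial variability parameters (sv, st, sz) and
response-bias estimation are deliberately out of scope.

## Psychophysical kernels

Momentary evidence is the sliding-window sum of the ±1 steps over 200,
300, 400 or 500 ms (12/18/24/30 frames); windows are labelled by their
*final* frame — the moment the summed evidence has been fully seen — which
keeps the post-commitment null sharp.  Response-locking maps the reaction
time to its containing frame by ceiling; lag 0 is the window ending at the
response frame.  Per lag, the window sum is correlated across trials with
the signed choice (−1/+1); trials too short to contain a lag drop out at
that lag, lags with < 10 trials are undefined, and kernels need ≥ 30
usable trials.  The peak is the maximum correlation between the expected
decision onset (negative median RT) and the response, ties breaking toward
the response; the slope is the least-squares slope of r against time from
onset to peak (units 1/s); peak latency is the peak-to-response time.
Condition contrasts per timespan use a paired t-test when Shapiro-Wilk
does not reject normality of the differences (α = 0.05), otherwise the
signed-rank test, Holm-corrected across the four timespans; all-zero
difference sets (e.g. identical peak latencies) short-circuit to p = 1.

## Pipeline, sizes and reproducibility

The `coreg` CLI exposes `simulate`, `endpoints`, `ddm-fit`, `kernels` and
`run`; stages exchange CSV/JSON intermediates, reject unknown config keys,
and are deterministic given the seed (per-stage seeds derive from it).
The acceptance script regenerates everything from scratch: design
constants; oracle equivalences; diffusion closed-form limits at 1e5
simulated walks; MLE recovery over 20 subjects × 400 trials at the
slow-decision group means; and a 40-participant, 160-trials-per-condition
cohort with the default planted effects, analysed by endpoints, a
five-model hierarchical comparison (12-participant subset, shortened
two-chain schedule: 400 burn-in, every third of 900), and kernels.  These
problem sizes are the package's chosen benchmark scale; the full published
schedule remains available through `MCMCConfig` defaults.

## Known limitations

- The trial-type thresholds (0.4/0.6 band, 90-frame "early" horizon,
  30-frame burn-in) are one reasonable operationalisation of qualitative
  descriptions; alternatives would shift type base rates.
- The generator's speed-accuracy contrast between decision conditions is
  flatter than the published one; endpoint *duration* effects, not
  accuracy contrasts, are the planted quantities.
- The hierarchical sampler is a straightforward adaptive MH-within-Gibbs;
  at sharply reduced schedules the Gelman-Rubin diagnostic can exceed 1.1
  for some group-level scales (reported and flagged, never hidden).
- The window-position and response-locking conventions of the kernels are
  configurable choices; published analyses do not state theirs.
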