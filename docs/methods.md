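# Methods

## The model

`normcascade` implements a cascaded firing-rate circuit in which value
coding is divisively normalized on two timescales.  Each of N choice
options is represented by a paired excitatory (value-coding, R) and
inhibitory (gain-control, G) unit in a *fast* and a *slow* subcircuit:

    tau_F dG_i^F/dt = -G_i^F + sum_j omega_ij R_j^F + sum_k alpha_ik R_k^S
    tau_F dR_i^F/dt = -R_i^F + V_i / (1 + G_i^F)
    tau_S dG_i^S/dt = -G_i^S + sum_j beta_ij R_j^S
    tau_S dR_i^S/dt = -R_i^S + V_i / (1 + G_i^S)

The fast circuit (tau_F ~ 100 ms) captures intra-trial dynamics of a
decision-related area: phasic onset transients, sustained value coding,
and cross-option normalization.  The slow circuit (tau_S ~ tens of
seconds) integrates value input over many trials; its excitatory output
feeds the fast circuit's gain pool, so the *statistics of recent rewards*
set the instantaneous gain of value coding.  With `alpha = 0` the fast
circuit decouples and the model reduces exactly to the classic
single-timescale dynamic normalization circuit — a reduction verified in
the tests against an independently coded integrator.

Assumptions inherited from the simplest form of the model: all weights
are 1 (gain pools are global within a stage, no tuned connectivity),
excitatory and inhibitory time constants are equal within a stage,
baseline activity is zero, and the slow circuit sees the same value
timeline as the fast circuit.  Because the equations are invariant under
a joint rescaling of (tau_F, tau_S, t), only the ratio tau_S/tau_F
matters; a property test asserts this invariance numerically.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| `tau_fast` | 100 | ms | fast normalization dynamics of value-coding circuits |
| `tau_slow` | 60 000 | ms | ratio 600; slow timescales of ~50–80 s best track behavioral adaptation |
| `omega`, `alpha`, `beta` | all-ones | – | simplest form: global, unweighted gain pools |
| `dt` | 1 | ms | behavioral timelines are evaluated at millisecond resolution |

## Numerics

**Integration.** Classical RK4 with the value input held constant over
each step at its step-midpoint value.  The input is piecewise constant,
so any step lying inside one segment integrates an autonomous system at
full fourth order; event boundaries are emitted on integer milliseconds
so the default 1 ms grid never straddles a discontinuity.  Empirical
convergence order on the block-step scenario is ~4.07.  The kernels are
numba-compiled; a full 578-trial session (~30 min of simulated time,
~1.8 M steps) integrates in well under a second.  Non-finite states abort
with the offending time and trial.  From nonnegative initial conditions
and inputs all activities stay nonnegative (property-tested); state is
carried continuously across trials and blocks from an all-zero start, and
no reset occurs at the block boundary.

**Steady state.** The slow subsystem is autonomous, so its fixed point
`R^S (1 + beta R^S) = V` is solved first (scipy `hybr` root finder,
damped fixed-point iteration as fallback, long integration as last
resort); the slow output then enters the fast stage as a constant.  For
N = 1 and all-ones weights the stages are quadratics, used as exact test
oracles.

## Task model and synthetic sessions

A session is two contiguous blocks (narrow/wide, order random) of 289
trials: 60% adapter trials with both offers drawn i.i.d. from a
block-specific discretized Gaussian over the magnitude grid, 40% test
trials pairing a fixed reference against one of five variable magnitudes
(identical design in both blocks).  ITIs are uniform integers on 600–900
ms; 15% of trials abort (matching ~85% task accuracy) and append a
time-out to their ITI while still presenting their offers to the model.

Stated-world choices the task description leaves open, fixed once:

- magnitude grid 1–12 (discrete displayed reward quantities), adapter
  mean 6, SD 1 (narrow) vs 3 (wide);
- test magnitudes {2, 4, 6, 8, 10} versus reference 6 of the other juice
  type — the reference sits at the middle level so curves straddle
  indifference;
- value input = reward magnitude (identity map).  Juice-type utility
  differences are absorbed into the reference magnitude; the model input
  is a scalar value per option;
- display window 2100 ms per trial (1200 ms fixation-hold + 500 ms
  saccade + 400 ms target hold), during which V is on; V = 0 otherwise;
- post-abort time-out 2000 ms.

The generator emulates the task's *statistical* structure only.  It does
not model satiety, preference drift, reaction times, or any sequential
choice strategy, and the stand-in chooser (base-10 logistic in the
magnitude difference) has, by construction, no adaptation to reward
variance.  A green adaptation test therefore establishes that the
*model* converts adapter variability into choice-curve slope changes —
not that the synthetic behavior does.

## Choice readout

Each non-aborted test trial is read out as the mean fast-circuit rate of
each option over the final 200 ms of the display (the plateau of the
phasic response; the readout window is configurable).  Two readouts are
reported per trial:

- **argmax** — deterministic choice of the larger readout; ties within
  `tie_epsilon = 1e-12` go to option a.  With all-ones weights both
  options share one gain pool, so the argmax follows the value ordering
  on essentially every trial: it yields step-function choice curves that
  are *identical across blocks* and carries no adaptation signal.
- **probabilistic** (default for slope analyses) — the rate difference
  dR = r_a − r_b is mapped through `p(a) = 1 / (1 + 10^(−dR/sigma))`
  with sigma equal to the pooled SD of dR over the session's test
  trials.  This operationalizes reading choice stochasticity out of the
  *size and variability* of the firing-rate difference: the gain set by
  reward history rescales dR trial by trial, and because sigma is common
  to both blocks, block differences in that rescaling appear as block
  differences in choice-curve slope.  The pooled SD is dominated by the
  fixed spread of test magnitudes, so sigma acts as a stable per-session
  readout-noise scale rather than a block-dependent normalizer.

The mechanism of the adaptation effect: in wide blocks the slow circuit's
activity fluctuates more across ~tau_S windows, so the fast gain at test
trials is more variable, dR/(readout scale) is more variable, and the
aggregated choice curve is flatter — narrow-block curves come out steeper
on average, with session-to-session scatter in both directions.

## Psychometrics

Per-block choice data are summarized as per-level chose-variable
proportions and fit with `y(x) = 1/(1 + 10^((x50 − x) s))`.  The default
objective is least squares on the level proportions (matching how fit
quality is reported as an rmse); binomial maximum likelihood is available
via `method="mle"` and is the statistically efficient choice for
parameter-recovery questions.  Initialization: x50 at the level nearest
proportion 0.5, s from a base-10 logit line; bounds s ∈ [0, 10] (10 per
magnitude unit is effectively a step function on a grid spaced 2 units
apart).  Fits with every level on one side of indifference, or with s at
its cap, are flagged `boundary`; slopes below 1e-6 are snapped to exactly
0 so degenerate flat fits are detectable.  The adaptation measure is the
symmetric contrast `(s_narrow − s_wide)/(s_narrow + s_wide)` (undefined
when both slopes are 0); the raw fits are also returned.

## Statistics

- **Mean-effect tests** — two-tailed one-sample t test plus a sign-flip
  permutation: each session's contrast has its sign flipped, exactly
  enumerated for n ≤ 20 (p = count(|perm sum| ≥ |observed|)/2^n) and
  Monte Carlo with the (b+1)/(n+1) correction otherwise.  Type-I error is
  calibration-tested at ~5%.
- **Model–behavior correspondence** — Pearson r with two-tailed p across
  sessions; a chi-square association between contrast signs is available.
- **Tau sweep** — re-simulates every session at each ratio
  (`DEFAULT_SWEEP_RATIOS` spans tau_S = 5–125 s at tau_F = 100 ms) and
  reports r(tau); per-session failures are logged as NaN, never fatal.
- **Shuffle controls** — the *magnitude shuffle* permutes trial content
  (offers, trial type, abort flag, recorded choice) across temporal
  slots while every slot keeps its onset, duration, ITI (time-outs
  included), and block label; the *ITI shuffle* permutes ITIs and
  recomputes onsets, keeping content order and total duration.  The null
  distribution of r over repeated shuffles gives a two-sided empirical
  p with the (b+1)/(n+1) correction; fewer than 100 repetitions warns.

All stochastic procedures take explicit seeds; the pipeline derives
per-stage substreams from one root seed and stamps outputs with a
configuration hash.

## Known limitations

- The model's per-session slope contrast is small (≈0.1–0.5% normalized
  at the default stated world), so cohorts of ~50 sessions are needed for
  the direction to reach significance; real behavioral contrasts are an
  order of magnitude larger.
- Binary sampling of choices from the model's probabilities makes fitted
  slopes noisy at realistic trial counts (sigmoid-fit boundary effects);
  timescale self-recovery is therefore demonstrated with Gaussian
  observation noise on the model's contrasts rather than Bernoulli
  resampling.
- The regression control over session covariates and the
  reinforcement-learning comparison model are out of scope, as are
  reaction times, lapse rates, and any electrophysiological claims.
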