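# normcascade

Cascaded multi-timescale divisive normalization: a firing-rate circuit
model of how the statistics of recently experienced rewards adapt the
neural coding of value — and with it, the stochasticity of choices.

**Who this is for.** Computational neuroscientists and decision
scientists studying context-dependent valuation: the package lets you
simulate the circuit on millisecond-resolution behavioral timelines,
generate synthetic two-alternative sessions with narrow/wide
reward-variance blocks, and run the full behavioral-adaptation analysis
(choice-curve fits, block contrasts, timescale sweeps, shuffle controls)
from Python.

## The model

Each choice option i has paired excitatory (R) and inhibitory (G) units
in a fast and a slow subcircuit; inhibition is divisive and pooled:

    tau_F dG_i^F/dt = -G_i^F + Σ_j ω_ij R_j^F + Σ_k α_ik R_k^S
    tau_F dR_i^F/dt = -R_i^F + V_i / (1 + G_i^F)
    tau_S dG_i^S/dt = -G_i^S + Σ_j β_ij R_j^S
    tau_S dR_i^S/dt = -R_i^S + V_i / (1 + G_i^S)

The fast circuit (tau_F ≈ 100 ms) produces within-trial value coding —
phasic transients, plateaus, cross-option normalization.  The slow
circuit (tau_S ≈ tens of seconds) integrates reward input over many
trials and feeds the fast gain pool, so reward history rescales the
fast value code.  Choices are read out from the fast-circuit rate
difference between the two offers; blocks of low reward variability
("narrow") produce steeper, less stochastic choice curves than
high-variability ("wide") blocks — an efficient-coding signature that
emerges from the dynamics alone, with the slow/fast time-constant ratio
as the model's only free balance.  Choice curves are the standard
sigmoid `y = 1/(1 + 10^((x50 − x)·s))`; the adaptation measure is the
normalized slope contrast `(s_narrow − s_wide)/(s_narrow + s_wide)`.

See `docs/methods.md` for assumptions, stated-world defaults, and
numerical choices.

## Worked example

```python
from normcascade import (GeneratorConfig, NetworkParams, generate_session,
                         model_block_fits, predict_choices, slope_difference)

session = generate_session(GeneratorConfig(seed=7))     # two-block task session
params = NetworkParams.from_ratio(600.0)                # tau_slow = 60 s
pred = predict_choices(session, params)                 # simulate + read out
fits = model_block_fits(pred)                           # sigmoid fit per block
for block, fit in fits.items():
    print(f"{block}: x50={fit.x50:.2f} slope={fit.s:.3f}")
print("slope difference:", slope_difference(fits["narrow"], fits["wide"]))
```

prints

```
narrow: x50=6.05 slope=0.343
wide: x50=6.05 slope=0.347
slope difference: -0.005200...
```

Both blocks are indifferent near the reference magnitude (x50 ≈ 6); this
particular session adapts slightly in the *opposite* direction
(narrow < wide), which is expected — the per-session effect is small and
scattered.  Across a cohort it is systematically positive
(`examples/04_adaptation_experiment.py`, 50 sessions):

```
mean +0.0017, positive in 36/50 sessions
t(49) = 2.875, p = 0.0060 (t test)
sign-flip permutation p = 0.0057 (monte-carlo, 10000 patterns)
```

The `examples/` directory has one short script per capability: circuit
dynamics and steady states (`01`), session generation (`02`), choice
curves (`03`), the multi-session adaptation test (`04`), and the
tau-ratio sweep plus magnitude/ITI shuffle controls (`05`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic cohort from scratch, runs the full pipeline
(simulate → read out → fit → contrast → aggregate tests → tau sweep →
magnitude-shuffle null), prints the recomputed statistics, and writes
the JSON report to `--out`.  All randomness derives from `--seed`.
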