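"""Trial-by-trial choice readout from fast-circuit activity.

The model's choice signal on a trial is the difference in fast-circuit
excitatory rates between the two displayed options, averaged over a late
window of the display period (the plateau of the phasic response).  Two
readouts are provided:

* ``choice`` - deterministic argmax of the window-averaged rates, with a
  documented tie rule;
* ``p_a`` - a probabilistic readout mapping the rate difference through a
  base-10 logistic whose noise scale is the pooled SD of the difference
  across the session's test trials.  Because the scale is common to both
  blocks, block differences in the size and variability of the rate
  difference translate into block differences in choice-curve slope,
  which is how adaptation of choice stochasticity is expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .network import IntegrationError, NetworkParams, NetworkState, Trajectory
from .task import Session, Trial, compile_value_timeline

__all__ = ["ReadoutConfig", "readout", "predict_choices"]


@dataclass
class ReadoutConfig:
    """How fast-circuit activity is converted to a choice.

    ``window`` holds (start, end) offsets in ms relative to display onset;
    ``None`` selects the final 200 ms of each trial's display period.
    ``prob_scale`` sets the logistic noise scale of the probabilistic
    readout: the string ``"pooled_sd"`` (default) uses the SD of the rate
    difference across the session's non-aborted test trials, a float fixes
    it in rate units.
    """

    window: tuple[float, float] | None = None
    rule: str = "argmax"
    tie_epsilon: float = 1e-12
    prob_scale: object = "pooled_sd"

    def __post_init__(self) -> None:
        if self.tie_epsilon < 0:
            raise ValueError("tie_epsilon must be nonnegative")
        if self.rule != "argmax":
            raise ValueError(f"unknown readout rule {self.rule!r}")

    def resolve_window(self, trial: Trial) -> tuple[float, float]:
        if self.window is None:
            lo, hi = trial.display_duration - 200.0, trial.display_duration
        else:
            lo, hi = self.window
        if not 0 <= lo < hi <= trial.display_duration + 1e-9:
            raise ValueError(
                f"readout window ({lo}, {hi}) outside display period of "
                f"trial {trial.index}"
            )
        return trial.display_on + lo, trial.display_on + hi


def _window_steps(t_lo: float, t_hi: float, dt: float, n_steps: int, trial: Trial):
    lo = int(math.ceil(t_lo / dt - 1e-9))
    hi = int(math.floor(t_hi / dt + 1e-9))
    if lo > hi or lo < 0 or hi > n_steps:
        raise ValueError(
            f"readout window of trial {trial.index} not covered by the "
            f"integration grid (steps {lo}..{hi} of {n_steps})"
        )
    return lo, hi


def readout(
    trajectory: Trajectory, trial: Trial, cfg: ReadoutConfig | None = None
) -> tuple[float, float]:
    """Mean fast-circuit rate of each option over the trial's window."""
    cfg = cfg or ReadoutConfig()
    t_lo, t_hi = cfg.resolve_window(trial)
    dt = trajectory.dt
    n_steps = trajectory.times.size - 1
    lo, hi = _window_steps(t_lo, t_hi, dt, n_steps, trial)
    window = trajectory.r_fast[lo : hi + 1]
    return float(window[:, 0].mean()), float(window[:, 1].mean())


def _argmax_choice(r_a: float, r_b: float, tie_epsilon: float) -> str:
    # ties broken toward option a (measure-zero under continuous dynamics)
    return "a" if r_a >= r_b - tie_epsilon else "b"


def predict_choices(
    session: Session,
    params: NetworkParams,
    cfg: ReadoutConfig | None = None,
    dt: float = 1.0,
    init: NetworkState | None = None,
    value_map=None,
) -> pd.DataFrame:
    """Simulate a session once and read out every non-aborted test trial.

    The network state evolves continuously across trials and blocks from
    an all-zero start.  Returns one row per non-aborted test trial with
    the window-averaged rates ``r_a``/``r_b``, their difference ``dr``,
    the deterministic argmax ``choice``, and the probabilistic readout
    ``p_a``.
    """
    cfg = cfg or ReadoutConfig()
    timeline = compile_value_timeline(session, value_map=value_map)
    n_steps = int(round(timeline.duration / dt))
    trials = [t for t in session.test_trials() if not t.aborted]
    lo = np.empty(len(trials), dtype=np.int64)
    hi = np.empty(len(trials), dtype=np.int64)
    for k, tr in enumerate(trials):
        t_lo, t_hi = cfg.resolve_window(tr)
        lo[k], hi[k] = _window_steps(t_lo, t_hi, dt, n_steps, tr)
    if init is None:
        init = NetworkState.zeros(params.n_options)
    means, _, fail = _kernels.integrate_windows(
        init.as_vector(),
        timeline.breaks,
        timeline.values,
        dt,
        n_steps,
        params.tau_fast,
        params.tau_slow,
        params.omega,
        params.alpha,
        params.beta,
        lo,
        hi,
    )
    if fail >= 0:
        bad = next(
            (t.index for t in session.trials if t.display_on <= fail * dt <= t.end),
            None,
        )
        raise IntegrationError(
            f"non-finite state at t={fail * dt:.6g} ms (trial {bad})"
        )
    r_a = means[:, 0]
    r_b = means[:, 1]
    dr = r_a - r_b
    if isinstance(cfg.prob_scale, str):
        if cfg.prob_scale != "pooled_sd":
            raise ValueError(f"unknown prob_scale {cfg.prob_scale!r}")
        scale = float(np.std(dr)) if dr.size else 0.0
    else:
        scale = float(cfg.prob_scale)
        if scale <= 0:
            raise ValueError("prob_scale must be positive")
    if scale > 0:
        p_a = 1.0 / (1.0 + 10.0 ** (-dr / scale))
    else:
        # degenerate session: fall back to the deterministic readout
        p_a = np.where(dr >= 0, 1.0, 0.0)
    return pd.DataFrame(
        {
            "trial": [t.index for t in trials],
            "block": [t.block for t in trials],
            "magnitude_a": [t.option_a.magnitude for t in trials],
            "magnitude_b": [t.option_b.magnitude for t in trials],
            "r_a": r_a,
            "r_b": r_b,
            "dr": dr,
            "choice": [
                _argmax_choice(a, b, cfg.tie_epsilon) for a, b in zip(r_a, r_b)
            ],
            "p_a": p_a,
        }
    )
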