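"""Cascaded multi-timescale divisive-normalization circuit.

The model represents each choice option with a paired excitatory
(value-coding, R) and inhibitory (gain-control, G) unit, duplicated across
a fast and a slow subcircuit.  Divisive normalization is implemented by
recurrent inhibition: each gain unit pools excitatory output and divides
its partner's value input.  The fast circuit additionally receives the
slow circuit's excitatory output in its gain pool, so reward history
integrated on the slow timescale modulates the instantaneous gain of value
coding.  With time constants ``tau_fast`` and ``tau_slow`` the dynamics
are

    tau_F dG_i^F/dt = -G_i^F + sum_j omega_ij R_j^F + sum_k alpha_ik R_k^S
    tau_F dR_i^F/dt = -R_i^F + V_i / (1 + G_i^F)
    tau_S dG_i^S/dt = -G_i^S + sum_j beta_ij R_j^S
    tau_S dR_i^S/dt = -R_i^S + V_i / (1 + G_i^S)

Setting ``alpha = 0`` decouples the fast circuit, recovering the classic
single-timescale dynamic normalization model.  Only the ratio
``tau_slow / tau_fast`` affects the trajectory up to a rescaling of time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from . import _kernels

__all__ = [
    "NetworkParams",
    "NetworkState",
    "ValueTimeline",
    "Trajectory",
    "IntegrationError",
    "SteadyStateError",
    "derivatives",
    "rk4_step",
    "simulate",
    "steady_state",
    "step_scenario",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


class SteadyStateError(RuntimeError):
    """Raised when the fixed-point solver fails to converge."""


def _as_weight(value, n: int, name: str) -> np.ndarray:
    if value is None:
        w = np.ones((n, n))
    elif np.isscalar(value):
        w = np.full((n, n), float(value))
    else:
        w = np.asarray(value, dtype=float)
    if w.shape != (n, n):
        raise ValueError(f"{name} must have shape ({n}, {n}), got {w.shape}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError(f"{name} entries must be finite and nonnegative")
    return w


@dataclass
class NetworkParams:
    """Weights and timescales of the cascaded circuit.

    Defaults follow the simplest form of the model: all-ones weights
    (global inhibition within each stage, no a-priori excitation/inhibition
    asymmetry), a fast time constant of 100 ms typical of intra-trial
    value-coding dynamics, and a slow time constant of 60 s (ratio 600)
    in the range that best tracks behavioral adaptation.
    """

    n_options: int = 2
    tau_fast: float = 100.0
    tau_slow: float = 60_000.0
    omega: np.ndarray | float | None = None
    alpha: np.ndarray | float | None = None
    beta: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        if self.n_options < 1:
            raise ValueError("n_options must be a positive integer")
        if not (self.tau_fast > 0 and self.tau_slow > 0):
            raise ValueError("time constants must be positive")
        self.omega = _as_weight(self.omega, self.n_options, "omega")
        self.alpha = _as_weight(self.alpha, self.n_options, "alpha")
        self.beta = _as_weight(self.beta, self.n_options, "beta")

    @property
    def tau_ratio(self) -> float:
        return self.tau_slow / self.tau_fast

    @classmethod
    def from_ratio(
        cls, ratio: float, tau_fast: float = 100.0, n_options: int = 2, **kw
    ) -> "NetworkParams":
        """Build parameters from the slow/fast time-constant ratio."""
        if ratio <= 0:
            raise ValueError("tau ratio must be positive")
        return cls(
            n_options=n_options, tau_fast=tau_fast, tau_slow=ratio * tau_fast, **kw
        )


@dataclass
class NetworkState:
    """Instantaneous activities of all excitatory/inhibitory units."""

    r_fast: np.ndarray
    g_fast: np.ndarray
    r_slow: np.ndarray
    g_slow: np.ndarray

    def __post_init__(self) -> None:
        self.r_fast = np.atleast_1d(np.asarray(self.r_fast, dtype=float))
        self.g_fast = np.atleast_1d(np.asarray(self.g_fast, dtype=float))
        self.r_slow = np.atleast_1d(np.asarray(self.r_slow, dtype=float))
        self.g_slow = np.atleast_1d(np.asarray(self.g_slow, dtype=float))
        n = self.r_fast.size
        for name in ("g_fast", "r_slow", "g_slow"):
            if getattr(self, name).size != n:
                raise ValueError("all state vectors must have equal length")

    @property
    def n(self) -> int:
        return self.r_fast.size

    @classmethod
    def zeros(cls, n: int) -> "NetworkState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.r_fast, self.g_fast, self.r_slow, self.g_slow])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "NetworkState":
        y = np.asarray(y, dtype=float)
        n = y.size // 4
        return cls(y[:n], y[n : 2 * n], y[2 * n : 3 * n], y[3 * n :])


class ValueTimeline:
    """Piecewise-constant map from time (ms) to the value-input vector.

    ``breaks`` are the S+1 segment boundaries starting at 0 and ending at
    the total duration; ``values`` is an (S, N) array of nonnegative value
    inputs, constant on the half-open interval [breaks[k], breaks[k+1]).
    """

    def __init__(self, breaks, values, n_options: int | None = None) -> None:
        self.breaks = np.atleast_1d(np.asarray(breaks, dtype=float))
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            # degenerate empty timeline (zero duration)
            if n_options is None:
                raise ValueError("empty timeline requires explicit n_options")
            self.values = np.zeros((0, n_options))
            if self.breaks.size != 1 or self.breaks[0] != 0.0:
                raise ValueError("empty timeline must have breaks == [0.0]")
            return
        self.values = np.atleast_2d(values)
        if self.breaks.ndim != 1 or self.breaks.size != self.values.shape[0] + 1:
            raise ValueError("breaks must have one more entry than value segments")
        if self.breaks[0] != 0.0:
            raise ValueError("timeline must start at t=0")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("segment boundaries must be strictly increasing")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("value inputs must be finite and nonnegative")

    @property
    def duration(self) -> float:
        return float(self.breaks[-1])

    @property
    def n_options(self) -> int:
        return self.values.shape[1]

    @classmethod
    def constant(cls, values, duration: float) -> "ValueTimeline":
        return cls([0.0, float(duration)], np.atleast_2d(values))

    @classmethod
    def from_segments(cls, segments, duration: float, n_options: int) -> "ValueTimeline":
        """Build from sorted, non-overlapping (start, end, vector) triples.

        Gaps between segments (and before/after) carry zero input.
        """
        breaks = [0.0]
        vals = []
        zero = np.zeros(n_options)
        t = 0.0
        for start, end, vec in segments:
            if start < t - 1e-9:
                raise ValueError("segments overlap or are unsorted")
            if end <= start:
                raise ValueError("segment end must exceed start")
            if start > t:
                vals.append(zero)
                breaks.append(float(start))
            vals.append(np.asarray(vec, dtype=float))
            breaks.append(float(end))
            t = float(end)
        if duration < t - 1e-9:
            raise ValueError("duration shorter than last segment")
        if duration > t:
            vals.append(zero)
            breaks.append(float(duration))
        if not vals:
            return cls([0.0], np.empty((0, n_options)), n_options=n_options)
        return cls(np.array(breaks), np.array(vals))

    def value_at(self, t: float) -> np.ndarray:
        if t < 0 or t > self.duration + 1e-9:
            raise ValueError(f"time {t} outside timeline [0, {self.duration}]")
        if self.values.shape[0] == 0:
            return np.zeros(self.n_options)
        idx = int(np.searchsorted(self.breaks, t, side="right")) - 1
        idx = min(max(idx, 0), self.values.shape[0] - 1)
        return self.values[idx]


@dataclass
class Trajectory:
    """Uniformly sampled network states along an integration run."""

    times: np.ndarray
    states: np.ndarray  # (T, 4N)
    n_options: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_options == 0:
            self.n_options = self.states.shape[1] // 4

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def r_fast(self) -> np.ndarray:
        return self.states[:, : self.n_options]

    @property
    def g_fast(self) -> np.ndarray:
        return self.states[:, self.n_options : 2 * self.n_options]

    @property
    def r_slow(self) -> np.ndarray:
        return self.states[:, 2 * self.n_options : 3 * self.n_options]

    @property
    def g_slow(self) -> np.ndarray:
        return self.states[:, 3 * self.n_options :]

    @property
    def final_state(self) -> NetworkState:
        return NetworkState.from_vector(self.states[-1])

    def to_frame(self):
        """Columnar export (time_ms, R_fast_i..., G_fast_i..., ...)."""
        import pandas as pd

        n = self.n_options
        cols = {"time_ms": self.times}
        for label, block in (
            ("R_fast", self.r_fast),
            ("G_fast", self.g_fast),
            ("R_slow", self.r_slow),
            ("G_slow", self.g_slow),
        ):
            for i in range(n):
                cols[f"{label}_{i}"] = block[:, i]
        return pd.DataFrame(cols)


def _check_values(values, n: int) -> np.ndarray:
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if v.size != n:
        raise ValueError(f"value vector must have length {n}, got {v.size}")
    if np.any(v < 0):
        raise ValueError("value inputs must be nonnegative")
    return v


def derivatives(
    state: NetworkState, values, params: NetworkParams
) -> NetworkState:
    """Tau-scaled right-hand sides of the cascaded system."""
    n = params.n_options
    if state.n != n:
        raise ValueError(f"state has {state.n} options, params expect {n}")
    v = _check_values(values, n)
    d_gf = (-state.g_fast + params.omega @ state.r_fast + params.alpha @ state.r_slow) / params.tau_fast
    d_rf = (-state.r_fast + v / (1.0 + state.g_fast)) / params.tau_fast
    d_gs = (-state.g_slow + params.beta @ state.r_slow) / params.tau_slow
    d_rs = (-state.r_slow + v / (1.0 + state.g_slow)) / params.tau_slow
    return NetworkState(d_rf, d_gf, d_rs, d_gs)


def rk4_step(
    state: NetworkState,
    t: float,
    dt: float,
    timeline: ValueTimeline,
    params: NetworkParams,
) -> NetworkState:
    """One classical RK4 step, holding the input sampled at the midpoint.

    The midpoint convention keeps fourth-order accuracy for piecewise-
    constant inputs whose breakpoints fall on the step grid.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = timeline.value_at(t + 0.5 * dt)
    y = state.as_vector()

    def f(yy):
        return derivatives(NetworkState.from_vector(yy), v, params).as_vector()

    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    y_new = y + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    if not np.all(np.isfinite(y_new)):
        raise IntegrationError(f"non-finite state after RK4 step at t={t}")
    return NetworkState.from_vector(y_new)


def _n_steps(duration: float, dt: float) -> int:
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-6 * max(1.0, duration):
        raise ValueError(f"dt={dt} does not divide timeline duration {duration}")
    return n_steps


def simulate(
    timeline: ValueTimeline,
    params: NetworkParams,
    dt: float = 1.0,
    init: NetworkState | None = None,
) -> Trajectory:
    """Integrate the network over a value timeline on a uniform grid."""
    if timeline.n_options != params.n_options:
        raise ValueError("timeline and params disagree on the number of options")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if init is None:
        init = NetworkState.zeros(params.n_options)
    n_steps = _n_steps(timeline.duration, dt)
    states, fail = _kernels.integrate_record(
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
    )
    if fail >= 0:
        raise IntegrationError(
            f"non-finite state at t={(fail + 1) * dt:.6g} ms (step {fail})"
        )
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times, states, params.n_options)


def steady_state(
    values,
    params: NetworkParams,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> NetworkState:
    """Fixed point of the cascaded system for a constant value input.

    The slow subsystem is autonomous, so its equilibrium
    ``R^S (1 + beta R^S) = V`` is solved first; the slow output then enters
    the fast gain equation ``R^F (1 + omega R^F + alpha R^S) = V`` as a
    constant.  Both stages use a root finder with damped fixed-point and
    long-integration fallbacks.
    """
    n = params.n_options
    v = _check_values(values, n)

    def solve_stage(w: np.ndarray, extra: np.ndarray) -> np.ndarray:
        # roots of r * (1 + w r + extra) - v = 0, r >= 0
        def fun(r):
            return r * (1.0 + w @ r + extra) - v

        r0 = v / (1.0 + extra + v.sum())
        sol = scipy.optimize.root(fun, r0, method="hybr", tol=tol)
        r = sol.x
        if not sol.success or np.any(r < -1e-9) or np.max(np.abs(fun(r))) > 1e-8:
            # damped fixed-point fallback
            r = r0.copy()
            for _ in range(max_iter):
                r_new = 0.5 * r + 0.5 * v / (1.0 + w @ r + extra)
                if np.max(np.abs(r_new - r)) < tol:
                    r = r_new
                    break
                r = r_new
            if np.max(np.abs(fun(r))) > 1e-7:
                return None
        return np.maximum(r, 0.0)

    r_slow = solve_stage(params.beta, np.zeros(n))
    r_fast = (
        None if r_slow is None else solve_stage(params.omega, params.alpha @ r_slow)
    )
    if r_slow is None or r_fast is None:
        # last resort: relax to the fixed point by long integration
        tl = ValueTimeline.constant(v, 60.0 * params.tau_slow)
        state = simulate(tl, params, dt=params.tau_fast / 20.0).final_state
        resid = np.max(np.abs(derivatives(state, v, params).as_vector()))
        if resid * params.tau_fast > 1e-6:
            raise SteadyStateError(
                f"steady state not found (long-integration residual {resid:.3g})"
            )
        return state
    g_slow = params.beta @ r_slow
    g_fast = params.omega @ r_fast + params.alpha @ r_slow
    return NetworkState(r_fast, g_fast, r_slow, g_slow)


def step_scenario(
    tau_ratio: float = 1000.0,
    v1_levels=(20.0, 40.0, 60.0),
    v2: float = 40.0,
    repeats: int = 2,
    trials_per_block: int = 50,
    on_duration: float = 3.0,
    off_duration: float = 4.0,
    tau_fast: float = 1.0,
) -> tuple[ValueTimeline, NetworkParams]:
    """Two-option block-step stimulation protocol.

    Option 1 steps through ``v1_levels`` across blocks (each level repeated
    ``repeats`` times) while option 2 is held constant; within each block,
    values are gated on for ``on_duration`` per trial and off between
    trials.  Time units are arbitrary with ``tau_fast = 1``; only the
    slow/fast ratio matters.  The default off period of several fast time
    constants mirrors the task's ITI (6-9 fast time constants) and lets
    the fast circuit discharge enough between trials to show a phasic
    transient on every trial.
    """
    params = NetworkParams(
        n_options=2, tau_fast=tau_fast, tau_slow=tau_ratio * tau_fast
    )
    segments = []
    t = 0.0
    period = on_duration + off_duration
    for _ in range(repeats):
        for v1 in v1_levels:
            for _ in range(trials_per_block):
                segments.append((t, t + on_duration, np.array([v1, v2])))
                t += period
    timeline = ValueTimeline.from_segments(segments, duration=t, n_options=2)
    return timeline, params
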