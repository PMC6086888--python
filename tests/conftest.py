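import numpy as np
import pytest

from normcascade import GeneratorConfig, NetworkParams, generate_session


@pytest.fixture
def params1():
    """Single-option circuit with all-ones weights."""
    return NetworkParams(n_options=1, tau_fast=1.0, tau_slow=1000.0)


@pytest.fixture
def params2():
    """Default two-option circuit (tau_fast 100 ms, ratio 600)."""
    return NetworkParams()


@pytest.fixture
def small_config():
    """Reduced session size for fast end-to-end tests."""
    return GeneratorConfig(trials_per_block=40, seed=11)


@pytest.fixture
def small_session(small_config):
    return generate_session(small_config)


def single_circuit_oracle(breaks, values, tau, dt, n_steps, omega, y0=None):
    """Independently coded integrator for the single-timescale circuit.

    Plain-numpy RK4 on dG/dt = (-G + omega R)/tau, dR/dt = (-R + V/(1+G))/tau
    with the input held at the step-midpoint value.  Used as the oracle for
    the alpha=0 reduction of the cascaded model.
    Returns (R trajectory, G trajectory), each (n_steps+1, N).
    """
    breaks = np.asarray(breaks, float)
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[1]
    r = np.zeros(n) if y0 is None else np.asarray(y0[0], float).copy()
    g = np.zeros(n) if y0 is None else np.asarray(y0[1], float).copy()
    rs = np.empty((n_steps + 1, n))
    gs = np.empty((n_steps + 1, n))
    rs[0], gs[0] = r, g

    def f(rr, gg, v):
        return (-rr + v / (1.0 + gg)) / tau, (-gg + omega @ rr) / tau

    for i in range(n_steps):
        tmid = (i + 0.5) * dt
        seg = min(np.searchsorted(breaks, tmid, side="right") - 1, values.shape[0] - 1)
        v = values[seg]
        kr1, kg1 = f(r, g, v)
        kr2, kg2 = f(r + 0.5 * dt * kr1, g + 0.5 * dt * kg1, v)
        kr3, kg3 = f(r + 0.5 * dt * kr2, g + 0.5 * dt * kg2, v)
        kr4, kg4 = f(r + dt * kr3, g + dt * kg3, v)
        r = r + dt * (kr1 + 2 * kr2 + 2 * kr3 + kr4) / 6.0
        g = g + dt * (kg1 + 2 * kg2 + 2 * kg3 + kg4) / 6.0
        rs[i + 1], gs[i + 1] = r, g
    return rs, gs
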