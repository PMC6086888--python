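"""Unit and property tests for the cascaded normalization circuit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import single_circuit_oracle

from normcascade import (
    IntegrationError,
    NetworkParams,
    NetworkState,
    ValueTimeline,
    derivatives,
    rk4_step,
    simulate,
    steady_state,
    step_scenario,
)

# closed-form single-option fixed point for V=20, all-ones weights:
# slow: R(1+R)=20 -> R=(-1+sqrt(81))/2 = 4;  fast: R(5+R)=20 -> (-5+sqrt(105))/2
R_SLOW_20 = 4.0
R_FAST_20 = (-5.0 + np.sqrt(105.0)) / 2.0


class TestDerivatives:
    def test_zero_fixed_point(self, params2):
        d = derivatives(NetworkState.zeros(2), [0.0, 0.0], params2)
        assert np.all(d.as_vector() == 0.0)

    def test_step_from_rest(self):
        p = NetworkParams(n_options=2, tau_fast=1.0, tau_slow=1000.0)
        d = derivatives(NetworkState.zeros(2), [20.0, 0.0], p)
        np.testing.assert_allclose(d.r_fast, [20.0, 0.0])
        np.testing.assert_allclose(d.g_fast, [0.0, 0.0])
        np.testing.assert_allclose(d.r_slow, [20.0 / 1000.0, 0.0])
        np.testing.assert_allclose(d.g_slow, [0.0, 0.0])

    def test_closed_form_fixed_point_has_zero_derivative(self, params1):
        state = NetworkState(
            r_fast=[R_FAST_20],
            g_fast=[R_FAST_20 + R_SLOW_20],
            r_slow=[R_SLOW_20],
            g_slow=[R_SLOW_20],
        )
        d = derivatives(state, [20.0], params1)
        assert np.max(np.abs(d.as_vector())) <= 1e-9

    def test_contract_violations(self, params2):
        with pytest.raises(ValueError):
            derivatives(NetworkState.zeros(3), [1.0, 1.0], params2)
        with pytest.raises(ValueError):
            derivatives(NetworkState.zeros(2), [1.0, -1.0], params2)


class TestSteadyState:
    def test_closed_form(self, params1):
        ss = steady_state([20.0], params1)
        assert abs(ss.r_slow[0] - R_SLOW_20) < 1e-9
        assert abs(ss.r_fast[0] - R_FAST_20) < 1e-9

    def test_zero_input(self, params2):
        ss = steady_state([0.0, 0.0], params2)
        assert np.all(ss.as_vector() == 0.0)

    def test_normalization_signs(self, params2):
        # R1_fast rises with own value, falls with the competitor's value
        base = steady_state([20.0, 20.0], params2).r_fast[0]
        up_own = steady_state([25.0, 20.0], params2).r_fast[0]
        up_other = steady_state([20.0, 25.0], params2).r_fast[0]
        assert up_own > base > up_other


class TestIntegration:
    def test_zero_input_stays_zero(self, params2):
        tl = ValueTimeline.constant([0.0, 0.0], 500.0)
        traj = simulate(tl, params2, dt=1.0)
        assert np.all(traj.states == 0.0)

    def test_simulate_matches_rk4_step(self, params2):
        tl = ValueTimeline.constant([20.0, 10.0], 50.0)
        traj = simulate(tl, params2, dt=1.0)
        state = NetworkState.zeros(2)
        for k in range(50):
            state = rk4_step(state, k * 1.0, 1.0, tl, params2)
        np.testing.assert_allclose(
            state.as_vector(), traj.states[-1], rtol=0, atol=1e-12
        )

    def test_richardson_error_halving(self):
        # constant input: halving dt shrinks global error ~16x (order 4)
        p = NetworkParams(n_options=2, tau_fast=1.0, tau_slow=10.0)
        tl = ValueTimeline.constant([20.0, 40.0], 8.0)
        dt_ref = 0.25 / 64
        ref = simulate(tl, p, dt=dt_ref).states
        errs = []
        for dt in (0.25, 0.125):
            traj = simulate(tl, p, dt=dt).states
            stride = int(round(dt / dt_ref))
            errs.append(np.max(np.abs(traj - ref[::stride])))
        assert 10.0 < errs[0] / errs[1] < 22.0

    def test_time_rescaling_invariance(self):
        # scaling (tau_F, tau_S, dt, timeline) by c reproduces the trajectory
        tl, p = step_scenario(tau_ratio=50.0, trials_per_block=3)
        traj = simulate(tl, p, dt=0.05)
        c = 7.0
        tl_c = ValueTimeline(tl.breaks * c, tl.values)
        p_c = NetworkParams(
            n_options=2, tau_fast=p.tau_fast * c, tau_slow=p.tau_slow * c
        )
        traj_c = simulate(tl_c, p_c, dt=0.05 * c)
        np.testing.assert_allclose(traj_c.states, traj.states, rtol=0, atol=1e-12)

    def test_long_constant_input_reaches_steady_state(self):
        p = NetworkParams(n_options=2, tau_fast=1.0, tau_slow=100.0)
        tl = ValueTimeline.constant([20.0, 30.0], 2000.0)
        traj = simulate(tl, p, dt=0.05)
        expect = steady_state([20.0, 30.0], p)
        np.testing.assert_allclose(
            traj.final_state.as_vector(), expect.as_vector(), atol=1e-6
        )

    def test_alpha_zero_reduces_to_single_circuit(self):
        oracle = single_circuit_oracle
        tl, p = step_scenario(tau_ratio=1000.0, trials_per_block=5)
        p0 = NetworkParams(
            n_options=2, tau_fast=p.tau_fast, tau_slow=p.tau_slow, alpha=0.0
        )
        dt = 0.05
        traj = simulate(tl, p0, dt=dt)
        n_steps = traj.times.size - 1
        r_ref, g_ref = oracle(tl.breaks, tl.values, p.tau_fast, dt, n_steps, p0.omega)
        assert np.max(np.abs(traj.r_fast - r_ref)) <= 1e-10
        assert np.max(np.abs(traj.g_fast - g_ref)) <= 1e-10

    def test_timescale_separation(self):
        # tau ratio 1000: slow activity barely moves within a trial
        tl, p = step_scenario(tau_ratio=1000.0)
        traj = simulate(tl, p, dt=0.05)
        per = 7.0
        steps = int(round(per / 0.05))
        on_steps = int(round(3.0 / 0.05))
        within = max(
            np.ptp(traj.r_slow[k * steps : k * steps + on_steps + 1, 0])
            for k in range(300)
        )
        session_range = np.ptp(traj.r_slow[:, 0])
        assert within < 0.05 * session_range

    def test_nonfinite_reported(self, params2):
        tl = ValueTimeline.constant([20.0, 10.0], 100.0)
        bad = NetworkState(
            [0.0, 0.0], [-1.0, 0.0], [0.0, 0.0], [0.0, 0.0]
        )  # G = -1 pole
        with pytest.raises(IntegrationError):
            simulate(tl, params2, dt=1.0, init=bad)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    v=st.lists(st.floats(0.0, 80.0), min_size=2, max_size=2),
    w=st.floats(0.0, 3.0),
    ratio=st.floats(1.0, 2000.0),
)
def test_nonnegativity_property(v, w, ratio):
    """Nonnegative inputs and weights keep every unit nonnegative."""
    p = NetworkParams(
        n_options=2, tau_fast=1.0, tau_slow=ratio, omega=w, alpha=w, beta=w
    )
    tl = ValueTimeline(
        [0.0, 5.0, 10.0, 20.0], [v, [0.0, 0.0], [v[1], v[0]]]
    )
    traj = simulate(tl, p, dt=0.05)
    assert traj.states.min() >= -1e-12


class TestValueTimeline:
    def test_lookup_and_bounds(self):
        tl = ValueTimeline([0.0, 10.0, 20.0], [[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(tl.value_at(0.0), [1.0, 2.0])
        np.testing.assert_allclose(tl.value_at(10.0), [3.0, 4.0])  # half-open
        np.testing.assert_allclose(tl.value_at(20.0), [3.0, 4.0])
        with pytest.raises(ValueError):
            tl.value_at(21.0)

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            ValueTimeline([0.0, 5.0, 5.0], [[1.0], [2.0]])
        with pytest.raises(ValueError):
            ValueTimeline([0.0, 5.0], [[-1.0]])
        with pytest.raises(ValueError):
            ValueTimeline.from_segments(
                [(0.0, 5.0, [1.0, 1.0]), (4.0, 8.0, [2.0, 2.0])], 8.0, 2
            )

    def test_gap_filling(self):
        tl = ValueTimeline.from_segments([(2.0, 4.0, [5.0, 6.0])], 10.0, 2)
        np.testing.assert_allclose(tl.value_at(1.0), [0.0, 0.0])
        np.testing.assert_allclose(tl.value_at(3.0), [5.0, 6.0])
        np.testing.assert_allclose(tl.value_at(9.0), [0.0, 0.0])
        assert tl.duration == 10.0
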