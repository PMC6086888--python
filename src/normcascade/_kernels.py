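"""Compiled Runge-Kutta integration kernels for the cascaded circuit.

The value input is piecewise constant; each RK4 step holds the input
sampled at the step midpoint, so steps that lie inside one segment see an
autonomous system and retain full fourth-order accuracy.  Segment
boundaries are expected to fall on the step grid (the task compiler emits
integer-millisecond events and the default step is 1 ms).

State layout is a flat vector of length 4N:
``[R_fast (N), G_fast (N), R_slow (N), G_slow (N)]``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True, inline="always", error_model="numpy")
def _deriv(y, v, tau_f, tau_s, omega, alpha, beta, out):
    n = v.shape[0]
    for i in range(n):
        s_om = 0.0
        s_al = 0.0
        s_be = 0.0
        for j in range(n):
            s_om += omega[i, j] * y[j]
            s_al += alpha[i, j] * y[2 * n + j]
            s_be += beta[i, j] * y[2 * n + j]
        out[i] = (-y[i] + v[i] / (1.0 + y[n + i])) / tau_f
        out[n + i] = (-y[n + i] + s_om + s_al) / tau_f
        out[2 * n + i] = (-y[2 * n + i] + v[i] / (1.0 + y[3 * n + i])) / tau_s
        out[3 * n + i] = (-y[3 * n + i] + s_be) / tau_s


@njit(cache=True, inline="always", error_model="numpy")
def _rk4_update(y, v, dt, tau_f, tau_s, omega, alpha, beta, k1, k2, k3, k4, yt):
    m = y.shape[0]
    _deriv(y, v, tau_f, tau_s, omega, alpha, beta, k1)
    for q in range(m):
        yt[q] = y[q] + 0.5 * dt * k1[q]
    _deriv(yt, v, tau_f, tau_s, omega, alpha, beta, k2)
    for q in range(m):
        yt[q] = y[q] + 0.5 * dt * k2[q]
    _deriv(yt, v, tau_f, tau_s, omega, alpha, beta, k3)
    for q in range(m):
        yt[q] = y[q] + dt * k3[q]
    _deriv(yt, v, tau_f, tau_s, omega, alpha, beta, k4)
    for q in range(m):
        y[q] = y[q] + dt * (k1[q] + 2.0 * k2[q] + 2.0 * k3[q] + k4[q]) / 6.0


@njit(cache=True, error_model="numpy")
def integrate_record(y0, breaks, values, dt, n_steps, tau_f, tau_s, omega, alpha, beta):
    """Integrate and record the state at every grid point.

    Returns ``(states, fail_step)`` where ``states`` has shape
    ``(n_steps + 1, 4N)`` and ``fail_step`` is -1 on success or the index
    of the first step that produced a non-finite state.
    """
    m = y0.shape[0]
    n = m // 4
    out = np.empty((n_steps + 1, m))
    y = y0.copy()
    k1 = np.empty(m)
    k2 = np.empty(m)
    k3 = np.empty(m)
    k4 = np.empty(m)
    yt = np.empty(m)
    n_seg = values.shape[0]
    seg = 0
    for q in range(m):
        out[0, q] = y[q]
    for i in range(n_steps):
        tmid = (i + 0.5) * dt
        while seg < n_seg - 1 and breaks[seg + 1] <= tmid:
            seg += 1
        v = values[seg]
        _rk4_update(y, v, dt, tau_f, tau_s, omega, alpha, beta, k1, k2, k3, k4, yt)
        ok = True
        for q in range(m):
            if not np.isfinite(y[q]):
                ok = False
            out[i + 1, q] = y[q]
        if not ok:
            return out, i
    return out, -1


@njit(cache=True, error_model="numpy")
def integrate_windows(
    y0, breaks, values, dt, n_steps, tau_f, tau_s, omega, alpha, beta, win_lo, win_hi
):
    """Integrate while accumulating mean fast-circuit rates over windows.

    ``win_lo``/``win_hi`` are inclusive step-index bounds of sorted,
    non-overlapping windows.  Returns ``(window_means, y_final, fail_step)``
    where ``window_means`` has shape ``(n_windows, N)`` holding the mean
    R_fast of each option over the grid points of each window.
    """
    m = y0.shape[0]
    n = m // 4
    n_win = win_lo.shape[0]
    sums = np.zeros((n_win, n))
    counts = np.zeros(n_win)
    y = y0.copy()
    k1 = np.empty(m)
    k2 = np.empty(m)
    k3 = np.empty(m)
    k4 = np.empty(m)
    yt = np.empty(m)
    n_seg = values.shape[0]
    seg = 0
    w = 0
    for i in range(n_steps + 1):
        while w < n_win and i > win_hi[w]:
            w += 1
        if w < n_win and win_lo[w] <= i <= win_hi[w]:
            for q in range(n):
                sums[w, q] += y[q]
            counts[w] += 1.0
        if i == n_steps:
            break
        tmid = (i + 0.5) * dt
        while seg < n_seg - 1 and breaks[seg + 1] <= tmid:
            seg += 1
        v = values[seg]
        _rk4_update(y, v, dt, tau_f, tau_s, omega, alpha, beta, k1, k2, k3, k4, yt)
        for q in range(m):
            if not np.isfinite(y[q]):
                return sums, y, i
    for w in range(n_win):
        if counts[w] > 0:
            for q in range(n):
                sums[w, q] /= counts[w]
    return sums, y, -1
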