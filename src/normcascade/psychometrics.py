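"""Sigmoid choice-curve fitting and block slope contrasts.

Choice data from test trials are summarized per block as the probability
of choosing the variable option as a function of its magnitude ``x`` and
fit with the standard sigmoid

    y(x) = 1 / (1 + 10 ** ((x50 - x) * s))

``x50`` is the indifference point and the slope ``s`` quantifies overall
choice stochasticity (steeper = less stochastic).  Fitting is least
squares on per-level choice proportions; a binomial maximum-likelihood
objective is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

__all__ = ["ChoiceCurveFit", "fit_choice_curve", "slope_difference", "sigmoid"]

S_MAX = 10.0  # per-magnitude-unit slope cap (effectively a step function)


def sigmoid(x, x50: float, s: float):
    """Standard base-10 choice sigmoid, y(x50) = 0.5 exactly."""
    return 1.0 / (1.0 + 10.0 ** ((x50 - np.asarray(x, dtype=float)) * s))


@dataclass
class ChoiceCurveFit:
    """Fitted sigmoid parameters for one block's test trials."""

    x50: float
    s: float
    rmse: float
    n_trials: int
    levels: np.ndarray = field(repr=False)
    proportions: np.ndarray = field(repr=False)
    boundary: bool = False

    def predict(self, x):
        return sigmoid(x, self.x50, self.s)


def _aggregate(magnitudes, outcomes):
    mags = np.asarray(magnitudes, dtype=float)
    outs = np.asarray(outcomes, dtype=float)
    if mags.size != outs.size or mags.size == 0:
        raise ValueError("need matched, non-empty magnitude/outcome arrays")
    if np.any((outs < 0) | (outs > 1)):
        raise ValueError("outcomes must lie in [0, 1]")
    levels = np.unique(mags)
    props = np.array([outs[mags == lv].mean() for lv in levels])
    counts = np.array([(mags == lv).sum() for lv in levels])
    return levels, props, counts


def fit_choice_curve(test_trials, method: str = "ls") -> ChoiceCurveFit:
    """Fit (x50, s) to (variable magnitude, chose-variable) pairs.

    ``test_trials`` is an iterable of ``(magnitude, outcome)`` pairs where
    the outcome is a 0/1 choice indicator or a choice probability.
    ``method`` selects least squares on per-level proportions (``"ls"``,
    default) or binomial maximum likelihood (``"mle"``, meaningful for
    binary outcomes).  Fits in which every level falls on one side of
    indifference, or the slope hits its cap, are flagged ``boundary``.
    """
    pairs = list(test_trials)
    mags = [p[0] for p in pairs]
    outs = [p[1] for p in pairs]
    levels, props, counts = _aggregate(mags, outs)
    if levels.size < 2:
        raise ValueError("need at least two distinct magnitudes to fit a curve")
    span = levels[-1] - levels[0]

    # init: x50 at the level nearest indifference, s from a logit line
    x0 = levels[int(np.argmin(np.abs(props - 0.5)))]
    z = np.log10(np.clip(props, 0.01, 0.99) / (1.0 - np.clip(props, 0.01, 0.99)))
    s0 = float(np.polyfit(levels, z, 1)[0]) if levels.size > 1 else 1.0
    s0 = min(max(s0, 1e-3), S_MAX)

    lo = (levels[0] - span, 0.0)
    hi = (levels[-1] + span, S_MAX)
    x0 = min(max(x0, lo[0]), hi[0])

    if method == "ls":
        def resid(theta):
            return sigmoid(levels, *theta) - props

        sol = scipy.optimize.least_squares(
            resid, (x0, s0), bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        x50, s = sol.x
    elif method == "mle":
        k = props * counts

        def nll(theta):
            p = np.clip(sigmoid(levels, *theta), 1e-12, 1 - 1e-12)
            return -np.sum(k * np.log(p) + (counts - k) * np.log(1 - p))

        sol = scipy.optimize.minimize(
            nll, (x0, s0), bounds=list(zip(lo, hi)), method="L-BFGS-B"
        )
        x50, s = sol.x
    else:
        raise ValueError(f"unknown fitting method {method!r}")

    if s < 1e-6:  # numerically flat curve: report exactly zero slope
        s = 0.0
    pred = sigmoid(levels, x50, s)
    rmse = float(np.sqrt(np.mean((pred - props) ** 2)))
    one_sided = bool(np.all(props > 0.5) or np.all(props < 0.5))
    boundary = one_sided or s >= S_MAX - 1e-9
    return ChoiceCurveFit(
        x50=float(x50),
        s=float(s),
        rmse=rmse,
        n_trials=len(pairs),
        levels=levels,
        proportions=props,
        boundary=boundary,
    )


def slope_difference(narrow: ChoiceCurveFit, wide: ChoiceCurveFit) -> float:
    """Normalized narrow-minus-wide slope contrast, (s_n - s_w)/(s_n + s_w).

    Positive values mean sharper (less stochastic) choices in the narrow
    block.  Undefined when both slopes are zero.
    """
    total = narrow.s + wide.s
    if total <= 0:
        raise ValueError("slope contrast undefined: s_narrow + s_wide <= 0")
    return (narrow.s - wide.s) / total
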