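"""Session-level and aggregate adaptation statistics.

Quantifies the adaptation of choice stochasticity: per-session normalized
slope differences (narrow - wide) for model and behavior, one-sample
mean-effect tests (t test plus sign-flip permutation), Pearson
model-behavior correlation, a sweep of the slow/fast time-constant ratio,
and magnitude/ITI shuffle controls with permutation null distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.stats

from .choice import ReadoutConfig, predict_choices
from .network import NetworkParams
from .psychometrics import ChoiceCurveFit, fit_choice_curve, slope_difference
from .task import Session, Trial

__all__ = [
    "DEFAULT_SWEEP_RATIOS",
    "model_block_fits",
    "behavior_block_fits",
    "model_slope_difference",
    "behavior_slope_difference",
    "mean_effect_tests",
    "correlate_model_behavior",
    "sign_agreement",
    "tau_sweep",
    "magnitude_shuffle",
    "iti_shuffle",
    "shuffle_null",
]


# default sweep grid: slow time constants of 5-125 s at tau_fast = 100 ms,
# spanning about one trial up to many tens of trials of reward history
DEFAULT_SWEEP_RATIOS = (50.0, 100.0, 200.0, 400.0, 600.0, 750.0, 1000.0, 1250.0)


# ---------------------------------------------------------------------------
# per-session slope contrasts

def model_block_fits(
    predictions: pd.DataFrame, use_probability: bool = True
) -> dict[str, ChoiceCurveFit]:
    """Fit one choice curve per block from a model prediction table.

    With ``use_probability`` (default) the probabilistic readout ``p_a``
    is used as a graded chose-variable outcome; otherwise the binary
    argmax choices are used.
    """
    fits = {}
    for block, grp in predictions.groupby("block"):
        x = grp["magnitude_b"].to_numpy()
        if use_probability:
            y = 1.0 - grp["p_a"].to_numpy()
        else:
            y = (grp["choice"] == "b").to_numpy(dtype=float)
        fits[block] = fit_choice_curve(zip(x, y))
    return fits


def behavior_block_fits(
    session: Session, method: str = "ls"
) -> dict[str, ChoiceCurveFit]:
    """Fit per-block choice curves from recorded (or simulated) choices."""
    fits = {}
    for block in session.block_order:
        pairs = [
            (t.option_b.magnitude, 1.0 if t.choice == "b" else 0.0)
            for t in session.test_trials(block)
            if not t.aborted and t.choice != "none"
        ]
        if pairs:
            fits[block] = fit_choice_curve(pairs, method=method)
    return fits


def _narrow_wide_diff(fits: dict[str, ChoiceCurveFit]) -> float:
    if "narrow" not in fits or "wide" not in fits:
        raise ValueError("need fits for both a narrow and a wide block")
    try:
        return slope_difference(fits["narrow"], fits["wide"])
    except ValueError:
        return float("nan")


def model_slope_difference(
    session: Session,
    params: NetworkParams,
    cfg: ReadoutConfig | None = None,
    dt: float = 1.0,
    use_probability: bool = True,
) -> float:
    """Simulate a session and return the model's normalized slope contrast."""
    pred = predict_choices(session, params, cfg=cfg, dt=dt)
    return _narrow_wide_diff(model_block_fits(pred, use_probability=use_probability))


def behavior_slope_difference(session: Session) -> float:
    return _narrow_wide_diff(behavior_block_fits(session))


# ---------------------------------------------------------------------------
# aggregate tests

def _enumerate_signflip_p(diffs: np.ndarray) -> tuple[float, int]:
    """Exact two-sided sign-flip p by enumerating all 2^n sign patterns."""
    n = diffs.size
    sums = np.zeros(1)
    for d in diffs:
        sums = np.concatenate([sums - d, sums + d])
    obs = abs(diffs.sum())
    count = int(np.sum(np.abs(sums) >= obs - 1e-12))
    return count / sums.size, sums.size


def mean_effect_tests(
    slope_diffs, n_reps: int = 10_000, seed: int = 0
) -> dict[str, float]:
    """One-sample tests of the mean slope difference against zero.

    Returns the two-tailed t test (``t``, ``df``, ``p_t``) and a sign-flip
    permutation p (``p_perm``): each session's difference has its sign
    flipped independently, exactly enumerated for n <= 20 and Monte Carlo
    with a (b+1)/(n+1) correction otherwise.
    """
    diffs = np.asarray(slope_diffs, dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    n = diffs.size
    if n < 3:
        raise ValueError("need at least 3 sessions for a mean-effect test")
    if np.allclose(diffs, diffs[0]):
        # degenerate constant input: t is 0/0 for all-zero, +/-inf otherwise
        t_stat = 0.0 if diffs[0] == 0 else float(np.inf * np.sign(diffs[0]))
        p_t = 1.0 if diffs[0] == 0 else 0.0
    else:
        t_res = scipy.stats.ttest_1samp(diffs, 0.0)
        t_stat, p_t = float(t_res.statistic), float(t_res.pvalue)
    if n <= 20:
        p_perm, n_used = _enumerate_signflip_p(diffs)
        scheme = "exact"
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_reps, n))
        perm = np.abs(signs @ diffs)
        b = int(np.sum(perm >= abs(diffs.sum()) - 1e-12))
        p_perm = (b + 1) / (n_reps + 1)
        n_used = n_reps
        scheme = "monte-carlo"
    return {
        "t": t_stat,
        "df": n - 1,
        "p_t": p_t,
        "p_perm": float(p_perm),
        "n_perm": n_used,
        "scheme": scheme,
        "mean": float(diffs.mean()),
        "n": n,
    }


def correlate_model_behavior(model_diffs, behavior_diffs) -> dict[str, float]:
    """Pearson correlation (two-tailed) between per-session contrasts."""
    m = np.asarray(model_diffs, dtype=float)
    b = np.asarray(behavior_diffs, dtype=float)
    if m.size != b.size:
        raise ValueError("model and behavior arrays must be aligned")
    keep = np.isfinite(m) & np.isfinite(b)
    m, b = m[keep], b[keep]
    if m.size < 3:
        raise ValueError("need at least 3 sessions to correlate")
    if np.std(m) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance in a contrast vector")
    r, p = scipy.stats.pearsonr(m, b)
    return {"r": float(r), "p": float(p), "n": int(m.size)}


def sign_agreement(model_diffs, behavior_diffs) -> dict[str, float]:
    """Chi-square association between the signs of the two contrasts."""
    m = np.sign(np.asarray(model_diffs, dtype=float))
    b = np.sign(np.asarray(behavior_diffs, dtype=float))
    keep = (m != 0) & (b != 0) & np.isfinite(m) & np.isfinite(b)
    m, b = m[keep], b[keep]
    table = np.array(
        [
            [np.sum((m > 0) & (b > 0)), np.sum((m > 0) & (b < 0))],
            [np.sum((m < 0) & (b > 0)), np.sum((m < 0) & (b < 0))],
        ]
    )
    chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "table": table}


# ---------------------------------------------------------------------------
# tau-ratio sweep

def tau_sweep(
    sessions,
    behavior_diffs,
    ratios,
    tau_fast: float = 100.0,
    cfg: ReadoutConfig | None = None,
    dt: float = 1.0,
    use_probability: bool = True,
) -> pd.DataFrame:
    """Correlation between model and behavior contrasts at each tau ratio.

    For every ratio, every session is re-simulated with
    ``tau_slow = ratio * tau_fast``, block choice curves are re-fit, and
    the per-session model contrasts are correlated with the fixed behavior
    contrasts.  Per-session failures are recorded as NaN and logged, not
    fatal.
    """
    behavior_diffs = np.asarray(behavior_diffs, dtype=float)
    rows = []
    for ratio in ratios:
        params = NetworkParams.from_ratio(ratio, tau_fast=tau_fast)
        diffs = np.full(len(sessions), np.nan)
        for k, sess in enumerate(sessions):
            try:
                diffs[k] = model_slope_difference(
                    sess, params, cfg=cfg, dt=dt, use_probability=use_probability
                )
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                warnings.warn(f"session {k} failed at tau ratio {ratio}: {exc}")
        res = correlate_model_behavior(diffs, behavior_diffs)
        rows.append(
            {
                "tau_ratio": float(ratio),
                "tau_slow_ms": float(ratio * tau_fast),
                "r": res["r"],
                "p": res["p"],
                "n_sessions": res["n"],
                "mean_model_diff": float(np.nanmean(diffs)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shuffle controls

_CONTENT_FIELDS = ("trial_type", "option_a", "option_b", "aborted", "choice")


def magnitude_shuffle(session: Session, seed: int = 0, perm=None) -> Session:
    """Permute trial content across temporal slots, keeping all timing.

    The k-th temporal slot keeps its display onset, display duration, ITI
    (including any time-out), and block label; the sequence of offers
    (with their trial type, abort flag, and recorded choice) is permuted
    uniformly across the whole session.  ``perm`` overrides the random
    permutation with an explicit slot -> source index array.
    """
    if perm is None:
        perm = np.random.default_rng(seed).permutation(len(session.trials))
    new_trials = []
    for slot, src in zip(session.trials, (session.trials[p] for p in perm)):
        new_trials.append(
            replace(slot, **{f: getattr(src, f) for f in _CONTENT_FIELDS})
        )
    return Session(new_trials, dict(session.metadata))


def iti_shuffle(session: Session, seed: int = 0, perm=None) -> Session:
    """Permute ITIs across trials, keeping the trial content sequence.

    Display onsets are recomputed cumulatively, so total session duration
    is preserved (the ITI multiset, including post-abort time-outs, is
    unchanged).  ``perm`` overrides the random permutation.
    """
    if perm is None:
        perm = np.random.default_rng(seed).permutation(len(session.trials))
    itis = [session.trials[p].iti_after for p in perm]
    new_trials: list[Trial] = []
    t = session.trials[0].display_on if session.trials else 0.0
    for tr, iti in zip(session.trials, itis):
        new_trials.append(replace(tr, display_on=t, iti_after=iti))
        t += tr.display_duration + iti
    return Session(new_trials, dict(session.metadata))


_SHUFFLES = {"magnitude": magnitude_shuffle, "iti": iti_shuffle}


def shuffle_null(
    sessions,
    behavior_diffs,
    kind: str,
    n_reps: int = 1000,
    params: NetworkParams | None = None,
    cfg: ReadoutConfig | None = None,
    dt: float = 1.0,
    seed: int = 0,
    use_probability: bool = True,
) -> dict:
    """Null distribution of the model-behavior correlation under shuffles.

    Each repetition shuffles every session (magnitude or ITI permutation),
    recomputes model slope contrasts, and correlates them with the fixed
    behavior contrasts.  The two-sided empirical p uses the (b+1)/(n+1)
    correction: the fraction of |null r| >= |observed r|.
    """
    if kind not in _SHUFFLES:
        raise ValueError(f"unknown shuffle kind {kind!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be a positive integer")
    if n_reps < 100:
        warnings.warn("fewer than 100 permutations: reported p is coarse")
    params = params or NetworkParams()
    shuffle = _SHUFFLES[kind]
    behavior_diffs = np.asarray(behavior_diffs, dtype=float)

    def safe_diff(sess) -> float:
        # degenerate blocks (e.g. < 2 test-magnitude levels after a
        # shuffle of a small session) yield NaN and are dropped pairwise
        try:
            return model_slope_difference(
                sess, params, cfg=cfg, dt=dt, use_probability=use_probability
            )
        except ValueError:
            return float("nan")

    observed = np.array([safe_diff(s) for s in sessions])
    r_obs = correlate_model_behavior(observed, behavior_diffs)["r"]

    root = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for rep in range(n_reps):
        diffs = np.array(
            [
                safe_diff(shuffle(sess, seed=int(root.integers(2**31))))
                for sess in sessions
            ]
        )
        null[rep] = correlate_model_behavior(diffs, behavior_diffs)["r"]
    b = int(np.sum(np.abs(null) >= abs(r_obs)))
    return {
        "kind": kind,
        "r_observed": float(r_obs),
        "null": null,
        "p": (b + 1) / (n_reps + 1),
        "n_reps": n_reps,
        "seed": seed,
        "model_diffs_observed": observed,
    }
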