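"""Aggregate adaptation statistics, shuffles, and permutation machinery."""

import dataclasses
import warnings

import numpy as np
import pytest

from normcascade import (
    GeneratorConfig,
    NetworkParams,
    correlate_model_behavior,
    generate_session,
    iti_shuffle,
    magnitude_shuffle,
    mean_effect_tests,
    model_slope_difference,
    shuffle_null,
    sign_agreement,
    tau_sweep,
)

TINY = GeneratorConfig(trials_per_block=25, seed=31)
FAST_PARAMS = NetworkParams.from_ratio(300.0)


@pytest.fixture(scope="module")
def tiny_sessions():
    return [
        generate_session(dataclasses.replace(TINY, seed=100 + k)) for k in range(4)
    ]


class TestMeanEffect:
    def test_all_zero_diffs(self):
        res = mean_effect_tests([0.0] * 8)
        assert res["t"] == 0.0
        assert res["p_t"] == 1.0
        assert res["p_perm"] == 1.0

    def test_constant_positive_diffs_exact_enumeration(self):
        # only the all-plus and all-minus sign patterns reach |sum| = 10c
        res = mean_effect_tests([0.3] * 10)
        assert res["scheme"] == "exact"
        assert res["p_perm"] == pytest.approx(2 * 2**-10)

    def test_monte_carlo_branch(self):
        rng = np.random.default_rng(1)
        res = mean_effect_tests(rng.normal(0.2, 1.0, 40), n_reps=2000, seed=2)
        assert res["scheme"] == "monte-carlo"
        assert 0.0 < res["p_perm"] <= 1.0

    def test_too_few_sessions(self):
        with pytest.raises(ValueError):
            mean_effect_tests([0.1, 0.2])

    def test_type_one_error_calibration(self):
        # under a mean-zero null the permutation test rejects at ~alpha
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            res = mean_effect_tests(rng.normal(0.0, 1.0, 12))
            rejections += res["p_perm"] < 0.05
        rate = rejections / n_rep
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < ci + 0.005


class TestCorrelation:
    def test_identical_vectors(self):
        x = [0.1, -0.2, 0.3, 0.05]
        assert correlate_model_behavior(x, x)["r"] == pytest.approx(1.0)
        assert correlate_model_behavior(x, [-v for v in x])["r"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_model_behavior([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_attenuation_by_independent_noise(self):
        # behavior = model + noise at SNR 1: E[r] ~ 1/sqrt(2)
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(500):
            m = rng.normal(0.0, 1.0, 40)
            b = m + rng.normal(0.0, 1.0, 40)
            rs.append(correlate_model_behavior(m, b)["r"])
        assert abs(np.mean(rs) - 1 / np.sqrt(2)) < 0.03

    def test_sign_agreement_detects_concordance(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0.0, 1.0, 60)
        res = sign_agreement(m, m + rng.normal(0.0, 0.3, 60))
        assert res["chi2"] > 10
        assert res["p"] < 0.01


class TestShuffles:
    def test_identity_permutations_are_noops(self, tiny_sessions):
        sess = tiny_sessions[0]
        ident = np.arange(len(sess.trials))
        assert magnitude_shuffle(sess, perm=ident).trials == sess.trials
        assert iti_shuffle(sess, perm=ident).trials == sess.trials

    def test_magnitude_shuffle_invariants(self, tiny_sessions):
        sess = tiny_sessions[1]
        shuf = magnitude_shuffle(sess, seed=7)
        shuf.validate()
        content = lambda s: sorted(
            (t.option_a, t.option_b, t.trial_type, t.aborted) for t in s.trials
        )
        assert content(shuf) == content(sess)
        for a, b in zip(sess.trials, shuf.trials):
            assert (a.display_on, a.display_duration, a.iti_after, a.block) == (
                b.display_on,
                b.display_duration,
                b.iti_after,
                b.block,
            )
        assert shuf.duration == sess.duration

    def test_iti_shuffle_invariants(self, tiny_sessions):
        sess = tiny_sessions[2]
        shuf = iti_shuffle(sess, seed=8)
        shuf.validate()
        for a, b in zip(sess.trials, shuf.trials):
            assert (a.option_a, a.option_b, a.trial_type, a.block) == (
                b.option_a,
                b.option_b,
                b.trial_type,
                b.block,
            )
        assert sorted(t.iti_after for t in shuf.trials) == sorted(
            t.iti_after for t in sess.trials
        )
        assert shuf.duration == pytest.approx(sess.duration)

    def test_shuffled_sessions_compile_to_same_on_time(self, tiny_sessions):
        from normcascade import compile_value_timeline

        sess = tiny_sessions[3]
        for shuf in (magnitude_shuffle(sess, seed=9), iti_shuffle(sess, seed=9)):
            tl = compile_value_timeline(shuf)
            tl0 = compile_value_timeline(sess)
            on = lambda t: sum(
                hi - lo
                for lo, hi, v in zip(t.breaks[:-1], t.breaks[1:], t.values)
                if v.any()
            )
            assert on(tl) == pytest.approx(on(tl0))


class TestShuffleNull:
    def test_zero_reps_rejected(self, tiny_sessions):
        with pytest.raises(ValueError):
            shuffle_null(tiny_sessions, [0.1, 0.2, -0.1, 0.3], "magnitude", n_reps=0)

    def test_unknown_kind_rejected(self, tiny_sessions):
        with pytest.raises(ValueError):
            shuffle_null(tiny_sessions, [0.1, 0.2, -0.1, 0.3], "block", n_reps=10)

    def test_seeded_run_reproducible_and_warns_when_small(self, tiny_sessions):
        behavior = [0.1, -0.2, 0.15, 0.05]
        kw = dict(
            kind="magnitude", n_reps=4, params=FAST_PARAMS, dt=4.0, seed=13
        )
        with pytest.warns(UserWarning, match="fewer than 100"):
            a = shuffle_null(tiny_sessions, behavior, **kw)
        with pytest.warns(UserWarning, match="fewer than 100"):
            b = shuffle_null(tiny_sessions, behavior, **kw)
        np.testing.assert_array_equal(a["null"], b["null"])
        assert a["p"] == b["p"]
        assert a["null"].size == 4


class TestTauSweep:
    def test_single_ratio_matches_direct_call(self, tiny_sessions):
        behavior = [0.1, -0.2, 0.15, 0.05]
        sweep = tau_sweep(tiny_sessions, behavior, [300.0], dt=4.0)
        diffs = [
            model_slope_difference(s, FAST_PARAMS, dt=4.0) for s in tiny_sessions
        ]
        direct = correlate_model_behavior(diffs, behavior)
        assert sweep.loc[0, "r"] == pytest.approx(direct["r"])
        assert sweep.loc[0, "p"] == pytest.approx(direct["p"])

    def test_duplicate_ratios_identical(self, tiny_sessions):
        behavior = [0.1, -0.2, 0.15, 0.05]
        sweep = tau_sweep(tiny_sessions, behavior, [200.0, 200.0], dt=4.0)
        assert sweep.iloc[0].equals(sweep.iloc[1])
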