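"""Multi-session adaptation analysis: block contrasts and aggregate tests.

Simulates a cohort of sessions, computes each session's normalized
narrow-wide slope difference for the model, and tests whether the mean
contrast is positive (choice curves sharper after low reward variability)
with a one-sample t test and an exact sign-flip permutation test.
"""

import numpy as np

from normcascade import (
    GeneratorConfig,
    NetworkParams,
    generate_session,
    mean_effect_tests,
    model_slope_difference,
)

N_SESSIONS = 50
params = NetworkParams.from_ratio(600.0)

diffs = []
for k in range(N_SESSIONS):
    session = generate_session(GeneratorConfig(seed=1000 + k))
    diffs.append(model_slope_difference(session, params))
diffs = np.array(diffs)

print("first 10 per-session model slope differences (narrow - wide):")
print("  " + "  ".join(f"{d:+.4f}" for d in diffs[:10]))
res = mean_effect_tests(diffs)
print(f"mean {res['mean']:+.4f}, positive in {np.sum(diffs > 0)}/{N_SESSIONS} sessions")
print(f"t({res['df']}) = {res['t']:.3f}, p = {res['p_t']:.4f} (t test)")
print(f"sign-flip permutation p = {res['p_perm']:.4f} ({res['scheme']}, "
      f"{res['n_perm']} patterns)")
print("the per-session effect is small (~0.1-0.5% normalized), so a cohort of")
print("dozens of sessions is needed before the narrow > wide direction is")
print("statistically unambiguous")
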