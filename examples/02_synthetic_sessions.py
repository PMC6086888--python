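"""Generate a synthetic behavioral session and inspect its structure.

One session holds two blocks of 289 trials (~60% adapter / 40% test).
Adapter offers are drawn from a block-specific discretized Gaussian with a
common mean but narrow vs wide SD; test trials pair a fixed reference
against one of five variable magnitudes and are identical across blocks.
"""

import numpy as np

from normcascade import GeneratorConfig, generate_session, write_session

config = GeneratorConfig(seed=42)
session = generate_session(config)
print(f"trials: {len(session)}  blocks: {session.block_order}  "
      f"duration: {session.duration / 60000:.1f} min")

for block in session.block_order:
    adapters = [t for t in session.trials if t.block == block and t.trial_type == "adapter"]
    mags = np.array([m for t in adapters for m in (t.option_a.magnitude, t.option_b.magnitude)])
    tests = session.test_trials(block)
    print(f"{block:>6} block: {len(adapters)} adapter trials, "
          f"offer mean {mags.mean():.2f}, SD {mags.std():.2f}; "
          f"{len(tests)} test trials")

aborted = sum(t.aborted for t in session.trials)
print(f"aborted trials: {aborted} ({aborted / len(session):.0%}), "
      f"each adding a {config.timeout_ms:.0f} ms time-out to its ITI")

write_session(session, "scratch_session.csv")
print("written to scratch_session.csv (CSV round-trips via read_session)")
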