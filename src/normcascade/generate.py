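"""Synthetic two-alternative sessions with narrow/wide adapter blocks.

No behavioral dataset accompanies the model, so this module emulates the
task's statistical structure: each session holds one narrow and one wide
block (order randomized), 60% adapter trials whose two offers are drawn
i.i.d. from a block-specific discretized Gaussian (common mean, different
SD), and 40% test trials pairing a fixed reference reward against one of
five variable magnitudes.  ITIs are jittered uniformly on 600-900 ms and
aborted trials append a time-out to their ITI.

A logistic stand-in chooser converts magnitude differences into stochastic
choices so the model-vs-behavior pipeline can be exercised end to end
without animal data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .task import Option, Session, Trial

__all__ = ["GeneratorConfig", "generate_session", "synthetic_chooser"]


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic task.

    Magnitudes are in arbitrary reward units on an integer grid (the task
    displays discrete reward quantities).  Narrow and wide blocks share
    the adapter mean and differ only in SD.
    """

    trials_per_block: int = 289
    adapter_fraction: float = 0.60
    test_magnitudes: tuple = (2.0, 4.0, 6.0, 8.0, 10.0)
    reference_magnitude: float = 6.0
    reference_juice: str = "A"
    variable_juice: str = "B"
    adapter_mean: float = 6.0
    adapter_sd_narrow: float = 1.0
    adapter_sd_wide: float = 3.0
    magnitude_grid: tuple = tuple(float(m) for m in range(1, 13))
    iti_range_ms: tuple = (600.0, 900.0)
    display_duration_ms: float = 2100.0
    abort_rate: float = 0.15
    timeout_ms: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.test_magnitudes or not self.magnitude_grid:
            raise ValueError("magnitude lists must be non-empty")
        if len(self.test_magnitudes) != 5:
            raise ValueError("the task uses exactly five variable test magnitudes")
        if not 0.0 <= self.adapter_fraction <= 1.0:
            raise ValueError("adapter_fraction must be a probability")
        if not 0.0 <= self.abort_rate < 1.0:
            raise ValueError("abort_rate must be a probability below 1")
        if not self.adapter_sd_narrow < self.adapter_sd_wide:
            raise ValueError("narrow adapter SD must be below wide adapter SD")
        if min(self.magnitude_grid) <= 0 or min(self.test_magnitudes) <= 0:
            raise ValueError("magnitudes must be positive")
        if self.reference_magnitude <= 0:
            raise ValueError("reference magnitude must be positive")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be positive")
        if self.timeout_ms < 0 or self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ValueError("invalid timing configuration")

    def to_dict(self) -> dict:
        # JSON-normalized (tuples become lists) so session metadata
        # round-trips losslessly through the file formats
        return json.loads(json.dumps(asdict(self)))


def _adapter_probs(config: GeneratorConfig, sd: float) -> np.ndarray:
    # truncated discrete Gaussian over the allowed magnitude grid
    grid = np.asarray(config.magnitude_grid, dtype=float)
    logp = -0.5 * ((grid - config.adapter_mean) / sd) ** 2
    p = np.exp(logp - logp.max())
    return p / p.sum()


def generate_session(config: GeneratorConfig) -> Session:
    """Generate one two-block session, fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    blocks = ["narrow", "wide"]
    if rng.random() < 0.5:
        blocks.reverse()
    grid = np.asarray(config.magnitude_grid, dtype=float)
    trials: list[Trial] = []
    t = 0.0
    index = 0
    for block in blocks:
        sd = config.adapter_sd_narrow if block == "narrow" else config.adapter_sd_wide
        probs = _adapter_probs(config, sd)
        for _ in range(config.trials_per_block):
            is_adapter = rng.random() < config.adapter_fraction
            if is_adapter:
                mags = rng.choice(grid, size=2, p=probs)
                opt_a = Option(config.variable_juice, float(mags[0]))
                opt_b = Option(config.variable_juice, float(mags[1]))
                trial_type = "adapter"
            else:
                mag_b = float(rng.choice(np.asarray(config.test_magnitudes)))
                opt_a = Option(config.reference_juice, config.reference_magnitude)
                opt_b = Option(config.variable_juice, mag_b)
                trial_type = "test"
            aborted = bool(rng.random() < config.abort_rate)
            iti = float(rng.integers(int(config.iti_range_ms[0]), int(config.iti_range_ms[1]) + 1))
            if aborted:
                iti += config.timeout_ms
            trials.append(
                Trial(
                    index=index,
                    trial_type=trial_type,
                    block=block,
                    option_a=opt_a,
                    option_b=opt_b,
                    display_on=t,
                    display_duration=config.display_duration_ms,
                    iti_after=iti,
                    aborted=aborted,
                    choice="none",
                )
            )
            t += config.display_duration_ms + iti
            index += 1
    session = Session(
        trials,
        metadata={
            "generator": config.to_dict(),
            "seed": config.seed,
            "block_order": blocks,
        },
    )
    session.validate()
    return session


def synthetic_chooser(
    session: Session,
    sensitivity: float,
    bias: float = 0.0,
    seed: int = 0,
) -> dict[int, str]:
    """Stochastic logistic chooser standing in for animal behavior.

    Option a is chosen with probability
    ``1 / (1 + 10 ** ((bias - dmag) * sensitivity))`` where
    ``dmag = magnitude_a - magnitude_b``.  Returns a choice ('a'/'b') per
    non-aborted trial keyed by trial index; apply with
    :meth:`Session.with_choices`.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    rng = np.random.default_rng(seed)
    choices: dict[int, str] = {}
    for tr in session.trials:
        if tr.aborted:
            continue
        dmag = tr.option_a.magnitude - tr.option_b.magnitude
        with np.errstate(over="ignore"):
            p_a = float(1.0 / (1.0 + np.float64(10.0) ** ((bias - dmag) * sensitivity)))
        choices[tr.index] = "a" if rng.random() < p_a else "b"
    return choices
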