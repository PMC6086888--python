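"""End-to-end analysis runs: generate/load -> simulate -> fit -> contrast.

`run_pipeline` ties the modules together for reproducible multi-session
experiments.  All randomness flows from one root seed through named
substreams, every output is stamped with a hash of the configuration, and
the result bundle is serializable to CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice import ReadoutConfig
from .generate import GeneratorConfig, generate_session, synthetic_chooser
from .network import NetworkParams
from .stats import (
    behavior_slope_difference,
    correlate_model_behavior,
    mean_effect_tests,
    model_slope_difference,
    shuffle_null,
    tau_sweep,
)
from .task import read_session

__all__ = ["RunConfig", "run_pipeline", "load_config"]

# fixed substream ids so stages draw independent, reproducible randomness
_STREAMS = {"sessions": 1, "chooser": 2, "permutation": 3, "shuffle": 4}


def _substream(seed: int, name: str) -> int:
    return int(
        np.random.SeedSequence([seed, _STREAMS[name]]).generate_state(1)[0] % (2**31)
    )


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    seed: int = 0
    n_sessions: int = 8
    dt: float = 1.0
    session_paths: list[str] | None = None
    generator: GeneratorConfig | None = None
    network: NetworkParams = field(default_factory=NetworkParams)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    chooser_sensitivity: float = 0.35
    chooser_bias: float = 0.0
    use_probability: bool = True
    sweep_ratios: list[float] | None = None
    shuffle_kind: str | None = None
    shuffle_reps: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if isinstance(raw.get("generator"), dict):
            raw["generator"] = GeneratorConfig(**raw["generator"])
        if isinstance(raw.get("network"), dict):
            raw["network"] = NetworkParams(**raw["network"])
        if isinstance(raw.get("readout"), dict):
            rd = dict(raw["readout"])
            if isinstance(rd.get("window"), list):
                rd["window"] = tuple(rd["window"])
            raw["readout"] = ReadoutConfig(**rd)
        return cls(**raw)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file; unknown keys rejected."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw or {})


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run and return the result bundle.

    Stages: obtain sessions (load from ``session_paths`` or generate
    ``n_sessions`` synthetic ones), attach synthetic behavior where
    sessions carry no choices, simulate the network and fit per-block
    choice curves, contrast narrow vs wide slopes for model and behavior,
    run the aggregate tests, and optionally a tau sweep and a shuffle
    null.  Writes CSV/JSON artifacts when ``out_dir`` is set.
    """
    stage = "setup"
    try:
        if config.session_paths:
            stage = "load-sessions"
            sessions = [read_session(p) for p in config.session_paths]
        elif config.generator is not None:
            stage = "generate-sessions"
            base = config.generator
            seed0 = _substream(config.seed, "sessions")
            sessions = [
                generate_session(dataclasses.replace(base, seed=seed0 + k))
                for k in range(config.n_sessions)
            ]
        else:
            raise ValueError("config provides neither session_paths nor a generator")

        stage = "behavior"
        chooser_seed = _substream(config.seed, "chooser")
        for k, sess in enumerate(sessions):
            if all(t.choice == "none" for t in sess.trials):
                choices = synthetic_chooser(
                    sess,
                    sensitivity=config.chooser_sensitivity,
                    bias=config.chooser_bias,
                    seed=chooser_seed + k,
                )
                sessions[k] = sess.with_choices(choices)

        stage = "simulate-and-fit"
        rows = []
        for k, sess in enumerate(sessions):
            rows.append(
                {
                    "session": k,
                    "model_diff": model_slope_difference(
                        sess,
                        config.network,
                        cfg=config.readout,
                        dt=config.dt,
                        use_probability=config.use_probability,
                    ),
                    "behavior_diff": behavior_slope_difference(sess),
                    "n_trials": len(sess),
                }
            )
        table = pd.DataFrame(rows)

        stage = "aggregate-tests"
        summary = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "n_sessions": len(sessions),
            "model": mean_effect_tests(
                table["model_diff"], seed=_substream(config.seed, "permutation")
            ),
            "behavior": mean_effect_tests(
                table["behavior_diff"], seed=_substream(config.seed, "permutation")
            ),
            "correlation": correlate_model_behavior(
                table["model_diff"], table["behavior_diff"]
            ),
        }

        bundle = {"sessions": sessions, "per_session": table, "summary": summary}

        if config.sweep_ratios:
            stage = "tau-sweep"
            bundle["sweep"] = tau_sweep(
                sessions,
                table["behavior_diff"].to_numpy(),
                config.sweep_ratios,
                tau_fast=config.network.tau_fast,
                cfg=config.readout,
                dt=config.dt,
                use_probability=config.use_probability,
            )
        if config.shuffle_kind and config.shuffle_reps:
            stage = "shuffle-null"
            bundle["shuffle"] = shuffle_null(
                sessions,
                table["behavior_diff"].to_numpy(),
                kind=config.shuffle_kind,
                n_reps=config.shuffle_reps,
                params=config.network,
                cfg=config.readout,
                dt=config.dt,
                seed=_substream(config.seed, "shuffle"),
                use_probability=config.use_probability,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        table.to_csv(os.path.join(config.out_dir, "per_session.csv"), index=False)
        if "sweep" in bundle:
            bundle["sweep"].to_csv(
                os.path.join(config.out_dir, "tau_sweep.csv"), index=False
            )
        summary_out = json.loads(json.dumps(summary, default=float))
        if "shuffle" in bundle:
            sh = bundle["shuffle"]
            summary_out["shuffle"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in sh.items()
            }
        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(summary_out, fh, indent=1, default=float)
    return bundle
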