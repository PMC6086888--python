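"""Behavioral-session data model and the session -> value-timeline compiler.

A session is an ordered list of two-option choice trials.  Each trial
displays a pair of juice offers for a fixed window; the value input to the
network is gated on during the display and off during inter-trial
intervals (ITIs), which include any post-abort time-outs.  Sessions carry
two contiguous blocks labelled ``narrow``/``wide`` according to the
variability of their adapter-trial reward distribution.

Sessions round-trip through CSV (one row per trial, ``#``-comment header
with a schema version) and an equivalent JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import ValueTimeline

__all__ = [
    "Option",
    "Trial",
    "Session",
    "SessionError",
    "compile_value_timeline",
    "read_session",
    "write_session",
]

SCHEMA_VERSION = 1
TRIAL_TYPES = ("test", "adapter")
BLOCKS = ("narrow", "wide")
CHOICES = ("a", "b", "none")

_CSV_COLUMNS = [
    "index",
    "trial_type",
    "block",
    "juice_a",
    "magnitude_a",
    "juice_b",
    "magnitude_b",
    "display_on",
    "display_duration",
    "iti_after",
    "aborted",
    "choice",
]


class SessionError(ValueError):
    """Schema or consistency violation in a session record."""


@dataclass(frozen=True, order=True)
class Option:
    juice: str
    magnitude: float


@dataclass(frozen=True)
class Trial:
    index: int
    trial_type: str
    block: str
    option_a: Option
    option_b: Option
    display_on: float
    display_duration: float
    iti_after: float
    aborted: bool = False
    choice: str = "none"

    @property
    def display_off(self) -> float:
        return self.display_on + self.display_duration

    @property
    def end(self) -> float:
        return self.display_off + self.iti_after


@dataclass
class Session:
    trials: list[Trial]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = list(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def block_order(self) -> tuple[str, ...]:
        order: list[str] = []
        for tr in self.trials:
            if not order or order[-1] != tr.block:
                order.append(tr.block)
        return tuple(order)

    @property
    def duration(self) -> float:
        return self.trials[-1].end if self.trials else 0.0

    def test_trials(self, block: str | None = None) -> list[Trial]:
        out = [t for t in self.trials if t.trial_type == "test"]
        if block is not None:
            out = [t for t in out if t.block == block]
        return out

    def validate(self) -> None:
        """Check ordering, ranges, labels, and block structure."""
        for k, tr in enumerate(self.trials):
            where = f"trial {tr.index}"
            if tr.trial_type not in TRIAL_TYPES:
                raise SessionError(f"{where}: unknown trial_type {tr.trial_type!r}")
            if tr.block not in BLOCKS:
                raise SessionError(f"{where}: unknown block label {tr.block!r}")
            if tr.choice not in CHOICES:
                raise SessionError(f"{where}: unknown choice {tr.choice!r}")
            if tr.option_a.magnitude <= 0 or tr.option_b.magnitude <= 0:
                raise SessionError(f"{where}: magnitudes must be positive")
            if tr.display_duration <= 0:
                raise SessionError(f"{where}: display_duration must be positive")
            if tr.iti_after < 0:
                raise SessionError(f"{where}: negative iti_after")
            if tr.aborted and tr.choice != "none":
                raise SessionError(f"{where}: aborted trial cannot carry a choice")
            if k > 0:
                prev = self.trials[k - 1]
                if tr.display_on < prev.end - 1e-9:
                    raise SessionError(
                        f"{where}: overlaps previous trial {prev.index} "
                        f"(starts {tr.display_on} < {prev.end})"
                    )
        # block labels must form contiguous runs (at most one per label)
        order = self.block_order
        if len(order) != len(set(order)):
            raise SessionError(f"block labels are not contiguous: order {order}")
        # test trials share a fixed reference option_a
        refs = {(t.option_a.juice, t.option_a.magnitude) for t in self.test_trials()}
        if len(refs) > 1:
            raise SessionError(
                f"test trials must share one reference option, found {sorted(refs)}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "index": tr.index,
                "trial_type": tr.trial_type,
                "block": tr.block,
                "juice_a": tr.option_a.juice,
                "magnitude_a": tr.option_a.magnitude,
                "juice_b": tr.option_b.juice,
                "magnitude_b": tr.option_b.magnitude,
                "display_on": tr.display_on,
                "display_duration": tr.display_duration,
                "iti_after": tr.iti_after,
                "aborted": tr.aborted,
                "choice": tr.choice,
            }
            for tr in self.trials
        ]
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def with_choices(self, choices: dict[int, str]) -> "Session":
        """Return a copy with per-trial choices filled in (by trial index)."""
        new_trials = []
        for tr in self.trials:
            if tr.index in choices:
                if tr.aborted:
                    raise SessionError(f"trial {tr.index}: cannot assign choice to abort")
                new_trials.append(replace(tr, choice=choices[tr.index]))
            else:
                new_trials.append(tr)
        return Session(new_trials, dict(self.metadata))


def compile_value_timeline(session: Session, value_map=None) -> ValueTimeline:
    """Compile a session into the two-option value-input timeline.

    ``value_map`` converts reward magnitude to model value input (identity
    by default); values are on during each trial's display window and zero
    otherwise.  The timeline covers the last trial plus its ITI.
    """
    session.validate()
    if value_map is None:
        value_map = lambda m: m  # noqa: E731 - identity magnitude->value map
    segments = []
    for tr in session.trials:
        va = float(value_map(tr.option_a.magnitude))
        vb = float(value_map(tr.option_b.magnitude))
        if va < 0 or vb < 0:
            raise SessionError(f"trial {tr.index}: value_map produced negative value")
        segments.append((tr.display_on, tr.display_off, np.array([va, vb])))
    return ValueTimeline.from_segments(segments, duration=session.duration, n_options=2)


def _trial_from_record(rec: dict, where: str) -> Trial:
    try:
        aborted = rec["aborted"]
        if isinstance(aborted, str):
            aborted = aborted.strip().lower() in ("true", "1", "yes")
        return Trial(
            index=int(rec["index"]),
            trial_type=str(rec["trial_type"]),
            block=str(rec["block"]),
            option_a=Option(str(rec["juice_a"]), float(rec["magnitude_a"])),
            option_b=Option(str(rec["juice_b"]), float(rec["magnitude_b"])),
            display_on=float(rec["display_on"]),
            display_duration=float(rec["display_duration"]),
            iti_after=float(rec["iti_after"]),
            aborted=bool(aborted),
            choice=str(rec.get("choice", "none")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SessionError(f"{where}: malformed trial record ({exc})") from exc


def write_session(session: Session, path) -> None:
    """Write a session as CSV (or JSON if the path ends in .json)."""
    path = str(path)
    if path.endswith(".json"):
        doc = {
            "schema_version": SCHEMA_VERSION,
            "metadata": session.metadata,
            "trials": session.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return
    with open(path, "w") as fh:
        fh.write(f"# normcascade-session v{SCHEMA_VERSION}\n")
        if session.metadata:
            fh.write(f"# metadata: {json.dumps(session.metadata, sort_keys=True)}\n")
        session.to_frame().to_csv(fh, index=False)


def read_session(path) -> Session:
    """Read and validate a session file written by :func:`write_session`."""
    path = str(path)
    metadata: dict = {}
    if path.endswith(".json"):
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise SessionError(
                f"{path}: unsupported schema_version {doc.get('schema_version')!r}"
            )
        metadata = doc.get("metadata", {})
        records = doc.get("trials", [])
    else:
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith(f"# normcascade-session v{SCHEMA_VERSION}"):
                raise SessionError(f"{path}: missing or unsupported schema header")
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("# metadata:"):
                metadata = json.loads(line.split(":", 1)[1])
            else:
                fh.seek(pos)
            frame = pd.read_csv(fh)
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise SessionError(f"{path}: missing columns {missing}")
        records = frame.to_dict(orient="records")
    trials = [
        _trial_from_record(rec, f"{path}: record {k}") for k, rec in enumerate(records)
    ]
    session = Session(trials, metadata)
    session.validate()
    return session
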