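"""Session tables for pulsatile-evidence decision tasks.

A session is an ordered list of trials. Each trial carries the two click
trains (times in seconds from stimulus onset), the stimulus duration, the
subject's choice and outcome, an optional reaction time, and a violation
flag (fixation broken: no choice, no outcome). Violation trials are kept
in the table so that trial ordering is preserved; downstream analyses skip
them but thread history state around them.

On-disk format is a plain CSV/TSV with one row per trial and click trains
encoded as semicolon-delimited second offsets (e.g. ``"0.012;0.104"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "SessionTable",
    "SessionRejection",
    "read_session_table",
    "write_session_table",
    "apply_session_filters",
]

Choice = Literal["L", "R", "none"]
Outcome = Literal["win", "loss", "none"]
TaskMode = Literal["fixed_duration", "reaction_time"]

#: hard ceiling on plausible reaction times, seconds
MAX_RT = 60.0

COLUMNS = [
    "session_id",
    "trial_index",
    "duration_s",
    "left_clicks",
    "right_clicks",
    "choice",
    "outcome",
    "rt_s",
    "violation",
]


class ValidationError(ValueError):
    """A trial or table violates a structural invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    Click times are seconds from stimulus onset, ascending, within
    ``[0, duration]``. ``violation`` is true iff no choice/outcome was
    recorded.
    """

    trial_index: int
    left_clicks: tuple[float, ...]
    right_clicks: tuple[float, ...]
    duration: float
    choice: Choice
    outcome: Outcome
    rt: float | None = None
    violation: bool = False
    session_id: str = "session0"

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValidationError(f"trial_index must be >= 1, got {self.trial_index}")
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        for name, clicks in (("left", self.left_clicks), ("right", self.right_clicks)):
            arr = np.asarray(clicks, dtype=float)
            # 2e-6 slack: serialized click times are rounded to microseconds
            if arr.size and (np.any(np.diff(arr) < 0) or arr.min() < 0 or arr.max() > self.duration + 2e-6):
                raise ValidationError(
                    f"trial {self.trial_index}: {name} clicks must be ascending within [0, duration]"
                )
        no_choice = self.choice == "none"
        no_outcome = self.outcome == "none"
        if not (self.violation == no_choice == no_outcome):
            raise ValidationError(
                f"trial {self.trial_index}: violation={self.violation} requires "
                "choice and outcome to both be 'none' (and vice versa)"
            )
        if self.rt is not None and not (0 < self.rt <= MAX_RT):
            raise ValidationError(f"trial {self.trial_index}: rt must be in (0, {MAX_RT}]")

    @property
    def click_difference(self) -> int:
        """Signed click count difference, #right − #left."""
        return len(self.right_clicks) - len(self.left_clicks)

    @property
    def history_pair(self) -> str:
        """Choice-outcome label Rw/Lw/Rl/Ll, or 'none' on violations."""
        if self.violation:
            return "none"
        return self.choice + ("w" if self.outcome == "win" else "l")


@dataclass(frozen=True)
class SessionTable:
    """Ordered collection of trials from a single session."""

    trials: tuple[TrialRecord, ...]
    task_mode: TaskMode = "fixed_duration"

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("trial_index must be strictly increasing")
        sids = {t.session_id for t in self.trials}
        if len(sids) > 1:
            raise ValidationError(f"multiple session ids in one table: {sorted(sids)}")
        if self.task_mode == "reaction_time":
            missing = [t.trial_index for t in self.trials if not t.violation and t.rt is None]
            if missing:
                raise ValidationError(f"reaction_time table missing rt on trials {missing[:5]}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def session_id(self) -> str:
        return self.trials[0].session_id if self.trials else "session0"

    def non_violation(self) -> "SessionTable":
        return SessionTable(tuple(t for t in self.trials if not t.violation), self.task_mode)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "session_id": t.session_id,
                    "trial_index": t.trial_index,
                    # fixed microsecond precision so write∘read round-trips exactly
                    "duration_s": f"{t.duration:.6f}",
                    "left_clicks": ";".join(f"{c:.6f}" for c in t.left_clicks),
                    "right_clicks": ";".join(f"{c:.6f}" for c in t.right_clicks),
                    "choice": "NA" if t.choice == "none" else t.choice,
                    "outcome": "NA" if t.outcome == "none" else t.outcome,
                    "rt_s": "NA" if t.rt is None else f"{t.rt:.6f}",
                    "violation": int(t.violation),
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS)


@dataclass(frozen=True)
class SessionRejection:
    """Marker returned when a session fails quality control."""

    session_id: str
    reason: str
    detail: str = ""


def _parse_clicks(cell: object, row: int, col: str) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    s = str(cell).strip()
    if not s or s.upper() == "NA":
        return ()
    try:
        return tuple(float(x) for x in s.split(";") if x.strip())
    except ValueError as e:
        raise ValidationError(f"row {row}: cannot parse {col} {s!r}") from e


def read_session_table(path: str | Path, task_mode: TaskMode = "fixed_duration") -> SessionTable:
    """Read a session CSV/TSV (delimiter sniffed from the extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"session_id": str, "choice": str, "outcome": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    trials = []
    for i, row in df.iterrows():
        choice = str(row["choice"]).strip()
        outcome = str(row["outcome"]).strip()
        rt = row["rt_s"]
        try:
            trials.append(
                TrialRecord(
                    trial_index=int(row["trial_index"]),
                    left_clicks=_parse_clicks(row["left_clicks"], i, "left_clicks"),
                    right_clicks=_parse_clicks(row["right_clicks"], i, "right_clicks"),
                    duration=float(row["duration_s"]),
                    choice="none" if choice in {"NA", "nan", ""} else choice,  # type: ignore[arg-type]
                    outcome="none" if outcome in {"NA", "nan", ""} else outcome,  # type: ignore[arg-type]
                    rt=None if pd.isna(rt) else float(rt),
                    violation=bool(int(row["violation"])),
                    session_id=str(row["session_id"]),
                )
            )
        except (ValueError, TypeError) as e:
            if isinstance(e, ValidationError):
                raise
            raise ValidationError(f"{path}: malformed row {i}: {e}") from e
    return SessionTable(tuple(trials), task_mode)


def write_session_table(table: SessionTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.to_frame().to_csv(path, sep=sep, index=False)


def per_side_accuracy(table: SessionTable) -> dict[str, float]:
    """Fraction correct among non-violation trials whose correct answer is
    that side (correct side inferred from choice+outcome)."""
    n = {"L": 0, "R": 0}
    hits = {"L": 0, "R": 0}
    for t in table:
        if t.violation:
            continue
        correct_side = t.choice if t.outcome == "win" else ("L" if t.choice == "R" else "R")
        n[correct_side] += 1
        hits[correct_side] += t.outcome == "win"
    return {s: (hits[s] / n[s] if n[s] else np.nan) for s in ("L", "R")}


def apply_session_filters(
    table: SessionTable,
    min_trials: int = 300,
    min_side_accuracy: float = 0.60,
    omit_first: int | None = None,
) -> SessionTable | SessionRejection:
    """Session-level quality control.

    Sessions with fewer than ``min_trials`` trials or below
    ``min_side_accuracy`` accuracy for either correct side are rejected.
    The first ``omit_first`` trials (default 50 for the reaction-time task,
    0 for fixed duration) are dropped from retained sessions. Idempotent:
    trials already dropped are identified by ``trial_index``.
    """
    if omit_first is None:
        omit_first = 50 if table.task_mode == "reaction_time" else 0
    kept = tuple(t for t in table.trials if t.trial_index > omit_first)
    trimmed = SessionTable(kept, table.task_mode)
    if len(trimmed) < min_trials:
        return SessionRejection(table.session_id, "min_trials", f"{len(trimmed)} < {min_trials}")
    acc = per_side_accuracy(trimmed)
    for side in ("L", "R"):
        if np.isnan(acc[side]) or acc[side] < min_side_accuracy:
            return SessionRejection(
                table.session_id, "min_side_accuracy", f"{side}: {acc[side]:.3f} < {min_side_accuracy}"
            )
    return trimmed
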