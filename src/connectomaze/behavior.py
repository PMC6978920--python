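"""Behavioral statistics from T-maze trial logs.

A session log is an ordered list of attempted trials.  Object-choice trials
carry the chosen side (left/right food well) and correctness; failures to
alternate turn direction are recorded as working-memory errors (WMEs), which
carry no object choice and are not logged as trials.  The response-bias
index of a session is |L - R| / T over object-choice trials: 1 when every
choice was on one side, 0 when the sides were chosen equally often.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["TrialRecord", "TrialLog", "SessionSummary",
           "response_bias", "session_performance", "mean_bias"]


class UndefinedBiasError(ValueError):
    """No object-choice trials: the bias index has an empty denominator."""


@dataclass(frozen=True)
class TrialRecord:
    """One attempted trial.

    ``kind`` is ``object_choice`` or ``wme``.  WME records carry no side or
    correctness (enforced).
    """

    day: int
    kind: str
    turn: str  # "left" | "right"
    side: Optional[str] = None     # "left_well" | "right_well"
    correct: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.kind not in ("object_choice", "wme"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.turn not in ("left", "right"):
            raise ValueError(f"unknown turn direction {self.turn!r}")
        if self.kind == "wme":
            if self.side is not None or self.correct is not None:
                raise ValueError("WME records carry no object choice")
        else:
            if self.side not in ("left_well", "right_well"):
                raise ValueError("object_choice records need a chosen side")
            if self.correct is None:
                raise ValueError("object_choice records need a correct flag")


class TrialLog:
    """Time-ordered attempted-trial records for one rat."""

    def __init__(self, records: Iterable[TrialRecord]):
        self.records = list(records)
        days = [r.day for r in self.records]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("day indices must be non-decreasing")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def days(self) -> list[int]:
        return sorted({r.day for r in self.records})

    def day_records(self, day: int) -> list[TrialRecord]:
        return [r for r in self.records if r.day == day]


@dataclass
class SessionSummary:
    """Per-day accounting: object-choice trial count, accuracy, WMEs, bias."""

    day: int
    n_trials: int
    percent_correct: float
    n_wme: int
    response_bias: float


def response_bias(log: TrialLog, day: int) -> float:
    """|L - R| / T over the day's object-choice trials.

    WMEs are excluded from the denominator (they are not logged as trials).
    Raises :class:`UndefinedBiasError` when the day has no object choices.
    """
    choices = [r for r in log.day_records(day) if r.kind == "object_choice"]
    if not choices:
        raise UndefinedBiasError(f"no object-choice trials on day {day}")
    left = sum(1 for r in choices if r.side == "left_well")
    right = len(choices) - left
    return abs(left - right) / len(choices)


def session_performance(log: TrialLog, day: int) -> SessionSummary:
    """Percent correct (object choices only), WME count and bias for a day."""
    records = log.day_records(day)
    if not records:
        raise ValueError(f"log does not cover day {day}")
    choices = [r for r in records if r.kind == "object_choice"]
    n_wme = sum(1 for r in records if r.kind == "wme")
    if not choices:
        raise UndefinedBiasError(f"no object-choice trials on day {day}")
    pct = 100.0 * sum(1 for r in choices if r.correct) / len(choices)
    return SessionSummary(
        day=day,
        n_trials=len(choices),
        percent_correct=pct,
        n_wme=n_wme,
        response_bias=response_bias(log, day),
    )


def mean_bias(log: TrialLog, days: Sequence[int] | None = None) -> float:
    """Mean of daily response-bias values over a day set (default all days).

    This is the multi-day aggregate used when relating behavior to scans
    (e.g. bias on the days adjacent to a scanning session)."""
    days = list(days) if days is not None else log.days
    if not days:
        raise UndefinedBiasError("empty day set")
    return float(np.mean([response_bias(log, d) for d in days]))
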