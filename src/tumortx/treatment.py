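"""Dosing schedules, pulse-decay dose rates and the TVRR endpoint."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ANTI_PD1",
    "ANTI_TNF",
    "DoseEvent",
    "Schedule",
    "dose_rate",
    "build_mouse_schedule",
    "build_human_schedule",
    "tvrr",
]

ANTI_PD1 = "anti-PD-1"
ANTI_TNF = "anti-TNF-a"
_DRUGS = (ANTI_PD1, ANTI_TNF)

#: default dose pulse decay constant (1/day)
DEFAULT_BETA = 1.55
#: length of one human treatment cycle (days)
CYCLE_DAYS = 21


@dataclass(frozen=True)
class DoseEvent:
    drug: str
    day: float
    gamma: float  # pulse amplitude, g/cm^3/day

    def __post_init__(self) -> None:
        if self.drug not in _DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.day < 0:
            raise ValueError(f"injection day must be nonnegative, got {self.day}")
        if self.gamma < 0:
            raise ValueError(f"dose amplitude must be nonnegative, got {self.gamma}")


@dataclass(frozen=True)
class Schedule:
    """A list of dose events plus the shared pulse decay and end time.

    Each injection at day ``t_i`` contributes a source
    ``gamma * exp(-beta (t - t_i))`` for ``t > t_i`` (strictly after the
    injection instant).
    """

    events: tuple[DoseEvent, ...] = ()
    beta: float = DEFAULT_BETA
    t_end: float = 30.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.t_end <= 0:
            raise ValueError(f"end time must be positive, got {self.t_end}")
        events = tuple(sorted(self.events, key=lambda e: e.day))
        object.__setattr__(self, "events", events)
        if events and events[-1].day >= self.t_end:
            raise ValueError("all injections must precede the end time")

    def days(self, drug: str) -> np.ndarray:
        return np.array([e.day for e in self.events if e.drug == drug])

    def amplitudes(self, drug: str) -> np.ndarray:
        return np.array([e.gamma for e in self.events if e.drug == drug])

    @classmethod
    def control(cls, t_end: float = 30.0) -> "Schedule":
        """The no-drug schedule."""
        return cls(events=(), t_end=t_end)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "events": [{"drug": e.drug, "day": e.day, "gamma": e.gamma}
                       for e in self.events],
            "beta": self.beta,
            "t_end": self.t_end,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Schedule":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        events = tuple(DoseEvent(e["drug"], e["day"], e["gamma"])
                       for e in doc["events"])
        return cls(events=events, beta=doc["beta"], t_end=doc["t_end"])


def dose_rate(t: float, schedule: Schedule, drug: str) -> float:
    """Instantaneous volumetric source rate of one drug (g/cm^3/day)."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    if drug not in _DRUGS:
        raise ValueError(f"unknown drug {drug!r}")
    rate = 0.0
    for event in schedule.events:
        if event.drug == drug and event.day < t:
            rate += event.gamma * np.exp(-schedule.beta * (t - event.day))
    return rate


def build_mouse_schedule(days,
                         gamma_A: float,
                         gamma_B: float,
                         beta: float = DEFAULT_BETA,
                         t_end: float = 30.0) -> Schedule:
    """Both drugs injected on every listed day (mouse protocol)."""
    days = list(days)
    if not days:
        raise ValueError("mouse schedule needs at least one injection day")
    events = []
    for day in days:
        events.append(DoseEvent(ANTI_PD1, float(day), gamma_A))
        events.append(DoseEvent(ANTI_TNF, float(day), gamma_B))
    return Schedule(events=tuple(events), beta=beta, t_end=t_end)


def build_human_schedule(variant: str,
                         n_cycles: int,
                         gamma_A: float,
                         gamma_B: float,
                         beta: float = DEFAULT_BETA) -> Schedule:
    """21-day-cycle schedule S1, S2 or S3.

    S1: both drugs on day 0 of each cycle.
    S2: anti-PD-1 on day 0, anti-TNF-a on day 7 of each cycle.
    S3: anti-TNF-a on day 0, anti-PD-1 on day 7 of each cycle.
    """
    offsets = {"S1": (0.0, 0.0), "S2": (0.0, 7.0), "S3": (7.0, 0.0)}
    if variant not in offsets:
        raise ValueError(f"unknown schedule variant {variant!r}")
    if n_cycles < 1:
        raise ValueError(f"need at least one cycle, got {n_cycles}")
    off_A, off_B = offsets[variant]
    events = []
    for k in range(n_cycles):
        start = k * CYCLE_DAYS
        events.append(DoseEvent(ANTI_PD1, start + off_A, gamma_A))
        events.append(DoseEvent(ANTI_TNF, start + off_B, gamma_B))
    return Schedule(events=tuple(events), beta=beta,
                    t_end=float(n_cycles * CYCLE_DAYS))


def tvrr(V0: float, Ve: float) -> float:
    """Tumor volume reduction rate (%) between start and end of treatment."""
    if V0 <= 0:
        raise ValueError(f"initial volume must be positive, got {V0}")
    if Ve < 0:
        raise ValueError(f"end volume must be nonnegative, got {Ve}")
    return (V0 - Ve) / V0 * 100.0
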