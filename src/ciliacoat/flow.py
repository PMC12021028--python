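"""Stepwise flow schedules for microfluidic detachment assays."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = ["FlowStep", "FlowSchedule", "DEFAULT_FLOW_SCHEDULE"]


@dataclass(frozen=True)
class FlowStep:
    pressure_mbar: float
    flow_rate_ml_min: float
    duration_s: float  # math.inf allowed for the final hold


@dataclass
class FlowSchedule:
    """Ordered pump steps with strictly increasing flow rate.

    The default schedule steps the pump every ~30 s from 3.77 to
    51.94 mL/min, holding the last step indefinitely.
    """

    steps: list[FlowStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("schedule needs at least one step")
        rates = [s.flow_rate_ml_min for s in self.steps]
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValidationError("flow rates must be strictly increasing")
        for i, s in enumerate(self.steps):
            if s.duration_s <= 0:
                raise ValidationError("step durations must be > 0")
            if math.isinf(s.duration_s) and i != len(self.steps) - 1:
                raise ValidationError("only the final step may be unbounded")

    @property
    def boundaries(self) -> list[float]:
        """Step start times in seconds (first step starts at 0)."""
        out, t = [], 0.0
        for s in self.steps:
            out.append(t)
            t += s.duration_s
        return out

    def total_duration(self) -> float:
        return sum(s.duration_s for s in self.steps)

    def step_at(self, t: float) -> int:
        """Index of the step active at time ``t`` seconds."""
        if t < 0:
            raise ValidationError(f"time {t} before schedule start")
        for i, (start, s) in enumerate(zip(self.boundaries, self.steps)):
            if t < start + s.duration_s:
                return i
        return len(self.steps) - 1

    def covers(self, duration: float) -> bool:
        return self.total_duration() >= duration

    @classmethod
    def from_csv(cls, path) -> "FlowSchedule":
        df = pd.read_csv(path)
        need = {"pressure_mbar", "flow_rate_ml_min", "duration_s"}
        if not need.issubset(df.columns):
            raise ValidationError(f"schedule CSV needs columns {sorted(need)}")
        steps = [
            FlowStep(r.pressure_mbar, r.flow_rate_ml_min, float(r.duration_s))
            for r in df.itertuples()
        ]
        return cls(steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pressure_mbar": [s.pressure_mbar for s in self.steps],
                "flow_rate_ml_min": [s.flow_rate_ml_min for s in self.steps],
                "duration_s": [s.duration_s for s in self.steps],
            }
        )


#: The published pump program: pressure [mbar], flow [mL/min], duration [s].
DEFAULT_FLOW_SCHEDULE = FlowSchedule(
    [
        FlowStep(5, 3.77, 25),
        FlowStep(10, 7.38, 30),
        FlowStep(20, 14.18, 30),
        FlowStep(40, 26.28, 30),
        FlowStep(60, 36.72, 30),
        FlowStep(80, 45.83, 30),
        FlowStep(95, 51.94, math.inf),
    ]
)
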