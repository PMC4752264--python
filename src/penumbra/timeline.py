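"""Experiment timeline: ordered baseline / hypoxia / recovery phases.

Every recording is laid out on a common clock starting at t = 0 h. Each
clock hour is split into a stimulation block (the first ``stim_minutes``
minutes) and a spontaneous-activity block (the remainder), mirroring the
hourly structure of the culture experiments this package models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASE_LABELS = ("baseline", "hypoxia", "recovery")


@dataclass(frozen=True)
class Phase:
    label: str
    start_h: float
    end_h: float

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


@dataclass
class PhaseTimeline:
    """Contiguous, non-overlapping experiment phases on an hour clock.

    Parameters
    ----------
    phases
        Ordered phases; must start at 0 h, be contiguous and carry labels
        from ``PHASE_LABELS``.
    stim_minutes
        Minutes at the start of each clock hour reserved for electrical
        stimulation (default 10; the remaining 50 min are spontaneous).
    """

    phases: list[Phase]
    stim_minutes: float = 10.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("timeline needs at least one phase")
        if abs(self.phases[0].start_h) > 1e-12:
            raise ValueError("first phase must start at 0 h")
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.end_h - b.start_h) > 1e-9:
                raise ValueError("phases must be contiguous")
        for p in self.phases:
            if p.label not in PHASE_LABELS:
                raise ValueError(f"unknown phase label {p.label!r}")
            if p.duration_h <= 0:
                raise ValueError("phase durations must be positive")
        if not 0 <= self.stim_minutes < 60:
            raise ValueError("stim_minutes must be in [0, 60)")

    @classmethod
    def standard(
        cls,
        baseline_h: float = 2.0,
        hypoxia_h: float = 6.0,
        recovery_h: float = 3.0,
        stim_minutes: float = 10.0,
    ) -> "PhaseTimeline":
        """Default protocol: 2 h baseline, a hypoxic period, >=3 h recovery."""
        phases = [Phase("baseline", 0.0, baseline_h)]
        t = baseline_h
        if hypoxia_h > 0:
            phases.append(Phase("hypoxia", t, t + hypoxia_h))
            t += hypoxia_h
        if recovery_h > 0:
            phases.append(Phase("recovery", t, t + recovery_h))
        return cls(phases, stim_minutes=stim_minutes)

    @property
    def duration_h(self) -> float:
        return self.phases[-1].end_h

    def span(self, label: str) -> tuple[float, float] | None:
        """(start_h, end_h) of the first phase with this label, or None."""
        for p in self.phases:
            if p.label == label:
                return (p.start_h, p.end_h)
        return None

    def phase_of(self, t_h):
        """Phase label at time(s) ``t_h`` (hours); vectorized."""
        t = np.asarray(t_h, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        for p in self.phases:
            mask = (t >= p.start_h) & (t < p.end_h)
            out[mask] = p.label
        out[np.isclose(t, self.duration_h)] = self.phases[-1].label
        if np.ndim(t_h) == 0:
            return str(out.item())
        return out.astype(str)

    def hours(self) -> np.ndarray:
        """Integer clock-hour starts covering the experiment."""
        return np.arange(int(np.ceil(self.duration_h - 1e-9)))

    def in_stim_window(self, t_h):
        """True where ``t_h`` falls in an hourly stimulation block."""
        t = np.asarray(t_h, dtype=float)
        return (t % 1.0) < self.stim_minutes / 60.0

    def stim_windows(self) -> list[tuple[float, float]]:
        """Hourly stimulation windows as (start_s, end_s) pairs."""
        out = []
        for h in self.hours():
            out.append((h * 3600.0, h * 3600.0 + self.stim_minutes * 60.0))
        return out
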