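"""In-memory container for spike-event recordings.

A :class:`Recording` holds the spike table (time, electrode, ground-truth
unit where known), optional per-spike waveform cutouts (96 samples at
16 kHz, peak at sample index 32), the phase timeline and, when present,
the stimulation schedule and the generating ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .timeline import PhaseTimeline

#: Samples per waveform cutout (6 ms at 16 kHz).
CUTOUT_SAMPLES = 96
#: 0-based sample index of the peak inside a cutout (2 ms = 32 samples in).
PEAK_INDEX = 32
#: Default sampling rate (Hz).
SAMPLE_RATE = 16000.0


@dataclass
class Recording:
    """Time-ordered spike events plus experiment metadata.

    ``spikes`` has columns ``time_s`` (float64), ``electrode`` (int) and
    ``unit`` (int; -1 when the source unit is unknown, e.g. after
    threshold detection on real traces). ``waveforms`` is row-aligned with
    ``spikes`` when present.
    """

    spikes: pd.DataFrame
    timeline: PhaseTimeline
    waveforms: Optional[np.ndarray] = None
    schedule: object = None  # StimulationSchedule, kept loose to avoid cycles
    ground_truth: object = None  # NetworkGroundTruth
    n_electrodes: int = 60
    fs: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        required = {"time_s", "electrode", "unit"}
        missing = required - set(self.spikes.columns)
        if missing:
            raise ValueError(f"spike table missing columns {sorted(missing)}")
        t = self.spikes["time_s"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError("spike table must be sorted by time")
        if self.waveforms is not None:
            if len(self.waveforms) != len(self.spikes):
                raise ValueError("waveforms not aligned with spike table")
            if self.waveforms.shape[1] != CUTOUT_SAMPLES:
                raise ValueError(f"cutouts must have {CUTOUT_SAMPLES} samples")

    def __len__(self) -> int:
        return len(self.spikes)

    @property
    def duration_h(self) -> float:
        return self.timeline.duration_h

    @property
    def duration_s(self) -> float:
        return self.timeline.duration_h * 3600.0

    def times(self, electrode: int | None = None, unit: int | None = None) -> np.ndarray:
        """Spike times (s), optionally restricted to one electrode or unit."""
        df = self.spikes
        if electrode is not None:
            df = df[df["electrode"] == electrode]
        if unit is not None:
            df = df[df["unit"] == unit]
        return df["time_s"].to_numpy()

    def electrode_times(self) -> dict[int, np.ndarray]:
        """Sorted spike times per electrode (all electrodes, possibly empty)."""
        out = {e: np.empty(0) for e in range(self.n_electrodes)}
        for e, grp in self.spikes.groupby("electrode"):
            out[int(e)] = grp["time_s"].to_numpy()
        return out

    def select(self, mask: np.ndarray) -> "Recording":
        """New Recording restricted to the boolean row mask."""
        wf = self.waveforms[mask] if self.waveforms is not None else None
        return Recording(
            self.spikes[mask].reset_index(drop=True),
            self.timeline,
            waveforms=wf,
            schedule=self.schedule,
            ground_truth=self.ground_truth,
            n_electrodes=self.n_electrodes,
            fs=self.fs,
        )


def merge_recordings(a: Recording, b: Recording) -> Recording:
    """Merge two recordings on the same timeline, re-sorting by time.

    Waveforms are kept only if both inputs carry them.
    """
    if a.timeline.duration_h != b.timeline.duration_h:
        raise ValueError("recordings must share a timeline")
    spikes = pd.concat([a.spikes, b.spikes], ignore_index=True)
    order = np.argsort(spikes["time_s"].to_numpy(), kind="stable")
    spikes = spikes.iloc[order].reset_index(drop=True)
    wf = None
    if a.waveforms is not None and b.waveforms is not None:
        wf = np.concatenate([a.waveforms, b.waveforms])[order]
    return Recording(
        spikes,
        a.timeline,
        waveforms=wf,
        schedule=a.schedule or b.schedule,
        ground_truth=a.ground_truth or b.ground_truth,
        n_electrodes=max(a.n_electrodes, b.n_electrodes),
        fs=a.fs,
    )


def spike_frame(time_s, electrode, unit=None) -> pd.DataFrame:
    """Build a canonical spike table from arrays (sorted by time)."""
    time_s = np.asarray(time_s, dtype=np.float64)
    electrode = np.asarray(electrode, dtype=np.int32)
    if unit is None:
        unit = np.full(len(time_s), -1, dtype=np.int32)
    unit = np.asarray(unit, dtype=np.int32)
    order = np.argsort(time_s, kind="stable")
    return pd.DataFrame(
        {
            "time_s": time_s[order],
            "electrode": electrode[order],
            "unit": unit[order],
        }
    )
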