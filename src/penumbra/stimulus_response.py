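"""Stimulus-evoked network responses: PSTH and the synaptic area A_syn.

The array-wide peristimulus time histogram (PSTH) counts spikes on all
electrodes per latency bin after each pulse, averaged over pulses. The
synaptically mediated response A_syn is the area under the PSTH from 15
to 150 ms -- the early (<15 ms) phase mixes directly and synaptically
evoked spikes and is not analysed. Per stimulation electrode, A_syn is
normalized to its baseline mean; electrodes with a baseline A_syn below
6 spikes are excluded from the normalized series to avoid unstable
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording

#: Half-open latency window of the synaptically mediated phase (ms).
ASYN_WINDOW_MS = (15.0, 150.0)
#: Minimum baseline A_syn (spikes/pulse) for inclusion of an electrode.
ASYN_BASELINE_MIN = 6.0


@dataclass
class PSTH:
    """Array-wide per-pulse-averaged spike counts vs latency."""

    counts: np.ndarray  # mean spikes per pulse per latency bin
    bin_ms: float
    t_max_ms: float
    n_pulses: int

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return np.arange(len(self.counts)) * self.bin_ms


def build_psth(
    rec: Recording,
    stim_electrode: int,
    pulses: np.ndarray | None = None,
    t_max_ms: float = 300.0,
    bin_ms: float = 1.0,
    blank_ms: float = 2.0,
) -> PSTH:
    """Average response of the whole array to pulses on one electrode.

    Spikes on any electrode within ``blank_ms`` after a pulse are
    excluded (stimulation-artefact blanking). Latency bin k covers
    ``[k*bin_ms, (k+1)*bin_ms)``.
    """
    if pulses is None:
        if rec.schedule is None:
            raise ValueError("no pulses given and recording has no schedule")
        pulses = rec.schedule.pulse_times[stim_electrode]
    pulses = np.asarray(pulses, dtype=float)
    if len(pulses) == 0:
        raise ValueError("no stimulation pulses")
    t = rec.spikes["time_s"].to_numpy()
    n_bins = int(round(t_max_ms / bin_ms))
    counts = np.zeros(n_bins)
    t_max_s = t_max_ms / 1e3
    lo = np.searchsorted(t, pulses + blank_ms / 1e3, side="left")
    hi = np.searchsorted(t, pulses + t_max_s, side="left")
    for a, b, t0 in zip(lo, hi, pulses):
        if b > a:
            dt_ms = (t[a:b] - t0) * 1e3
            # epsilon guards spikes landing exactly on a bin edge after
            # floating-point subtraction
            idx = np.floor(dt_ms / bin_ms + 1e-9).astype(int)
            counts += np.bincount(idx[(idx >= 0) & (idx < n_bins)], minlength=n_bins)
    return PSTH(counts / len(pulses), bin_ms, t_max_ms, len(pulses))


def compute_asyn(psth: PSTH, window_ms: tuple = ASYN_WINDOW_MS) -> float:
    """Area under the PSTH over the half-open window (default [15, 150) ms).

    The PSTH is a discrete counting curve, so the area is the sum of
    per-pulse-averaged counts over the window bins: the expected number
    of synaptically relayed spikes per pulse.
    """
    if psth.t_max_ms < window_ms[1]:
        raise ValueError("PSTH does not cover the A_syn window")
    starts = psth.bin_starts_ms
    sel = (starts >= window_ms[0] - 1e-9) & (starts + psth.bin_ms <= window_ms[1] + 1e-9)
    return float(psth.counts[sel].sum())


def asyn_series(
    rec: Recording,
    stim_electrode: int,
    t_max_ms: float = 300.0,
    bin_ms: float = 1.0,
    blank_ms: float = 2.0,
) -> pd.DataFrame:
    """A_syn per hourly stimulation block for one stimulation electrode."""
    if rec.schedule is None:
        raise ValueError("recording has no stimulation schedule")
    pulses = rec.schedule.pulse_times[stim_electrode]
    rows = []
    for h in rec.timeline.hours():
        block = pulses[(pulses >= h * 3600.0) & (pulses < (h + 1) * 3600.0)]
        if len(block) == 0:
            continue
        psth = build_psth(
            rec, stim_electrode, pulses=block, t_max_ms=t_max_ms, bin_ms=bin_ms,
            blank_ms=blank_ms,
        )
        rows.append(
            {
                "stim_electrode": stim_electrode,
                "hour": int(h),
                "phase": rec.timeline.phase_of(h + 0.5 * rec.timeline.stim_minutes / 60.0),
                "n_pulses": len(block),
                "A_syn": compute_asyn(psth),
            }
        )
    return pd.DataFrame(rows)


def normalize_asyn(
    series: pd.DataFrame, baseline_min: float = ASYN_BASELINE_MIN
) -> pd.DataFrame:
    """Add ``A_syn_norm`` and ``excluded`` columns per stimulation electrode.

    The divisor is the electrode's mean A_syn over baseline-phase blocks;
    electrodes whose baseline mean falls below ``baseline_min`` spikes are
    flagged excluded and left unnormalized (NaN).
    """
    out = series.copy()
    out["A_syn_norm"] = np.nan
    out["excluded"] = True
    for e, grp in series.groupby("stim_electrode"):
        base = grp[grp["phase"] == "baseline"]["A_syn"]
        if len(base) == 0:
            continue
        mean = base.mean()
        if mean < baseline_min:
            continue
        sel = out["stim_electrode"] == e
        out.loc[sel, "A_syn_norm"] = out.loc[sel, "A_syn"] / mean
        out.loc[sel, "excluded"] = False
    return out
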