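"""Single-neuron electrode screening and action-potential shape tracking.

An electrode counts as recording a single neuron when its first baseline
hour holds at least 100 spikes with no 1-ms refractory violations and a
waveform-variability statistic below 1. The statistic averages the
product of the per-sample SD and mean over samples 9-59 (1-based; 1.5 ms
before to ~1.6 ms after the peak) and normalizes by the mean-waveform
amplitude; cutouts are amplitude-normalized first so the statistic is
dimensionless and the threshold of 1 meaningful.

For single-neuron electrodes the hourly mean waveform is tracked: the
shape counts as constant while its mean correlation with all preceding
hourly means stays above 0.9 and its amplitude above 80% of the baseline
amplitude. Each electrode is assigned a fate: active throughout, inactive
after a shape change, or inactive without one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .recording import Recording

#: 1-based inclusive sample window of the variability statistic.
VAR_WINDOW = (9, 59)

FATES = ("active_throughout", "inactive_after_change", "inactive_no_change")


@dataclass
class VariabilityResult:
    electrode: int
    n_spikes_baseline_h1: int
    refractory_violations: int
    variability: float
    is_single_neuron: bool


@dataclass
class WaveformTrack:
    """Hourly mean-waveform history of one single-neuron electrode.

    ``table`` columns: ``hour``, ``n_spikes``, ``missing`` (fewer than 5
    spont spikes), ``amplitude``, ``r_mean``, ``constant``.
    """

    electrode: int
    table: pd.DataFrame
    hourly_means: dict  # hour -> mean waveform (non-missing hours only)
    baseline_amplitude: float
    constant_until_h: Optional[int]
    first_violation_h: Optional[int]


def compute_variability(waveforms: np.ndarray, window: tuple = VAR_WINDOW) -> float:
    """Dimensionless waveform-variability statistic of a cutout stack.

    ``|sum_n SD[n] * Mean[n] / n_window| / max|Mean|`` over the 1-based
    sample window, evaluated on cutouts divided by the mean-waveform
    amplitude. Zero for identical cutouts; grows when shapes mix, with
    emphasis near the peak where |Mean| is large.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    if waveforms.ndim != 2 or len(waveforms) < 2:
        raise ValueError("need at least two waveform cutouts")
    mean_raw = waveforms.mean(axis=0)
    amp = np.max(np.abs(mean_raw))
    if amp == 0:
        raise ValueError("mean waveform has zero amplitude")
    norm = waveforms / amp
    mean = norm.mean(axis=0)
    sd = norm.std(axis=0, ddof=1)
    lo, hi = window  # 1-based inclusive
    seg = slice(lo - 1, hi)
    n_window = hi - lo + 1
    return float(
        np.abs(np.sum(sd[seg] * mean[seg]) / n_window) / np.max(np.abs(mean))
    )


def single_neuron_screen(
    rec: Recording,
    electrode: int,
    min_spikes: int = 100,
    refractory_ms: float = 1.0,
    variability_threshold: float = 1.0,
) -> VariabilityResult:
    """Apply the single-neuron criteria on the first baseline hour."""
    if rec.waveforms is None:
        raise ValueError("recording carries no waveform cutouts")
    base = rec.timeline.span("baseline")
    if base is None:
        raise ValueError("timeline has no baseline phase")
    t0, t1 = base[0] * 3600.0, min(base[0] + 1.0, base[1]) * 3600.0
    t = rec.spikes["time_s"].to_numpy()
    sel = (rec.spikes["electrode"].to_numpy() == electrode) & (t >= t0) & (t < t1)
    times = t[sel]
    n = int(sel.sum())
    violations = int(np.sum(np.diff(times) < refractory_ms / 1e3)) if n > 1 else 0
    if n >= 2:
        variability = compute_variability(rec.waveforms[sel])
    else:
        variability = np.inf
    is_single = (
        n >= min_spikes and violations == 0 and variability < variability_threshold
    )
    return VariabilityResult(
        electrode=electrode,
        n_spikes_baseline_h1=n,
        refractory_violations=violations,
        variability=float(variability),
        is_single_neuron=bool(is_single),
    )


def track_shape(
    rec: Recording,
    electrode: int,
    min_spikes_per_hour: int = 5,
    r_threshold: float = 0.9,
    amplitude_fraction: float = 0.8,
    exclude_stim_window: bool = True,
) -> WaveformTrack:
    """Hourly mean waveforms with shape-constancy flags.

    Hours with fewer than ``min_spikes_per_hour`` spontaneous spikes are
    marked missing and skipped (they do not break constancy by
    themselves). ``r_mean`` of an hour is the mean Pearson correlation of
    its mean waveform against every preceding non-missing hour. The
    baseline amplitude for the 80% rule is the mean hourly amplitude over
    baseline-phase hours. Spikes in the hourly stimulation window are
    excluded from the shape averages when a schedule is attached.
    """
    if rec.waveforms is None:
        raise ValueError("recording carries no waveform cutouts")
    hours = rec.timeline.hours()
    if len(hours) < 2:
        raise ValueError("need at least two hours of recording")
    t_h = rec.spikes["time_s"].to_numpy() / 3600.0
    on_e = rec.spikes["electrode"].to_numpy() == electrode
    spont = np.ones(len(t_h), dtype=bool)
    if exclude_stim_window and rec.schedule is not None:
        spont = ~rec.timeline.in_stim_window(t_h)
    means: dict[int, np.ndarray] = {}
    rows = []
    for h in hours:
        sel = on_e & spont & (t_h >= h) & (t_h < h + 1)
        n = int(sel.sum())
        missing = n < min_spikes_per_hour
        amp = np.nan
        if not missing:
            m = rec.waveforms[sel].mean(axis=0).astype(float)
            means[int(h)] = m
            amp = float(np.max(np.abs(m)))
        rows.append({"hour": int(h), "n_spikes": n, "missing": missing, "amplitude": amp})
    if len(means) < 2:
        raise ValueError("fewer than two non-missing hours")
    base = rec.timeline.span("baseline")
    base_hours = [
        h for h in means if base is not None and base[0] <= h < base[1]
    ]
    if base_hours:
        baseline_amp = float(np.mean([np.max(np.abs(means[h])) for h in base_hours]))
    else:  # no usable baseline hour: fall back on the first tracked hour
        baseline_amp = float(np.max(np.abs(means[min(means)])))
    table = pd.DataFrame(rows)
    r_mean = np.full(len(table), np.nan)
    constant = np.ones(len(table), dtype=bool)
    seen: list[int] = []
    first_violation = None
    for k, row in table.iterrows():
        h = int(row["hour"])
        if row["missing"]:
            continue
        if seen:
            rs = [_pearson(means[h], means[p]) for p in seen]
            r_mean[k] = float(np.mean(rs))
        ok_r = np.isnan(r_mean[k]) or r_mean[k] > r_threshold
        ok_amp = row["amplitude"] >= amplitude_fraction * baseline_amp
        constant[k] = bool(ok_r and ok_amp)
        if not constant[k] and first_violation is None:
            first_violation = h
        seen.append(h)
    table["r_mean"] = r_mean
    table["constant"] = constant
    tracked = table[~table["missing"]]
    if first_violation is None:
        constant_until = int(tracked["hour"].max())
    else:
        prior = tracked[tracked["hour"] < first_violation]
        constant_until = int(prior["hour"].max()) if len(prior) else None
    return WaveformTrack(
        electrode=electrode,
        table=table,
        hourly_means=means,
        baseline_amplitude=baseline_amp,
        constant_until_h=constant_until,
        first_violation_h=first_violation,
    )


def assign_fate(track: WaveformTrack, recording_end_h: float) -> str:
    """Fate of a single-neuron electrode.

    Inactive means the electrode fired no spikes from some complete hour
    through the end of the recording; the fate splits on whether a
    shape-constancy violation preceded the silence.
    """
    table = track.table
    active_hours = table[table["n_spikes"] > 0]["hour"]
    last_hour = int(np.floor(recording_end_h - 1e-9))
    if len(active_hours) == 0:
        silent_from = int(table["hour"].min())
    elif int(active_hours.max()) < last_hour:
        silent_from = int(active_hours.max()) + 1
    else:
        return "active_throughout"
    if track.first_violation_h is not None and track.first_violation_h <= silent_from:
        return "inactive_after_change"
    return "inactive_no_change"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 1.0 if sa == sb else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def track_to_frame(track: WaveformTrack) -> pd.DataFrame:
    df = track.table.copy()
    df.insert(0, "electrode", track.electrode)
    return df
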