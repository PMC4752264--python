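"""Threshold-based spike detection on raw voltage traces.

Events open when the absolute signal exceeds ``threshold_factor`` (default
5.5) times the estimated noise level; the event peak is the local maximum
of the absolute signal, and a 6-ms cutout (2 ms before the peak to 4 ms
after, 96 samples at 16 kHz) is stored per spike. The noise level is a
median-absolute-deviation estimate over 10-s windows, robust against the
spikes themselves. A simplified artefact screen rejects saturated cutouts
and waveform-identical coincidences across many electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import CUTOUT_SAMPLES, PEAK_INDEX, SAMPLE_RATE, Recording, spike_frame
from .timeline import Phase, PhaseTimeline

MAD_TO_SD = 0.6744897501960817  # Phi^-1(0.75): MAD of a Gaussian in sigma units


@dataclass(frozen=True)
class NoiseEstimate:
    electrode: int
    sigma: float
    window_s: float


@dataclass
class SpikeEvent:
    time_s: float
    electrode: int
    waveform: np.ndarray
    peak_index: int = PEAK_INDEX


def estimate_noise(
    trace: np.ndarray,
    fs: float = SAMPLE_RATE,
    window_s: float = 10.0,
    electrode: int = -1,
) -> NoiseEstimate:
    """Robust noise SD: median over windows of MAD / 0.6745.

    The median-absolute-deviation basis makes the estimate insensitive to
    the rare large excursions that are the spikes to be detected.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    win = max(1, int(round(window_s * fs)))
    sigmas = []
    for a in range(0, len(trace), win):
        chunk = trace[a : a + win]
        if len(chunk) < win // 2 and sigmas:
            break  # ignore a short trailing remainder
        med = np.median(chunk)
        sigmas.append(np.median(np.abs(chunk - med)) / MAD_TO_SD)
    return NoiseEstimate(electrode=electrode, sigma=float(np.median(sigmas)), window_s=window_s)


def detect_spikes(
    trace: np.ndarray,
    noise: NoiseEstimate,
    threshold_factor: float = 5.5,
    fs: float = SAMPLE_RATE,
    dead_time_ms: float = 1.0,
    min_supra_samples: int = 2,
    electrode: int = -1,
) -> list[SpikeEvent]:
    """Detect spikes as supra-threshold episodes of the absolute signal.

    Supra-threshold runs separated by less than ``dead_time_ms`` are merged
    into one episode (1-ms refractory bookkeeping); an episode must contain
    at least ``min_supra_samples`` supra-threshold samples, which suppresses
    single-sample noise excursions. Episodes whose cutout would cross the
    trace boundary are discarded.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < CUTOUT_SAMPLES:
        raise ValueError("trace shorter than one cutout")
    if noise.sigma <= 0:
        raise ValueError("noise sigma must be positive for thresholding")
    thr = threshold_factor * noise.sigma
    above = np.abs(trace) > thr
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(trace)]))
    dead = int(round(dead_time_ms / 1e3 * fs))
    episodes = []
    cur_a, cur_b = starts[0], ends[0]
    for a, b in zip(starts[1:], ends[1:]):
        if a - cur_b < dead:
            cur_b = b
        else:
            episodes.append((cur_a, cur_b))
            cur_a, cur_b = a, b
    episodes.append((cur_a, cur_b))
    events = []
    for a, b in episodes:
        if int(above[a:b].sum()) < min_supra_samples:
            continue
        peak = a + int(np.argmax(np.abs(trace[a:b])))
        lo = peak - PEAK_INDEX
        hi = lo + CUTOUT_SAMPLES
        if lo < 0 or hi > len(trace):
            continue
        events.append(
            SpikeEvent(time_s=peak / fs, electrode=electrode, waveform=trace[lo:hi].copy())
        )
    return events


def screen_artefacts(
    events: list[SpikeEvent],
    max_coincident: int = 10,
    coincidence_ms: float = 0.2,
    identity_corr: float = 0.95,
    saturation_run: int = 4,
):
    """Split events into (kept, rejected).

    Rejects (a) groups of events simultaneous within ``coincidence_ms``
    on more than ``max_coincident`` electrodes whose waveforms are
    near-identical (mean correlation to the group mean above
    ``identity_corr``) -- the signature of electrical pickup rather than
    biology -- and (b) clipped/saturated cutouts, identified by a run of
    ``saturation_run`` samples pinned at the cutout extreme.
    """
    if not events:
        return [], []
    rejected_idx: set[int] = set()

    # (b) saturation: a flat run at the extreme value
    for k, ev in enumerate(events):
        w = ev.waveform
        extreme = np.max(np.abs(w))
        if extreme == 0:
            continue
        pinned = np.abs(np.abs(w) - extreme) <= 1e-9 * max(extreme, 1.0)
        run = _longest_run(pinned)
        if run >= saturation_run:
            rejected_idx.add(k)

    # (a) cross-electrode coincidences with identical shapes
    order = np.argsort([ev.time_s for ev in events], kind="stable")
    times = np.array([events[k].time_s for k in order])
    tol = coincidence_ms / 1e3
    start = 0
    for end in range(1, len(order) + 1):
        if end == len(order) or times[end] - times[end - 1] > tol:
            group = order[start:end]
            if len(group) > max_coincident:
                electrodes = {events[k].electrode for k in group}
                if len(electrodes) > max_coincident:
                    wfs = np.stack([events[k].waveform for k in group])
                    mean = wfs.mean(axis=0)
                    rs = [_pearson(w, mean) for w in wfs]
                    if np.mean(rs) > identity_corr:
                        rejected_idx.update(int(k) for k in group)
            start = end
    kept = [ev for k, ev in enumerate(events) if k not in rejected_idx]
    rejected = [ev for k, ev in enumerate(events) if k in rejected_idx]
    return kept, rejected


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 1.0 if sa == sb else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def detect_recording(
    traces: dict,
    timeline: PhaseTimeline | None = None,
    fs: float = SAMPLE_RATE,
    threshold_factor: float = 5.5,
    screen: bool = True,
    **detect_kwargs,
) -> Recording:
    """Run noise estimation + detection (+ artefact screen) on a trace set.

    ``traces`` maps electrode id to its voltage array. Returns a Recording
    with unknown unit ids (-1).
    """
    all_events: list[SpikeEvent] = []
    for e, trace in sorted(traces.items()):
        noise = estimate_noise(trace, fs=fs, electrode=e)
        all_events.extend(
            detect_spikes(
                trace, noise, threshold_factor=threshold_factor, fs=fs, electrode=e,
                **detect_kwargs,
            )
        )
    if screen:
        all_events, _ = screen_artefacts(all_events)
    if timeline is None:
        dur_h = max((len(t) for t in traces.values()), default=0) / fs / 3600.0
        timeline = PhaseTimeline(
            [Phase("baseline", 0.0, max(dur_h, 1e-6))], stim_minutes=0.0
        )
    times = np.array([ev.time_s for ev in all_events])
    elecs = np.array([ev.electrode for ev in all_events], dtype=int)
    order = np.argsort(times, kind="stable")
    wf = (
        np.stack([all_events[k].waveform for k in order]).astype(np.float32)
        if all_events
        else None
    )
    spikes = spike_frame(times, elecs if len(elecs) else np.empty(0, int))
    n_elec = max(60, max(traces.keys(), default=0) + 1)
    return Recording(spikes, timeline, waveforms=wf, n_electrodes=n_elec, fs=fs)
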