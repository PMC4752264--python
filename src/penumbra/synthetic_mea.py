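"""Ground-truth-annotated synthetic MEA recordings.

Generates spike-event recordings (and optionally raw 16-kHz traces) with
the statistical structure the analysis pipeline assumes: ~60 electrodes,
excitatory units firing in a near-Poisson regime, inhibitory units firing
in rare intense bursts (which drives their high spike-count variability),
optional intrinsically active (tonic) units, pairwise coupling that
produces conditional-firing-probability peaks at known delays, per-unit
waveform templates with additive Gaussian noise, stimulus-locked network
responses, and a hypoxia protocol that scales coupling efficacy and firing
rates through an exponential pO2 relaxation.

Coupling model
--------------
Spike trains are built as a branching (Hawkes-like) point process: each
unit emits baseline spikes from an (in)homogeneous Poisson process, and
every spike of unit *i* independently triggers a spike of unit *j* with
probability ``adjacency[i, j] * efficacy(t)`` at latency
``delay_ms[i, j]`` plus a small Gaussian jitter. Triggered spikes can
trigger further spikes, up to a generation cap. Spikes of inhibitory
units instead *delete* target spikes within a short window after the edge
delay, with the same probability. A 1-ms refractory period is enforced on
every unit's final train. This event-driven construction has the same law,
for pair-statistics purposes, as a 1-ms-grid conditionally-Poisson model,
and keeps multi-hour 60-unit simulations fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .recording import (
    CUTOUT_SAMPLES,
    PEAK_INDEX,
    SAMPLE_RATE,
    Recording,
    merge_recordings,
)
from .timeline import Phase, PhaseTimeline

UNIT_CLASSES = ("excitatory", "inhibitory", "intrinsic")

REFRACTORY_S = 1e-3
#: Window after the edge delay in which an inhibitory spike can delete
#: target spikes (s).
INHIBITION_WINDOW_S = 10e-3


# ---------------------------------------------------------------------------
# waveform templates


def make_template(
    amplitude: float = 80.0,
    width_ms: float = 0.25,
    rebound: float = 0.35,
    rebound_delay_ms: float = 0.55,
    rebound_width_ms: float = 0.45,
    n_samples: int = CUTOUT_SAMPLES,
    peak_index: int = PEAK_INDEX,
    fs: float = SAMPLE_RATE,
) -> np.ndarray:
    """Biphasic extracellular spike template (negative main lobe).

    The peak of ``|template|`` sits exactly at ``peak_index`` and equals
    ``amplitude``.
    """
    t_ms = (np.arange(n_samples) - peak_index) / fs * 1e3
    shape = -np.exp(-(t_ms**2) / (2 * width_ms**2)) + rebound * np.exp(
        -((t_ms - rebound_delay_ms) ** 2) / (2 * rebound_width_ms**2)
    )
    return amplitude * shape / np.max(np.abs(shape))


def morph_template(
    template: np.ndarray,
    m: float,
    widen: float = 0.8,
    amplitude_loss: float = 0.6,
    peak_index: int = PEAK_INDEX,
) -> np.ndarray:
    """Progressive widening + amplitude decay, ``m`` in [0, 1].

    ``m = 0`` returns the template unchanged; ``m = 1`` stretches the time
    axis by ``1 + widen`` around the peak and scales the amplitude by
    ``1 - amplitude_loss``. Emulates the loss of membrane integrity seen
    as action-potential deformation before silencing.
    """
    m = float(np.clip(m, 0.0, 1.0))
    if m == 0.0:
        return template.copy()
    n = len(template)
    x = np.arange(n, dtype=float)
    src = peak_index + (x - peak_index) / (1.0 + widen * m)
    stretched = np.interp(src, x, template)
    return (1.0 - amplitude_loss * m) * stretched


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class NetworkGroundTruth:
    """Known generating network: units, classes, coupling, templates.

    ``adjacency[i, j]`` is the per-spike follow probability (excitatory
    source) or deletion probability (inhibitory source) of edge i -> j at
    efficacy 1; ``delay_ms`` holds the matching synaptic delays. For
    inhibitory units ``base_rate`` is the *mean* rate of the bursty
    regime; burst parameters are shared fields.
    """

    unit_electrode: np.ndarray
    unit_class: list
    base_rate: np.ndarray
    adjacency: np.ndarray
    delay_ms: np.ndarray
    templates: np.ndarray
    tonic_gain: float = 4.0
    burst_rate_per_h: float = 2.0
    burst_duration_s: float = 1.5
    burst_lognorm_sigma: float = 0.8
    background_rate: float = 0.005

    def __post_init__(self) -> None:
        self.unit_electrode = np.asarray(self.unit_electrode, dtype=int)
        self.base_rate = np.asarray(self.base_rate, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.delay_ms = np.asarray(self.delay_ms, dtype=float)
        self.templates = np.asarray(self.templates, dtype=float)
        n = self.n_units
        if n == 0:
            raise ValueError("ground truth must contain at least one unit")
        for name, arr, shape in [
            ("unit_electrode", self.unit_electrode, (n,)),
            ("base_rate", self.base_rate, (n,)),
            ("adjacency", self.adjacency, (n, n)),
            ("delay_ms", self.delay_ms, (n, n)),
            ("templates", self.templates, (n, CUTOUT_SAMPLES)),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if len(self.unit_class) != n:
            raise ValueError("unit_class length mismatch")
        for c in self.unit_class:
            if c not in UNIT_CLASSES:
                raise ValueError(f"unknown unit class {c!r}")
        if np.any(self.adjacency < 0):
            raise ValueError("coupling strengths must be >= 0")
        if np.any(self.delay_ms[self.adjacency > 0] <= 0):
            raise ValueError("synaptic delays must be > 0 on every edge")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-coupling is not allowed")

    @property
    def n_units(self) -> int:
        return len(self.unit_electrode)

    @property
    def template_amplitude(self) -> np.ndarray:
        return np.max(np.abs(self.templates), axis=1)

    def class_mask(self, label: str) -> np.ndarray:
        return np.array([c == label for c in self.unit_class])

    @classmethod
    def random(
        cls,
        n_units: int = 60,
        n_electrodes: int = 60,
        frac_inhibitory: float = 0.2,
        n_intrinsic: int = 0,
        edge_prob: float = 0.05,
        strength_range: tuple = (0.10, 0.25),
        delay_range_ms: tuple = (2.0, 10.0),
        exc_rate_range: tuple = (0.5, 2.0),
        inh_mean_rate: float = 0.06,
        amplitude_range: tuple = (40.0, 120.0),
        seed: int = 0,
    ) -> "NetworkGroundTruth":
        """Random cortical-culture-like network, one unit per electrode.

        Defaults follow the composition of dissociated cortical cultures
        (~80% excitatory / ~20% inhibitory) with a sparse random coupling
        graph whose branching ratio stays safely subcritical.
        """
        rng = np.random.default_rng(seed)
        n_inh = int(round(frac_inhibitory * n_units))
        classes = np.array(
            ["inhibitory"] * n_inh
            + ["intrinsic"] * n_intrinsic
            + ["excitatory"] * (n_units - n_inh - n_intrinsic)
        )
        rng.shuffle(classes)
        electrodes = np.arange(n_units) % n_electrodes
        rates = np.where(
            classes == "inhibitory",
            inh_mean_rate,
            rng.uniform(*exc_rate_range, size=n_units),
        )
        adj = np.zeros((n_units, n_units))
        mask = rng.random((n_units, n_units)) < edge_prob
        np.fill_diagonal(mask, False)
        adj[mask] = rng.uniform(*strength_range, size=mask.sum())
        delays = np.zeros_like(adj)
        delays[mask] = rng.uniform(*delay_range_ms, size=mask.sum())
        templates = np.stack(
            [
                make_template(
                    amplitude=rng.uniform(*amplitude_range),
                    width_ms=rng.uniform(0.2, 0.32),
                    rebound=rng.uniform(0.25, 0.45),
                )
                for _ in range(n_units)
            ]
        )
        return cls(
            unit_electrode=electrodes,
            unit_class=list(classes),
            base_rate=rates,
            adjacency=adj,
            delay_ms=delays,
            templates=templates,
        )


# ---------------------------------------------------------------------------
# hypoxia protocol


@dataclass
class HypoxiaProtocol:
    """Phase timeline plus pO2 dynamics and their effect on the network.

    The bath pO2 relaxes exponentially between set-points (defaults: 160
    mmHg baseline, 23 mmHg severe hypoxia, time constants 0.95 h down and
    0.51 h up). Hypoxic depth linearly scales synaptic coupling from 1
    down to ``efficacy_min`` at full depth; by default base firing rates
    follow the same multiplier (network drive), so baseline-phase
    multipliers are identically 1.
    """

    timeline: PhaseTimeline
    pO2_baseline: float = 160.0
    pO2_hypoxia: float = 23.0
    tau_down_h: float = 0.95
    tau_up_h: float = 0.51
    efficacy_min: float = 0.5
    rate_follows_efficacy: bool = True
    silencing_onset_h: Optional[np.ndarray] = None
    morph_onset_h: Optional[np.ndarray] = None
    morph_ramp_h: float = 5.0

    @classmethod
    def normoxic(cls, duration_h: float, stim_minutes: float = 10.0) -> "HypoxiaProtocol":
        """Control protocol: one long baseline phase, no perturbation."""
        tl = PhaseTimeline([Phase("baseline", 0.0, duration_h)], stim_minutes=stim_minutes)
        return cls(tl)

    def pO2(self, t_h):
        """Bath pO2 (mmHg) at time(s) ``t_h``; first-order relaxation."""
        t = np.atleast_1d(np.asarray(t_h, dtype=float))
        out = np.full(t.shape, self.pO2_baseline)
        v0 = self.pO2_baseline
        for ph in self.timeline.phases:
            target = self.pO2_hypoxia if ph.label == "hypoxia" else self.pO2_baseline
            last = ph is self.timeline.phases[-1]
            mask = (t >= ph.start_h) & ((t < ph.end_h) | last)
            if mask.any():
                if np.isclose(v0, target):
                    out[mask] = target
                else:
                    tau = self.tau_down_h if target < v0 else self.tau_up_h
                    out[mask] = target + (v0 - target) * np.exp(
                        -(t[mask] - ph.start_h) / tau
                    )
            if np.isclose(v0, target):
                v0 = target
            else:
                tau = self.tau_down_h if target < v0 else self.tau_up_h
                v0 = target + (v0 - target) * np.exp(-ph.duration_h / tau)
        if np.ndim(t_h) == 0:
            return float(out[0])
        return out

    def depth(self, t_h):
        """Normalized hypoxic depth in [0, 1] (0 at baseline pO2)."""
        p = self.pO2(t_h)
        d = (self.pO2_baseline - p) / (self.pO2_baseline - self.pO2_hypoxia)
        return np.clip(d, 0.0, 1.0)

    def efficacy(self, t_h):
        """Multiplier on all coupling strengths; 1 at baseline."""
        return 1.0 - (1.0 - self.efficacy_min) * self.depth(t_h)

    def rate_multiplier(self, t_h):
        """Multiplier on baseline firing intensities."""
        if self.rate_follows_efficacy:
            return self.efficacy(t_h)
        return np.ones_like(np.asarray(t_h, dtype=float))

    def intrinsic_multiplier(self, t_h, gain: float):
        """Rate multiplier for intrinsically active units (disinhibition)."""
        return 1.0 + gain * self.depth(t_h)


# ---------------------------------------------------------------------------
# stimulation


@dataclass
class ResponseKernel:
    """Per (stimulation electrode, unit) evoked-response description.

    ``early_prob[s, u]``: probability of one directly evoked spike in the
    2-12 ms window (not scaled by efficacy: direct electrical activation).
    ``late_mean[s, u]``: expected synaptically relayed spikes per pulse in
    the 15-150 ms window at efficacy 1; the realized mean scales linearly
    with the protocol's efficacy curve.
    """

    early_prob: np.ndarray
    late_mean: np.ndarray

    def __post_init__(self) -> None:
        self.early_prob = np.atleast_2d(np.asarray(self.early_prob, dtype=float))
        self.late_mean = np.atleast_2d(np.asarray(self.late_mean, dtype=float))
        if self.early_prob.shape != self.late_mean.shape:
            raise ValueError("kernel component shapes differ")
        if np.any(self.early_prob < 0) or np.any(self.early_prob > 1):
            raise ValueError("early_prob must be in [0, 1]")
        if np.any(self.late_mean < 0):
            raise ValueError("late_mean must be >= 0")

    @classmethod
    def random(
        cls,
        n_units: int,
        n_stim: int,
        total_late_mean: float = 15.0,
        early_fraction: float = 0.2,
        seed: int = 0,
    ) -> "ResponseKernel":
        rng = np.random.default_rng(seed)
        late = rng.gamma(1.0, size=(n_stim, n_units))
        late = total_late_mean * late / late.sum(axis=1, keepdims=True)
        responds = rng.random((n_stim, n_units)) < early_fraction
        early = np.where(responds, rng.uniform(0.2, 0.8, size=(n_stim, n_units)), 0.0)
        return cls(early_prob=early, late_mean=late)


@dataclass
class StimulationSchedule:
    """Pulse times per stimulation electrode plus the response kernel."""

    stim_electrodes: list
    pulse_times: dict
    kernel: Optional[ResponseKernel] = None
    ipi_s: tuple = (5.0, 10.0)

    def __post_init__(self) -> None:
        self.stim_electrodes = [int(e) for e in self.stim_electrodes]
        for e in self.stim_electrodes:
            t = np.asarray(self.pulse_times[e], dtype=float)
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("pulse times must be strictly increasing")
            self.pulse_times[e] = t

    @classmethod
    def hourly(
        cls,
        stim_electrodes,
        timeline: PhaseTimeline,
        pulses_per_electrode: int = 40,
        ipi_s: tuple = (5.0, 10.0),
        kernel: Optional[ResponseKernel] = None,
        seed: int = 0,
    ) -> "StimulationSchedule":
        """Pulses in the first ``stim_minutes`` of every hour.

        Electrodes are interleaved in random order with inter-pulse
        intervals drawn uniformly from ``ipi_s``; the sequence is
        truncated at the end of the stimulation block, so the delivered
        pulse count per electrode can fall below the nominal 40.
        """
        rng = np.random.default_rng(seed)
        times = {int(e): [] for e in stim_electrodes}
        window_s = timeline.stim_minutes * 60.0
        for h in timeline.hours():
            order = np.repeat(np.asarray(stim_electrodes, int), pulses_per_electrode)
            rng.shuffle(order)
            t = h * 3600.0 + np.cumsum(rng.uniform(*ipi_s, size=len(order)))
            keep = t < h * 3600.0 + window_s
            for e, ti in zip(order[keep], t[keep]):
                times[int(e)].append(ti)
        pulse_times = {e: np.array(v) for e, v in times.items()}
        return cls(list(stim_electrodes), pulse_times, kernel=kernel, ipi_s=ipi_s)

    def all_pulses(self):
        """(times, electrodes) of every pulse, time-sorted."""
        ts, es = [], []
        for e in self.stim_electrodes:
            ts.append(self.pulse_times[e])
            es.append(np.full(len(self.pulse_times[e]), e, dtype=int))
        t = np.concatenate(ts) if ts else np.empty(0)
        e = np.concatenate(es) if es else np.empty(0, int)
        order = np.argsort(t, kind="stable")
        return t[order], e[order]


# ---------------------------------------------------------------------------
# helpers


def enforce_refractory(times: np.ndarray, refractory_s: float = REFRACTORY_S) -> np.ndarray:
    """Greedily drop spikes closer than ``refractory_s`` to the previous kept one."""
    t = np.sort(np.asarray(times, dtype=float))
    while len(t) > 1:
        bad = np.where(np.diff(t) < refractory_s)[0]
        if len(bad) == 0:
            break
        # only resolve the first violation of each chain per pass; chains
        # re-evaluate on the next pass so the greedy rule stays exact
        starts = bad[np.concatenate(([True], np.diff(bad) > 1))]
        keep = np.ones(len(t), dtype=bool)
        keep[starts + 1] = False
        t = t[keep]
    return t


def _ragged_gather(values: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Concatenate values[lo[k]:hi[k]] for all k, plus the owner index of each."""
    spans = hi - lo
    total = int(spans.sum())
    if total == 0:
        return np.empty(0), np.empty(0, dtype=int)
    cum = np.cumsum(spans)
    idx = np.arange(total) + np.repeat(lo - np.concatenate(([0], cum[:-1])), spans)
    owner = np.repeat(np.arange(len(lo)), spans)
    return values[idx], owner


def _morph_factor(protocol: HypoxiaProtocol, unit: int, t_h: np.ndarray) -> np.ndarray:
    if protocol.morph_onset_h is None:
        return np.zeros(np.shape(t_h))
    onset = protocol.morph_onset_h[unit]
    if not np.isfinite(onset):
        return np.zeros(np.shape(t_h))
    return np.clip((np.asarray(t_h) - onset) / protocol.morph_ramp_h, 0.0, 1.0)


def _make_waveforms(
    unit_ids: np.ndarray,
    times_s: np.ndarray,
    gt: NetworkGroundTruth,
    protocol: HypoxiaProtocol,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Template (+hypoxic morph) + i.i.d. Gaussian noise per spike.

    Morph factors are quantized to 0.05 steps so stretched templates can
    be cached per (unit, level).
    """
    n = len(times_s)
    wf = rng.standard_normal((n, CUTOUT_SAMPLES), dtype=np.float32) * np.float32(noise_sd)
    cache: dict = {}
    t_h = times_s / 3600.0
    for u in np.unique(unit_ids):
        rows = np.where(unit_ids == u)[0]
        m = np.round(_morph_factor(protocol, int(u), t_h[rows]) / 0.05) * 0.05
        for level in np.unique(m):
            key = (int(u), float(level))
            if key not in cache:
                cache[key] = morph_template(gt.templates[int(u)], float(level)).astype(
                    np.float32
                )
            wf[rows[m == level]] += cache[key]
    return wf


# ---------------------------------------------------------------------------
# spontaneous activity


def _baseline_train(
    unit: int,
    gt: NetworkGroundTruth,
    protocol: HypoxiaProtocol,
    T: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Baseline (pre-coupling) spike times for one unit over [0, T) seconds."""
    cls = gt.unit_class[unit]
    r = gt.base_rate[unit]
    if cls == "inhibitory":
        # rare intense bursts: this is what pushes the 6-s-bin Fano factor
        # (SD/mean) far above the inhibitory threshold
        lam_burst = gt.burst_rate_per_h / 3600.0
        n_bursts = rng.poisson(lam_burst * T)
        starts = np.sort(rng.uniform(0.0, T, size=n_bursts))
        keep = rng.random(n_bursts) < protocol.rate_multiplier(starts / 3600.0)
        starts = starts[keep]
        sigma = gt.burst_lognorm_sigma
        per_burst = max(0.0, (r - gt.background_rate) * 3600.0 / gt.burst_rate_per_h)
        spikes = []
        for t0 in starts:
            gain = np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
            count = rng.poisson(per_burst * gain)
            spikes.append(t0 + rng.uniform(0.0, gt.burst_duration_s, size=count))
        n_bg = rng.poisson(gt.background_rate * T)
        bg = rng.uniform(0.0, T, size=n_bg)
        bg = bg[rng.random(n_bg) < protocol.rate_multiplier(bg / 3600.0)]
        spikes.append(bg)
        t = np.concatenate(spikes) if spikes else np.empty(0)
    else:
        if cls == "intrinsic":
            r_max = r * (1.0 + gt.tonic_gain)
            n_cand = rng.poisson(r_max * T)
            cand = np.sort(rng.uniform(0.0, T, size=n_cand))
            accept_p = r * protocol.intrinsic_multiplier(cand / 3600.0, gt.tonic_gain) / r_max
        else:
            r_max = r
            n_cand = rng.poisson(r_max * T)
            cand = np.sort(rng.uniform(0.0, T, size=n_cand))
            accept_p = protocol.rate_multiplier(cand / 3600.0)
        t = cand[rng.random(n_cand) < accept_p]
    if protocol.silencing_onset_h is not None:
        t = t[t / 3600.0 < protocol.silencing_onset_h[unit]]
    return np.sort(t)


def simulate_spontaneous(
    gt: NetworkGroundTruth,
    protocol: HypoxiaProtocol,
    duration_h: Optional[float] = None,
    seed: int = 0,
    with_waveforms: bool = True,
    noise_sd: float = 4.0,
    max_generations: int = 6,
    delay_jitter_ms: float = 0.2,
) -> Recording:
    """Simulate spontaneous network activity over the protocol timeline.

    Returns a time-sorted :class:`Recording` whose spikes carry their true
    source unit id; cutouts (template + noise) are attached when
    ``with_waveforms`` is set. With zero coupling and a normoxic protocol
    the per-unit spike counts are exactly Poisson at ``base_rate``.
    """
    if duration_h is None:
        duration_h = protocol.timeline.duration_h
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if duration_h > protocol.timeline.duration_h + 1e-9:
        raise ValueError("duration exceeds the protocol timeline")
    n = gt.n_units
    T = duration_h * 3600.0
    ss = np.random.SeedSequence(seed)
    rng_base, rng_casc, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    per_unit = [
        [_baseline_train(u, gt, protocol, T, rng_base)] for u in range(n)
    ]

    # excitatory branching cascade
    src, tgt = np.nonzero(gt.adjacency)
    inh = gt.class_mask("inhibitory")
    exc_edges = [
        (int(i), int(j), gt.adjacency[i, j], gt.delay_ms[i, j])
        for i, j in zip(src, tgt)
        if not inh[i]
    ]
    jitter_s = delay_jitter_ms / 1e3
    current = {u: per_unit[u][0] for u in range(n)}
    for _ in range(max_generations):
        children: dict[int, list] = {}
        for i, j, w, d_ms in exc_edges:
            ti = current.get(i)
            if ti is None or len(ti) == 0:
                continue
            p = w * protocol.efficacy(ti / 3600.0)
            m = rng_casc.random(len(ti)) < p
            k = int(m.sum())
            if k == 0:
                continue
            child = ti[m] + d_ms / 1e3 + rng_casc.normal(0.0, jitter_s, size=k)
            child = child[(child >= 0) & (child < T)]
            if protocol.silencing_onset_h is not None:
                child = child[child / 3600.0 < protocol.silencing_onset_h[j]]
            if len(child):
                children.setdefault(j, []).append(child)
        if not children:
            break
        current = {j: np.concatenate(v) for j, v in sorted(children.items())}
        for j, v in current.items():
            per_unit[j].append(v)

    trains = [enforce_refractory(np.concatenate(v)) for v in per_unit]

    # inhibitory suppression: deletion in a short window at the edge delay
    inh_edges = [
        (int(i), int(j), gt.adjacency[i, j], gt.delay_ms[i, j])
        for i, j in zip(src, tgt)
        if inh[i]
    ]
    if inh_edges:
        pre = [t.copy() for t in trains]
        delete: dict[int, list] = {}
        for i, j, w, d_ms in inh_edges:
            ti, tj = pre[i], pre[j]
            if len(ti) == 0 or len(tj) == 0:
                continue
            lo = np.searchsorted(tj, ti + d_ms / 1e3, side="left")
            hi = np.searchsorted(tj, ti + d_ms / 1e3 + INHIBITION_WINDOW_S, side="left")
            _, owner = _ragged_gather(tj, lo, hi)
            if len(owner) == 0:
                continue
            spans = hi - lo
            cand_idx = np.concatenate(
                [np.arange(a, b) for a, b in zip(lo, hi) if b > a]
            )
            p = w * protocol.efficacy(np.repeat(ti, spans) / 3600.0)
            hit = cand_idx[rng_casc.random(len(cand_idx)) < p]
            if len(hit):
                delete.setdefault(j, []).append(hit)
        for j, hits in delete.items():
            mask = np.ones(len(trains[j]), dtype=bool)
            mask[np.unique(np.concatenate(hits))] = False
            trains[j] = trains[j][mask]

    unit_ids = np.concatenate(
        [np.full(len(t), u, dtype=np.int32) for u, t in enumerate(trains)]
    )
    times = np.concatenate(trains) if trains else np.empty(0)
    order = np.argsort(times, kind="stable")
    times, unit_ids = times[order], unit_ids[order]
    electrodes = gt.unit_electrode[unit_ids].astype(np.int32)

    if duration_h == protocol.timeline.duration_h:
        timeline = protocol.timeline
    else:
        kept = []
        for ph in protocol.timeline.phases:
            if ph.start_h >= duration_h:
                break
            kept.append(Phase(ph.label, ph.start_h, min(ph.end_h, duration_h)))
        timeline = PhaseTimeline(kept, stim_minutes=protocol.timeline.stim_minutes)

    wf = None
    if with_waveforms:
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        wf = _make_waveforms(unit_ids, times, gt, protocol, noise_sd, rng_noise)

    spikes = pd.DataFrame(
        {"time_s": times, "electrode": electrodes, "unit": unit_ids}
    )
    n_elec = max(60, int(gt.unit_electrode.max()) + 1)
    return Recording(
        spikes,
        timeline,
        waveforms=wf,
        ground_truth=gt,
        n_electrodes=n_elec,
    )


# ---------------------------------------------------------------------------
# stimulus responses


def simulate_stimulus_responses(
    gt: NetworkGroundTruth,
    schedule: StimulationSchedule,
    protocol: HypoxiaProtocol,
    seed: int = 0,
    spontaneous: Optional[Recording] = None,
    noise_sd: float = 4.0,
) -> Recording:
    """Evoked spikes from the schedule's response kernel, merged with
    spontaneous activity.

    Early (direct) spikes occur with a fixed probability per pulse at
    2-12 ms; late (synaptically relayed) spike counts are Poisson with a
    mean that scales with the protocol efficacy at the pulse time, with
    latencies spread over 15-150 ms.
    """
    if schedule.kernel is None:
        raise ValueError("schedule carries no response kernel")
    ss = np.random.SeedSequence(seed)
    s_spont, s_evoked, s_noise = ss.spawn(3)
    if spontaneous is None:
        spontaneous = simulate_spontaneous(
            gt, protocol, seed=seed + 1, noise_sd=noise_sd
        )
    duration_s = spontaneous.duration_s
    rng = np.random.default_rng(s_evoked)
    kern = schedule.kernel
    ev_times, ev_units = [], []
    for s_idx, e in enumerate(schedule.stim_electrodes):
        pulses = schedule.pulse_times[e]
        if len(pulses) and pulses.max() > duration_s:
            raise ValueError("stimulation schedule extends beyond the recording")
        early_p = kern.early_prob[s_idx]
        late_mu = kern.late_mean[s_idx]
        for t0 in pulses:
            eff = protocol.efficacy(t0 / 3600.0)
            direct = np.where(rng.random(gt.n_units) < early_p)[0]
            if len(direct):
                lat = 0.002 + 0.010 * rng.beta(2.0, 2.0, size=len(direct))
                ev_times.append(t0 + lat)
                ev_units.append(direct)
            counts = rng.poisson(late_mu * eff)
            total = int(counts.sum())
            if total:
                lat = 0.015 + 0.135 * rng.beta(2.0, 4.0, size=total)
                ev_times.append(t0 + lat)
                ev_units.append(np.repeat(np.arange(gt.n_units), counts))
    if ev_times:
        times = np.concatenate(ev_times)
        units = np.concatenate(ev_units).astype(np.int32)
        keep = times < duration_s
        times, units = times[keep], units[keep]
        if protocol.silencing_onset_h is not None:
            alive = times / 3600.0 < protocol.silencing_onset_h[units]
            times, units = times[alive], units[alive]
    else:
        times = np.empty(0)
        units = np.empty(0, dtype=np.int32)
    order = np.argsort(times, kind="stable")
    times, units = times[order], units[order]
    wf = None
    if spontaneous.waveforms is not None:
        wf = _make_waveforms(
            units, times, gt, protocol, noise_sd, np.random.default_rng(s_noise)
        )
    evoked = Recording(
        pd.DataFrame(
            {
                "time_s": times,
                "electrode": gt.unit_electrode[units].astype(np.int32)
                if len(units)
                else np.empty(0, np.int32),
                "unit": units,
            }
        ),
        spontaneous.timeline,
        waveforms=wf,
        n_electrodes=spontaneous.n_electrodes,
    )
    merged = merge_recordings(spontaneous, evoked)
    merged = _dedupe_refractory(merged)
    merged.schedule = schedule
    merged.ground_truth = gt
    return merged


def _dedupe_refractory(rec: Recording, refractory_s: float = REFRACTORY_S) -> Recording:
    """Drop per-unit refractory violations introduced by merging."""
    t = rec.spikes["time_s"].to_numpy()
    u = rec.spikes["unit"].to_numpy()
    keep = np.ones(len(t), dtype=bool)
    for unit in np.unique(u):
        rows = np.where(u == unit)[0]
        if unit < 0 or len(rows) < 2:
            continue
        kept = enforce_refractory(t[rows], refractory_s)
        # mark rows whose time survives (greedy rule keeps earliest of a chain)
        keep[rows] = np.isin(t[rows], kept)
    return rec.select(keep)


# ---------------------------------------------------------------------------
# raw traces


def render_raw_traces(
    rec: Recording,
    noise_sd: float,
    seed: int = 0,
    electrodes=None,
    fs: Optional[float] = None,
) -> dict:
    """Per-electrode sampled voltage traces: templates at spike times + noise.

    Overlapping placements are summed. Intended for short segments (a few
    minutes at most): one hour of one electrode is 57.6 M samples.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fs = fs or rec.fs
    gt = rec.ground_truth
    n_samples = int(round(rec.duration_s * fs))
    rng = np.random.default_rng(seed)
    if electrodes is None:
        electrodes = sorted(rec.spikes["electrode"].unique())
    traces = {}
    for e in electrodes:
        trace = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else np.zeros(n_samples)
        sel = rec.spikes["electrode"] == e
        times = rec.spikes.loc[sel, "time_s"].to_numpy()
        units = rec.spikes.loc[sel, "unit"].to_numpy()
        rows = np.where(sel.to_numpy())[0]
        for t, u, row in zip(times, units, rows):
            if gt is not None and u >= 0:
                tmpl = gt.templates[u]
                m = float(_morph_factor_scalar(rec, u, t / 3600.0))
                if m > 0:
                    tmpl = morph_template(tmpl, m)
            elif rec.waveforms is not None:
                tmpl = rec.waveforms[row]
            else:
                raise ValueError("no template available for spiking unit")
            start = int(round(t * fs)) - PEAK_INDEX
            a = max(start, 0)
            b = min(start + CUTOUT_SAMPLES, n_samples)
            if b > a:
                trace[a:b] += tmpl[a - start : b - start]
        traces[int(e)] = trace
    return traces


def _morph_factor_scalar(rec: Recording, unit: int, t_h: float) -> float:
    # Recording does not carry the protocol; raw-trace rendering of morphing
    # scenarios goes through simulate_spontaneous's stored waveforms instead.
    return 0.0
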