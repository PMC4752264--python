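"""End-to-end experiment orchestration.

``run_experiment`` drives a full analysis -- simulate (or load) a
recording, then compute AWFR, per-block connectivity with similarity
indices and baseline-normalized strengths, waveform tracks and fates,
E/I unit profiles and A_syn series -- and emits tidy tables plus a JSON
manifest of seeds and parameters. Group summaries are mean +- SEM per
time bin, with per-replicate normalization applied before averaging.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import compute_awfr, flag_focal_electrodes
from .connectivity import (
    block_connectivity,
    connection_count,
    matrices_to_frame,
    normalize_strengths,
    partition_blocks,
    si_series,
)
from .ei_classification import classify_units, fate_table, profiles_to_frame
from .recording import Recording
from .stimulus_response import asyn_series, normalize_asyn
from .synthetic_mea import (
    HypoxiaProtocol,
    NetworkGroundTruth,
    ResponseKernel,
    StimulationSchedule,
    simulate_stimulus_responses,
)
from .timeline import PhaseTimeline
from .waveforms import assign_fate, single_neuron_screen, track_shape, track_to_frame


@dataclass
class ExperimentConfig:
    """Fully serializable description of one simulated experiment run."""

    seed: int = 0
    # protocol
    baseline_h: float = 2.0
    hypoxia_h: float = 6.0
    recovery_h: float = 3.0
    efficacy_min: float = 0.5
    # network
    n_units: int = 60
    n_electrodes: int = 60
    frac_inhibitory: float = 0.2
    n_intrinsic: int = 0
    edge_prob: float = 0.05
    exc_rate_range: tuple = (0.5, 2.0)
    # stimulation
    n_stim_electrodes: int = 2
    pulses_per_electrode: int = 40
    total_late_mean: float = 15.0
    # generation
    with_waveforms: bool = True
    noise_sd: float = 4.0
    # analysis
    awfr_bin_min: float = 30.0
    block_size: int = 10000
    active_min: int = 50
    min_connections: int = 30
    tau_bin_ms: float = 0.5
    tau_max_ms: float = 500.0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exc_rate_range"] = list(d["exc_rate_range"])
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "exc_rate_range" in d:
            d["exc_rate_range"] = tuple(d["exc_rate_range"])
        return cls(**d)

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultBundle:
    config: ExperimentConfig
    recording: Recording
    awfr: pd.DataFrame
    focal_electrodes: list
    connectivity: pd.DataFrame
    si: pd.DataFrame
    strengths_norm: pd.DataFrame
    connectivity_excluded: bool
    tracks: pd.DataFrame
    profiles: pd.DataFrame
    fates: pd.DataFrame
    asyn: pd.DataFrame
    manifest: dict

    def tables(self) -> dict:
        return {
            "awfr": self.awfr,
            "connectivity": self.connectivity,
            "si": self.si,
            "strengths_norm": self.strengths_norm,
            "tracks": self.tracks,
            "profiles": self.profiles,
            "fates": self.fates,
            "asyn": self.asyn,
        }


def build_recording(config: ExperimentConfig) -> Recording:
    """Simulate the recording described by the config (seeded)."""
    gt = NetworkGroundTruth.random(
        n_units=config.n_units,
        n_electrodes=config.n_electrodes,
        frac_inhibitory=config.frac_inhibitory,
        n_intrinsic=config.n_intrinsic,
        edge_prob=config.edge_prob,
        exc_rate_range=config.exc_rate_range,
        seed=config.seed,
    )
    timeline = PhaseTimeline.standard(
        baseline_h=config.baseline_h,
        hypoxia_h=config.hypoxia_h,
        recovery_h=config.recovery_h,
    )
    protocol = HypoxiaProtocol(timeline, efficacy_min=config.efficacy_min)
    stim_electrodes = list(range(config.n_stim_electrodes))
    kernel = ResponseKernel.random(
        n_units=gt.n_units,
        n_stim=len(stim_electrodes),
        total_late_mean=config.total_late_mean,
        seed=config.seed + 10_000,
    )
    schedule = StimulationSchedule.hourly(
        stim_electrodes,
        timeline,
        pulses_per_electrode=config.pulses_per_electrode,
        kernel=kernel,
        seed=config.seed + 20_000,
    )
    from .synthetic_mea import simulate_spontaneous

    spont = simulate_spontaneous(
        gt,
        protocol,
        seed=config.seed + 30_000,
        with_waveforms=config.with_waveforms,
        noise_sd=config.noise_sd,
    )
    return simulate_stimulus_responses(
        gt,
        schedule,
        protocol,
        seed=config.seed + 40_000,
        spontaneous=spont,
        noise_sd=config.noise_sd,
    )


def run_experiment(
    config: ExperimentConfig,
    recording: Optional[Recording] = None,
    outdir: Optional[str] = None,
) -> ResultBundle:
    """Run the full analysis; optionally write tidy CSVs + manifest."""
    rec = recording if recording is not None else build_recording(config)

    awfr = compute_awfr(rec, bin_min=config.awfr_bin_min)
    focal = sorted(flag_focal_electrodes(rec))

    blocks = partition_blocks(
        rec, block_size=config.block_size, active_min=config.active_min
    )
    matrices = [
        block_connectivity(
            b,
            n_electrodes=rec.n_electrodes,
            tau_bin_ms=config.tau_bin_ms,
            tau_max_ms=config.tau_max_ms,
        )
        for b in blocks
    ]
    conn_df = matrices_to_frame(matrices)
    base_end = config.baseline_h
    baseline_matrices = [m for m in matrices if m.mid_h < base_end]
    baseline_ok = bool(baseline_matrices) and all(
        connection_count(m) >= config.min_connections for m in baseline_matrices
    )
    if baseline_ok:
        si = si_series(matrices, baseline_matrices[0], config.min_connections)
        norm = normalize_strengths(matrices, [m.block_index for m in baseline_matrices])
    else:
        si = pd.DataFrame(columns=["block", "mid_h", "si", "excluded"])
        norm = pd.DataFrame(
            columns=["block", "mid_h", "i", "j", "S", "T_ms", "S_norm", "is_new"]
        )

    tracks_rows, fates = [], {}
    single_neuron = []
    if rec.waveforms is not None:
        for e in range(rec.n_electrodes):
            res = single_neuron_screen(rec, e)
            if not res.is_single_neuron:
                continue
            single_neuron.append(e)
            try:
                track = track_shape(rec, e)
            except ValueError:
                continue
            fates[e] = assign_fate(track, rec.duration_h)
            tracks_rows.append(track_to_frame(track))
    tracks = (
        pd.concat(tracks_rows, ignore_index=True)
        if tracks_rows
        else pd.DataFrame(
            columns=["electrode", "hour", "n_spikes", "missing", "amplitude", "r_mean", "constant"]
        )
    )
    profiles = classify_units(rec, single_neuron, fates=fates)
    fate_df = fate_table(profiles)

    asyn_rows = []
    if rec.schedule is not None:
        for e in rec.schedule.stim_electrodes:
            asyn_rows.append(asyn_series(rec, e))
    asyn = (
        normalize_asyn(pd.concat(asyn_rows, ignore_index=True))
        if asyn_rows
        else pd.DataFrame(
            columns=["stim_electrode", "hour", "phase", "n_pulses", "A_syn", "A_syn_norm", "excluded"]
        )
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "config": config.to_dict(),
        "n_spikes": int(len(rec)),
        "n_blocks": len(blocks),
        "connectivity_excluded": not baseline_ok,
        "focal_electrodes": focal,
        "single_neuron_electrodes": single_neuron,
    }
    bundle = ResultBundle(
        config=config,
        recording=rec,
        awfr=awfr.table,
        focal_electrodes=focal,
        connectivity=conn_df,
        si=si,
        strengths_norm=norm,
        connectivity_excluded=not baseline_ok,
        tracks=tracks,
        profiles=profiles_to_frame(profiles),
        fates=fate_df,
        asyn=asyn,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: ResultBundle, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for name, df in bundle.tables().items():
        df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
    with open(os.path.join(outdir, "manifest.json"), "w") as f:
        json.dump(bundle.manifest, f, indent=2, sort_keys=True)


def summarize_group(
    tables: list[pd.DataFrame], value_col: str, key_col: str
) -> pd.DataFrame:
    """Group mean +- SEM per time bin over replicate tables.

    Each table is one replicate (already normalized within itself). Bins
    present in fewer than two replicates get a NaN SEM and a flag.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicates for a group summary")
    stacked = pd.concat(
        [df[[key_col, value_col]].assign(replicate=k) for k, df in enumerate(tables)],
        ignore_index=True,
    ).dropna(subset=[value_col])
    rows = []
    for key, grp in stacked.groupby(key_col):
        v = grp[value_col].to_numpy(dtype=float)
        n = len(v)
        rows.append(
            {
                key_col: key,
                "mean": v.mean(),
                "sem": v.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan,
                "n": n,
                "flagged": n < 2,
            }
        )
    return pd.DataFrame(rows)
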