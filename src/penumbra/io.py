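"""HDF5 and CSV persistence for recordings.

Layout of the HDF5 schema (all datasets optional except /spikes):

- ``/spikes/time_s`` float64, ``/spikes/electrode`` int32,
  ``/spikes/unit`` int32 (-1 = unknown), ``/spikes/waveform``
  (n, 96) float32
- ``/protocol/label`` (bytes), ``/protocol/start_h``, ``/protocol/end_h``
- ``/stim/electrodes``, ``/stim/pulse_electrode``, ``/stim/pulse_time_s``
- ``/ground_truth/{unit_electrode, unit_class, base_rate, adjacency,
  delay_ms, templates}``
- root attrs: ``fs``, ``n_electrodes``, ``stim_minutes``
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .recording import Recording, spike_frame
from .timeline import Phase, PhaseTimeline

_CLASS_CODES = {"excitatory": 0, "inhibitory": 1, "intrinsic": 2}
_CODE_CLASSES = {v: k for k, v in _CLASS_CODES.items()}


def write_recording(path: str, rec: Recording) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["fs"] = rec.fs
        f.attrs["n_electrodes"] = rec.n_electrodes
        f.attrs["stim_minutes"] = rec.timeline.stim_minutes
        g = f.create_group("spikes")
        g.create_dataset("time_s", data=rec.spikes["time_s"].to_numpy(np.float64))
        g.create_dataset("electrode", data=rec.spikes["electrode"].to_numpy(np.int32))
        g.create_dataset("unit", data=rec.spikes["unit"].to_numpy(np.int32))
        if rec.waveforms is not None:
            g.create_dataset(
                "waveform", data=np.asarray(rec.waveforms, dtype=np.float32)
            )
        p = f.create_group("protocol")
        p.create_dataset(
            "label",
            data=np.array([ph.label.encode() for ph in rec.timeline.phases]),
        )
        p.create_dataset(
            "start_h", data=np.array([ph.start_h for ph in rec.timeline.phases])
        )
        p.create_dataset(
            "end_h", data=np.array([ph.end_h for ph in rec.timeline.phases])
        )
        sched = rec.schedule
        if sched is not None:
            s = f.create_group("stim")
            s.create_dataset(
                "electrodes", data=np.asarray(sched.stim_electrodes, dtype=np.int32)
            )
            elec, times = [], []
            for e in sched.stim_electrodes:
                t = sched.pulse_times[e]
                elec.append(np.full(len(t), e, dtype=np.int32))
                times.append(t)
            s.create_dataset("pulse_electrode", data=np.concatenate(elec))
            s.create_dataset("pulse_time_s", data=np.concatenate(times))
        gt = rec.ground_truth
        if gt is not None:
            h = f.create_group("ground_truth")
            h.create_dataset("unit_electrode", data=gt.unit_electrode.astype(np.int32))
            h.create_dataset(
                "unit_class",
                data=np.array([_CLASS_CODES[c] for c in gt.unit_class], dtype=np.int8),
            )
            h.create_dataset("base_rate", data=gt.base_rate)
            h.create_dataset("adjacency", data=gt.adjacency)
            h.create_dataset("delay_ms", data=gt.delay_ms)
            h.create_dataset("templates", data=gt.templates.astype(np.float32))


def read_recording(path: str) -> Recording:
    import h5py

    from .synthetic_mea import NetworkGroundTruth, StimulationSchedule

    with h5py.File(path, "r") as f:
        g = f["spikes"]
        spikes = spike_frame(g["time_s"][:], g["electrode"][:], g["unit"][:])
        waveforms = g["waveform"][:] if "waveform" in g else None
        p = f["protocol"]
        phases = [
            Phase(lbl.decode(), float(s), float(e))
            for lbl, s, e in zip(p["label"][:], p["start_h"][:], p["end_h"][:])
        ]
        timeline = PhaseTimeline(phases, stim_minutes=float(f.attrs["stim_minutes"]))
        schedule = None
        if "stim" in f:
            s = f["stim"]
            electrodes = [int(e) for e in s["electrodes"][:]]
            pe, pt = s["pulse_electrode"][:], s["pulse_time_s"][:]
            pulse_times = {e: np.sort(pt[pe == e]) for e in electrodes}
            schedule = StimulationSchedule(electrodes, pulse_times)
        gt = None
        if "ground_truth" in f:
            h = f["ground_truth"]
            gt = NetworkGroundTruth(
                unit_electrode=h["unit_electrode"][:].astype(int),
                unit_class=[_CODE_CLASSES[int(c)] for c in h["unit_class"][:]],
                base_rate=h["base_rate"][:],
                adjacency=h["adjacency"][:],
                delay_ms=h["delay_ms"][:],
                templates=h["templates"][:].astype(np.float64),
            )
        return Recording(
            spikes,
            timeline,
            waveforms=waveforms,
            schedule=schedule,
            ground_truth=gt,
            n_electrodes=int(f.attrs["n_electrodes"]),
            fs=float(f.attrs["fs"]),
        )


def spikes_to_csv(path: str, rec: Recording, include_waveforms: bool = False) -> None:
    """Write the spike table as tidy CSV (optionally with 96 sample columns)."""
    df = rec.spikes.copy()
    if include_waveforms and rec.waveforms is not None:
        wf = pd.DataFrame(
            np.asarray(rec.waveforms),
            columns=[f"s{i:02d}" for i in range(rec.waveforms.shape[1])],
        )
        df = pd.concat([df, wf], axis=1)
    df.to_csv(path, index=False)


def spikes_from_csv(path: str, timeline: PhaseTimeline, **kwargs) -> Recording:
    df = pd.read_csv(path)
    wf_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    waveforms = df[wf_cols].to_numpy(np.float32) if len(wf_cols) == 96 else None
    spikes = spike_frame(df["time_s"], df["electrode"], df["unit"])
    return Recording(spikes, timeline, waveforms=waveforms, **kwargs)
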