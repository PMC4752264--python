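import numpy as np
import pandas as pd
import pytest

from penumbra import (
    HypoxiaProtocol,
    NetworkGroundTruth,
    PhaseTimeline,
    Recording,
    make_template,
)
from penumbra.recording import spike_frame
from penumbra.timeline import Phase


def make_ground_truth(
    n_units,
    classes=None,
    base_rate=1.0,
    adjacency=None,
    delay_ms=None,
    seed=0,
    **kwargs,
):
    """Small explicit ground truth for fixtures."""
    rng = np.random.default_rng(seed)
    if classes is None:
        classes = ["excitatory"] * n_units
    if np.isscalar(base_rate):
        base_rate = np.full(n_units, float(base_rate))
    if adjacency is None:
        adjacency = np.zeros((n_units, n_units))
    if delay_ms is None:
        delay_ms = np.where(np.asarray(adjacency) > 0, 5.0, 0.0)
    templates = np.stack(
        [make_template(amplitude=rng.uniform(60, 100)) for _ in range(n_units)]
    )
    return NetworkGroundTruth(
        unit_electrode=np.arange(n_units),
        unit_class=list(classes),
        base_rate=np.asarray(base_rate, dtype=float),
        adjacency=np.asarray(adjacency, dtype=float),
        delay_ms=np.asarray(delay_ms, dtype=float),
        templates=templates,
        **kwargs,
    )


def recording_from_arrays(
    time_s, electrode, timeline=None, waveforms=None, unit=None, **kwargs
):
    """Build a Recording straight from arrays (sorted internally)."""
    time_s = np.asarray(time_s, dtype=float)
    order = np.argsort(time_s, kind="stable")
    df = spike_frame(time_s, np.asarray(electrode, int), unit)
    if waveforms is not None:
        waveforms = np.asarray(waveforms)[order]
    if timeline is None:
        dur_h = max(time_s.max() / 3600.0 + 1e-6, 1.0) if len(time_s) else 1.0
        timeline = PhaseTimeline([Phase("baseline", 0.0, dur_h)], stim_minutes=0.0)
    return Recording(df, timeline, waveforms=waveforms, **kwargs)


@pytest.fixture
def normoxic_1h():
    return HypoxiaProtocol.normoxic(1.0)


@pytest.fixture
def template():
    return make_template(amplitude=80.0)
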