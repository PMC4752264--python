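"""Array-wide firing rate (AWFR) and per-electrode activity measures.

The AWFR is the summed spike count of all electrodes in 30-min bins,
normalized to its average over complete baseline bins so that cultures
with very different absolute activity can be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording


@dataclass
class AWFRSeries:
    """Binned array-wide firing rate.

    ``table`` columns: ``bin_start_h``, ``phase``, ``count``,
    ``normalized``, ``complete``. ``baseline_undefined`` is set when the
    baseline phase contains no spikes (normalization impossible); the
    normalized column is then NaN.
    """

    table: pd.DataFrame
    bin_min: float
    baseline_mean: float
    baseline_undefined: bool

    def phase_values(self, phase: str, complete_only: bool = True) -> np.ndarray:
        df = self.table[self.table["phase"] == phase]
        if complete_only:
            df = df[df["complete"]]
        return df["normalized"].to_numpy()


def compute_awfr(rec: Recording, bin_min: float = 30.0) -> AWFRSeries:
    """Array-wide firing rate in ``bin_min``-minute bins, baseline-normalized.

    Bins are aligned to the experiment start. A partial trailing bin is
    reported but excluded from all normalization statistics. The divisor
    is the mean count over complete baseline-phase bins.
    """
    bin_h = bin_min / 60.0
    dur_h = rec.duration_h
    if dur_h < bin_h:
        raise ValueError("recording shorter than one bin")
    n_bins = int(np.ceil(dur_h / bin_h - 1e-9))
    edges_h = np.arange(n_bins + 1) * bin_h
    t_h = rec.spikes["time_s"].to_numpy() / 3600.0
    counts, _ = np.histogram(t_h, bins=edges_h)
    complete = edges_h[1:] <= dur_h + 1e-9
    phases = rec.timeline.phase_of(edges_h[:-1])
    base_span = rec.timeline.span("baseline")
    baseline_bins = np.zeros(n_bins, dtype=bool)
    if base_span is not None:
        baseline_bins = (
            (edges_h[:-1] >= base_span[0] - 1e-9)
            & (edges_h[1:] <= base_span[1] + 1e-9)
            & complete
        )
    if baseline_bins.any() and counts[baseline_bins].sum() > 0:
        baseline_mean = float(counts[baseline_bins].mean())
        undefined = False
    else:
        baseline_mean = np.nan
        undefined = True
    normalized = counts / baseline_mean if not undefined else np.full(n_bins, np.nan)
    table = pd.DataFrame(
        {
            "bin_start_h": edges_h[:-1],
            "phase": phases,
            "count": counts,
            "normalized": normalized,
            "complete": complete,
        }
    )
    return AWFRSeries(table, bin_min, baseline_mean, undefined)


def electrode_rates(rec: Recording, span_h: tuple[float, float]) -> np.ndarray:
    """Mean firing rate (spikes/s) per electrode over the span (hours)."""
    t_h = rec.spikes["time_s"].to_numpy() / 3600.0
    sel = (t_h >= span_h[0]) & (t_h < span_h[1])
    elec = rec.spikes["electrode"].to_numpy()[sel]
    counts = np.bincount(elec, minlength=rec.n_electrodes)
    dur_s = (span_h[1] - span_h[0]) * 3600.0
    return counts / dur_s


def flag_focal_electrodes(
    rec: Recording,
    rate_factor: float = 1.0,
    array_median_max: float = 0.75,
) -> set[int]:
    """Electrodes with focally increased activity during hypoxia.

    An electrode is flagged when its hypoxia-phase mean rate exceeds
    ``rate_factor`` times its baseline rate *while* the median normalized
    rate of the remaining electrodes is below ``array_median_max`` --
    i.e. isolated hot spots on a globally suppressed array (tonic,
    disinhibited units). Globally elevated activity flags nothing.
    """
    base_span = rec.timeline.span("baseline")
    hyp_span = rec.timeline.span("hypoxia")
    if base_span is None or hyp_span is None:
        return set()
    base = electrode_rates(rec, base_span)
    hyp = electrode_rates(rec, hyp_span)
    active = base > 0
    ratio = np.full(rec.n_electrodes, np.nan)
    ratio[active] = hyp[active] / base[active]
    flagged: set[int] = set()
    for e in range(rec.n_electrodes):
        if not active[e] or not hyp[e] > rate_factor * base[e]:
            continue
        others = np.array([k for k in range(rec.n_electrodes) if k != e and active[k]])
        if len(others) == 0:
            continue
        if np.median(ratio[others]) < array_median_max:
            flagged.add(e)
    return flagged


def awfr_to_csv(series: AWFRSeries, path: str) -> None:
    series.table.to_csv(path, index=False)
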