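"""Excitatory/inhibitory classification by spike-count Fano factor.

The Fano factor used here is the ratio of the standard deviation (not the
variance) to the mean of spike counts in 6-s bins. Reference
distributions from paired patch-clamp/MEA work give excitatory units
3.17 +- 2.02 and inhibitory units 29.37 +- 8.45, so the class thresholds
are mean + 2 SD = 7.21 (below: excitatory) and mean - 2 SD = 12.47
(above: inhibitory); values in between are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

#: Reference Fano-factor distributions (mean, SD) per class.
EXCITATORY_REFERENCE = (3.17, 2.02)
INHIBITORY_REFERENCE = (29.37, 8.45)

EI_CLASSES = ("excitatory", "inhibitory", "unknown")


@dataclass
class UnitProfile:
    electrode: int
    fano: float
    ei_class: str
    fate: Optional[str] = None


def compute_thresholds(
    mean_exc: float, sd_exc: float, mean_inh: float, sd_inh: float
) -> tuple[float, float]:
    """(upper excitatory, lower inhibitory) bounds: mean +- 2 SD."""
    return mean_exc + 2.0 * sd_exc, mean_inh - 2.0 * sd_inh


DEFAULT_THRESHOLDS = compute_thresholds(*EXCITATORY_REFERENCE, *INHIBITORY_REFERENCE)


def fano_factor(
    spike_times: np.ndarray,
    window_s: tuple[float, float],
    bin_s: float = 6.0,
    min_bins: int = 10,
) -> float:
    """SD/mean of spike counts in ``bin_s`` bins over the window.

    Only complete bins are used; the sample SD (n-1 denominator) is
    taken. For a homogeneous Poisson train with per-bin mean mu this
    converges to 1/sqrt(mu).
    """
    t0, t1 = window_s
    n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
    if n_bins < min_bins:
        raise ValueError(f"window holds {n_bins} complete bins, need >= {min_bins}")
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= t0) & (t < t0 + n_bins * bin_s)]
    counts, _ = np.histogram(t, bins=n_bins, range=(t0, t0 + n_bins * bin_s))
    mean = counts.mean()
    if mean == 0:
        raise ValueError("zero mean count: Fano factor undefined")
    return float(counts.std(ddof=1) / mean)


def classify(fano: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    upper_exc, lower_inh = thresholds
    if fano < upper_exc:
        return "excitatory"
    if fano > lower_inh:
        return "inhibitory"
    return "unknown"


def classify_units(
    rec,
    electrodes,
    bin_s: float = 6.0,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    fates: Optional[dict] = None,
) -> list[UnitProfile]:
    """Profile the given (single-neuron) electrodes on the baseline phase.

    Classification deliberately precedes the hypoxic perturbation: counts
    are taken over the baseline phase only.
    """
    span = rec.timeline.span("baseline")
    if span is None:
        raise ValueError("timeline has no baseline phase")
    window = (span[0] * 3600.0, span[1] * 3600.0)
    profiles = []
    for e in electrodes:
        times = rec.times(electrode=e)
        try:
            f = fano_factor(times, window, bin_s=bin_s)
            cls = classify(f, thresholds)
        except ValueError:
            f, cls = np.nan, "unknown"
        profiles.append(
            UnitProfile(
                electrode=int(e),
                fano=f,
                ei_class=cls,
                fate=None if fates is None else fates.get(int(e)),
            )
        )
    return profiles


def fate_table(profiles: list[UnitProfile]) -> pd.DataFrame:
    """Counts and exact fractions of each fate within each E/I class.

    Fractions are computed with rational arithmetic before being exposed
    as floats; an empty class yields NaN fractions and ``flagged = True``.
    """
    from .waveforms import FATES

    rows = []
    for cls in EI_CLASSES:
        members = [p for p in profiles if p.ei_class == cls]
        total = len(members)
        for fate in FATES:
            n = sum(1 for p in members if p.fate == fate)
            frac = Fraction(n, total) if total else None
            rows.append(
                {
                    "ei_class": cls,
                    "fate": fate,
                    "count": n,
                    "class_total": total,
                    "fraction": float(frac) if frac is not None else np.nan,
                    "flagged": total == 0,
                }
            )
    return pd.DataFrame(rows)


def class_counts(profiles: list[UnitProfile]) -> dict[str, int]:
    return {cls: sum(1 for p in profiles if p.ei_class == cls) for cls in EI_CLASSES}


def excitatory_inhibitory_ratio(profiles: list[UnitProfile]) -> Fraction:
    """Exact excitatory : inhibitory count ratio."""
    counts = class_counts(profiles)
    if counts["inhibitory"] == 0:
        raise ValueError("no inhibitory units: ratio undefined")
    return Fraction(counts["excitatory"], counts["inhibitory"])


def profiles_to_frame(profiles: list[UnitProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "electrode": p.electrode,
                "fano": p.fano,
                "ei_class": p.ei_class,
                "fate": p.fate,
            }
            for p in profiles
        ]
    )
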