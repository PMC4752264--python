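"""Functional connectivity from conditional firing probabilities (CFP).

Long recordings are cut into data blocks of exactly 10,000 spikes; within
each block, for every ordered pair of active electrodes (>= 50 spikes in
the block), CFP_ij[tau] is the probability that electrode j fires in the
tau bin given a spike on electrode i at time 0. A functional connection
is summarized by its strength S (the CFP peak) and latency T (the delay
of the peak); the connection count N = |{S != 0}| and the similarity
index SI = |{S_A != 0} n {S_B != 0}|^2 / (|{S_A != 0}| |{S_B != 0}|)
compare connection sets across blocks.

Peak significance
-----------------
Whether a CFP peak counts as a connection is decided by a calibrated null
rule: the chance level lambda (followers per bin) is estimated from the
tail of the tau window (last 20%), and the peak's follower count must
exceed the Bonferroni-corrected upper Poisson tail across all bins at a
nominal pair-level alpha (default 0.05), with an absolute floor of 5
follower events. A fixed per-bin z-threshold would not control the
false-positive level, because the peak is a maximum over ~1000 bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .recording import Recording


@dataclass
class DataBlock:
    """Contiguous slice of exactly ``block_size`` spikes."""

    index: int
    spikes: pd.DataFrame
    active_electrodes: list[int]
    start_s: float
    end_s: float

    @property
    def mid_h(self) -> float:
        return 0.5 * (self.start_s + self.end_s) / 3600.0

    def electrode_times(self, electrode: int) -> np.ndarray:
        sel = self.spikes["electrode"] == electrode
        return self.spikes.loc[sel, "time_s"].to_numpy()


@dataclass
class CFPSet:
    """CFP curves for all ordered active pairs of one data block."""

    block_index: int
    active: list[int]
    tau_bin_ms: float
    tau_max_ms: float
    curves: dict  # (i, j) -> probability per tau bin
    n_conditioning: dict  # i -> number of i spikes in the block

    @property
    def n_bins(self) -> int:
        return int(round(self.tau_max_ms / self.tau_bin_ms))


@dataclass
class ConnectivityMatrix:
    """Strengths S and latencies T (ms) for one data block; 0 = no connection."""

    S: np.ndarray
    T: np.ndarray
    block_index: int
    mid_h: float = np.nan

    @property
    def N(self) -> int:
        """Connection count: number of nonzero strengths."""
        return connection_count(self)

    def nonzero_set(self) -> np.ndarray:
        return self.S != 0


def partition_blocks(
    rec: Recording, block_size: int = 10000, active_min: int = 50
) -> list[DataBlock]:
    """Cut the recording into blocks of exactly ``block_size`` spikes.

    The trailing remainder is dropped. Each block carries its own active
    electrode set (electrodes with at least ``active_min`` spikes in it).
    """
    n = len(rec.spikes)
    n_blocks = n // block_size
    if n_blocks == 0:
        warnings.warn(
            f"recording has {n} spikes, fewer than one {block_size}-spike block",
            stacklevel=2,
        )
        return []
    blocks = []
    for k in range(n_blocks):
        sl = rec.spikes.iloc[k * block_size : (k + 1) * block_size]
        counts = sl["electrode"].value_counts()
        active = sorted(int(e) for e, c in counts.items() if c >= active_min)
        blocks.append(
            DataBlock(
                index=k,
                spikes=sl.reset_index(drop=True),
                active_electrodes=active,
                start_s=float(sl["time_s"].iloc[0]),
                end_s=float(sl["time_s"].iloc[-1]),
            )
        )
    return blocks


def _bin_indices(dts: np.ndarray, bin_s: float) -> np.ndarray:
    # bin k covers (k*bin, (k+1)*bin]; a small epsilon guards against
    # floating-point dts landing exactly on a bin edge
    return np.ceil(dts / bin_s - 1e-9).astype(np.int64) - 1


def compute_cfp(
    block: DataBlock, tau_bin_ms: float = 0.5, tau_max_ms: float = 500.0
) -> CFPSet:
    """Conditional firing probabilities for all ordered active pairs.

    ``p[k] = #{i-spikes followed by >= 1 j-spike in bin k} / #{i-spikes}``
    where bin k covers ``(k*bin, (k+1)*bin]`` ms. Every i spike of the
    block conditions the estimate; simultaneous spikes (dt = 0) are not
    followers.
    """
    bin_s = tau_bin_ms / 1e3
    tau_max_s = tau_max_ms / 1e3
    n_bins = int(round(tau_max_ms / tau_bin_ms))
    times = {e: block.electrode_times(e) for e in block.active_electrodes}
    curves: dict = {}
    n_cond = {e: len(times[e]) for e in block.active_electrodes}
    for i in block.active_electrodes:
        ti = times[i]
        for j in block.active_electrodes:
            if i == j:
                continue
            tj = times[j]
            lo = np.searchsorted(tj, ti, side="right")
            hi = np.searchsorted(tj, ti + tau_max_s, side="right")
            spans = hi - lo
            total = int(spans.sum())
            p = np.zeros(n_bins)
            if total:
                cum = np.cumsum(spans)
                idx = np.arange(total) + np.repeat(
                    lo - np.concatenate(([0], cum[:-1])), spans
                )
                dts = tj[idx] - np.repeat(ti, spans)
                bins = _bin_indices(dts, bin_s)
                ok = (bins >= 0) & (bins < n_bins)
                owner = np.repeat(np.arange(len(ti)), spans)[ok]
                key = owner.astype(np.int64) * n_bins + bins[ok]
                uniq = np.unique(key)
                counts = np.bincount((uniq % n_bins).astype(int), minlength=n_bins)
                p = counts / len(ti)
            curves[(i, j)] = p
    return CFPSet(
        block_index=block.index,
        active=block.active_electrodes,
        tau_bin_ms=tau_bin_ms,
        tau_max_ms=tau_max_ms,
        curves=curves,
        n_conditioning=n_cond,
    )


def extract_connection(
    p: np.ndarray,
    n_conditioning: int,
    tau_bin_ms: float = 0.5,
    alpha: float = 0.05,
    min_support: int = 5,
    tail_fraction: float = 0.2,
) -> tuple[float, float]:
    """(S, T) of a CFP curve, or (0, nan) if the peak is not significant.

    The peak follower count must reach the Bonferroni-corrected upper
    Poisson tail of the chance level estimated from the last
    ``tail_fraction`` of the tau window, and never fewer than
    ``min_support`` follower events. The latency T is the upper edge of
    the peak bin (ms).
    """
    p = np.asarray(p, dtype=float)
    n_bins = len(p)
    if n_bins == 0 or n_conditioning == 0 or not np.any(p > 0):
        return 0.0, np.nan
    tail = p[int(np.floor(n_bins * (1 - tail_fraction))):]
    lam = float(tail.mean()) * n_conditioning
    peak_bin = int(np.argmax(p))
    peak_count = int(round(p[peak_bin] * n_conditioning))
    crit = stats.poisson.ppf(1.0 - alpha / n_bins, lam) + 1 if lam > 0 else 1
    threshold = max(min_support, int(crit))
    if peak_count >= threshold:
        return float(p[peak_bin]), (peak_bin + 1) * tau_bin_ms
    return 0.0, np.nan


def block_connectivity(
    block: DataBlock,
    n_electrodes: int = 60,
    tau_bin_ms: float = 0.5,
    tau_max_ms: float = 500.0,
    alpha: float = 0.05,
    min_support: int = 5,
    tail_fraction: float = 0.2,
) -> ConnectivityMatrix:
    """Full strength/latency matrix for one block."""
    cfp = compute_cfp(block, tau_bin_ms=tau_bin_ms, tau_max_ms=tau_max_ms)
    S = np.zeros((n_electrodes, n_electrodes))
    T = np.full((n_electrodes, n_electrodes), np.nan)
    for (i, j), p in cfp.curves.items():
        s, t = extract_connection(
            p,
            cfp.n_conditioning[i],
            tau_bin_ms=tau_bin_ms,
            alpha=alpha,
            min_support=min_support,
            tail_fraction=tail_fraction,
        )
        S[i, j] = s
        T[i, j] = t
    return ConnectivityMatrix(S=S, T=T, block_index=block.index, mid_h=block.mid_h)


def connection_count(matrix: ConnectivityMatrix) -> int:
    """N = |{S_ij != 0}|."""
    return int(np.count_nonzero(matrix.S))


def similarity_index(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """SI = |{S_A != 0} n {S_B != 0}|^2 / (|{S_A != 0}| |{S_B != 0}|).

    Symmetric, in [0, 1] (Cauchy-Schwarz on set sizes), 1 iff the
    connection sets coincide. NaN (undefined) when either block has no
    connections.
    """
    na = connection_count(a)
    nb = connection_count(b)
    if na == 0 or nb == 0:
        return float("nan")
    inter = int(np.count_nonzero(a.nonzero_set() & b.nonzero_set()))
    return inter**2 / (na * nb)


def si_series(
    matrices: list[ConnectivityMatrix],
    reference: ConnectivityMatrix,
    min_connections: int = 30,
) -> pd.DataFrame:
    """SI of each block vs a reference (e.g. a baseline block).

    Blocks (or the reference) with fewer than ``min_connections``
    connections are excluded, mirroring the inclusion rule for cultures
    with sufficient baseline activity.
    """
    rows = []
    ref_ok = connection_count(reference) >= min_connections
    for m in matrices:
        ok = ref_ok and connection_count(m) >= min_connections
        rows.append(
            {
                "block": m.block_index,
                "mid_h": m.mid_h,
                "si": similarity_index(m, reference) if ok else np.nan,
                "excluded": not ok,
            }
        )
    return pd.DataFrame(rows)


def normalize_strengths(
    matrices: list[ConnectivityMatrix], baseline_blocks: list[int]
) -> pd.DataFrame:
    """Per-connection strengths divided by their baseline-phase mean.

    The divisor for connection (i, j) is the mean of S_ij over the listed
    baseline blocks (zeros included), so the baseline mean of every
    normalized connection is exactly 1. Connections never present at
    baseline carry ``is_new = True`` and a NaN normalized strength.
    """
    base = [m for m in matrices if m.block_index in set(baseline_blocks)]
    if not base:
        raise ValueError("no baseline blocks available for normalization")
    base_mean = np.mean([m.S for m in base], axis=0)
    rows = []
    for m in matrices:
        ii, jj = np.nonzero(m.S)
        for i, j in zip(ii, jj):
            new = base_mean[i, j] == 0
            rows.append(
                {
                    "block": m.block_index,
                    "mid_h": m.mid_h,
                    "i": int(i),
                    "j": int(j),
                    "S": m.S[i, j],
                    "T_ms": m.T[i, j],
                    "S_norm": np.nan if new else m.S[i, j] / base_mean[i, j],
                    "is_new": bool(new),
                }
            )
    return pd.DataFrame(
        rows, columns=["block", "mid_h", "i", "j", "S", "T_ms", "S_norm", "is_new"]
    )


def matrices_to_frame(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Long-format (block, i, j, S, T) table of all nonzero connections."""
    rows = []
    for m in matrices:
        ii, jj = np.nonzero(m.S)
        for i, j in zip(ii, jj):
            rows.append(
                {
                    "block": m.block_index,
                    "mid_h": m.mid_h,
                    "i": int(i),
                    "j": int(j),
                    "S": m.S[i, j],
                    "T_ms": m.T[i, j],
                }
            )
    return pd.DataFrame(rows, columns=["block", "mid_h", "i", "j", "S", "T_ms"])
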