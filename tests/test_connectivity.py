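"""CFP connectivity: blocks, curves, connection extraction, SI, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penumbra import (
    ConnectivityMatrix,
    compute_cfp,
    connection_count,
    extract_connection,
    normalize_strengths,
    partition_blocks,
    similarity_index,
)
from penumbra.connectivity import DataBlock, si_series
from penumbra.timeline import Phase, PhaseTimeline

from conftest import recording_from_arrays


def make_block(times, electrodes, active=None, index=0):
    df = pd.DataFrame({"time_s": times, "electrode": electrodes, "unit": -1})
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    if active is None:
        active = sorted(df["electrode"].unique())
    return DataBlock(
        index=index,
        spikes=df,
        active_electrodes=[int(a) for a in active],
        start_s=float(df["time_s"].min()),
        end_s=float(df["time_s"].max()),
    )


def cfp_oracle(ti, tj, tau_bin_ms, tau_max_ms):
    """O(n^2) per-conditioning-spike pair counter (independent of the
    searchsorted implementation)."""
    bin_s = tau_bin_ms / 1e3
    nb = int(round(tau_max_ms / tau_bin_ms))
    p = np.zeros(nb)
    for t in ti:
        dt = tj - t
        dt = dt[(dt > 0) & (dt <= tau_max_ms / 1e3)]
        if len(dt) == 0:
            continue
        bins = np.unique(np.ceil(dt / bin_s - 1e-9).astype(int) - 1)
        bins = bins[(bins >= 0) & (bins < nb)]
        p[bins] += 1
    return p / len(ti)


def matrix_from_pairs(pairs, n=60, index=0, strength=0.5):
    S = np.zeros((n, n))
    T = np.full((n, n), np.nan)
    for i, j in pairs:
        S[i, j] = strength
        T[i, j] = 5.0
    return ConnectivityMatrix(S=S, T=T, block_index=index)


class TestPartitionBlocks:
    @staticmethod
    def _rec(n_spikes, n_electrodes=10):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 3600.0, n_spikes))
        e = rng.integers(0, n_electrodes, n_spikes)
        tl = PhaseTimeline([Phase("baseline", 0, 1)], stim_minutes=0.0)
        return recording_from_arrays(t, e, timeline=tl)

    def test_25000_spikes_two_blocks(self):
        blocks = partition_blocks(self._rec(25000))
        assert len(blocks) == 2
        assert all(len(b.spikes) == 10000 for b in blocks)

    def test_9999_spikes_zero_blocks_with_warning(self):
        with pytest.warns(UserWarning):
            assert partition_blocks(self._rec(9999)) == []

    def test_active_threshold_boundary_at_50(self):
        """49 spikes in a block -> excluded; 50 -> included."""
        t49 = np.linspace(0, 100, 49)
        t50 = np.linspace(0, 100, 50)
        filler = np.linspace(0, 100, 10000 - 99)
        times = np.concatenate([t49, t50, filler])
        elecs = np.concatenate(
            [np.zeros(49, int), np.ones(50, int), np.full(len(filler), 2)]
        )
        tl = PhaseTimeline([Phase("baseline", 0, 1)], stim_minutes=0.0)
        rec = recording_from_arrays(times, elecs, timeline=tl)
        blocks = partition_blocks(rec, active_min=50)
        assert blocks[0].active_electrodes == [1, 2]


class TestComputeCFP:
    def test_silent_target_all_zero(self):
        ti = np.linspace(1, 99, 200)
        tj = np.array([200.0] * 60)  # all after the window of every i spike
        blk = make_block(
            np.concatenate([ti, tj]),
            np.concatenate([np.zeros(200, int), np.ones(60, int)]),
        )
        cfp = compute_cfp(blk, tau_bin_ms=0.5, tau_max_ms=50.0)
        assert np.all(cfp.curves[(0, 1)] == 0)

    def test_deterministic_follower_peak_probability_one(self):
        """j fires exactly 5 ms after every i spike: p = 1 in the 5-ms bin."""
        ti = np.linspace(1, 99, 150)
        tj = ti + 0.005
        blk = make_block(
            np.concatenate([ti, tj]),
            np.concatenate([np.zeros(150, int), np.ones(150, int)]),
        )
        cfp = compute_cfp(blk, tau_bin_ms=0.5, tau_max_ms=50.0)
        p = cfp.curves[(0, 1)]
        assert p[9] == 1.0  # bin (4.5, 5.0]
        assert p.sum() == 1.0
        s, t = extract_connection(p, cfp.n_conditioning[0], tau_bin_ms=0.5)
        assert s == 1.0 and t == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        """Exact equality with the O(n^2) pair counter on random blocks."""
        rng = np.random.default_rng(1)
        for trial in range(10):
            n = int(rng.integers(300, 2000))
            t = np.sort(rng.uniform(0, 120.0, n))
            e = rng.integers(0, 6, n)
            blk = make_block(t, e)
            cfp = compute_cfp(blk, tau_bin_ms=0.5, tau_max_ms=50.0)
            for (i, j), p in cfp.curves.items():
                ti = blk.electrode_times(i)
                tj = blk.electrode_times(j)
                np.testing.assert_array_equal(p, cfp_oracle(ti, tj, 0.5, 50.0))

    def test_probabilities_bounded(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 60.0, 3000))
        e = rng.integers(0, 5, 3000)
        cfp = compute_cfp(make_block(t, e), tau_bin_ms=1.0, tau_max_ms=100.0)
        for p in cfp.curves.values():
            assert np.all((p >= 0) & (p <= 1))


class TestExtractConnection:
    def test_all_zero_curve_absent(self):
        s, t = extract_connection(np.zeros(1000), 200)
        assert s == 0.0 and np.isnan(t)

    def test_null_false_positive_rate(self):
        """Independent Poisson pairs pass the criterion in <= ~5% of runs."""
        rng = np.random.default_rng(3)
        fp = 0
        runs = 200
        for _ in range(runs):
            ti = np.sort(rng.uniform(0, 300.0, 600))
            tj = np.sort(rng.uniform(0, 300.0, 900))
            p = cfp_oracle(ti, tj, 0.5, 500.0)
            s, _ = extract_connection(p, len(ti), tau_bin_ms=0.5)
            fp += s > 0
        # consistent with a true rate <= 5%: 99.9% binomial upper bound
        from scipy.stats import binom

        assert fp <= binom.ppf(0.999, runs, 0.05)

    def test_minimum_support_floor(self):
        # a single follower event never counts, however clean the curve
        p = np.zeros(1000)
        p[10] = 1 / 60
        s, _ = extract_connection(p, 60, min_support=5)
        assert s == 0.0


class TestSimilarityIndex:
    def test_self_similarity_is_one(self):
        m = matrix_from_pairs([(0, 1), (2, 3), (4, 5)])
        assert similarity_index(m, m) == 1.0

    def test_disjoint_sets_zero(self):
        a = matrix_from_pairs([(0, 1), (2, 3)])
        b = matrix_from_pairs([(4, 5), (6, 7)])
        assert similarity_index(a, b) == 0.0

    def test_hand_example_quarter(self):
        """|A| = |B| = 4, |A n B| = 2 -> SI = 2^2 / (4*4) = 0.25."""
        a = matrix_from_pairs([(0, 1), (1, 2), (2, 3), (3, 4)])
        b = matrix_from_pairs([(0, 1), (1, 2), (5, 6), (7, 8)])
        assert similarity_index(a, b) == 0.25

    def test_empty_matrix_undefined(self):
        a = matrix_from_pairs([(0, 1)])
        empty = matrix_from_pairs([])
        assert np.isnan(similarity_index(a, empty))

    @given(st.integers(0, 2**30), st.floats(0.02, 0.3), st.floats(0.02, 0.3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_symmetry_on_random_pairs(self, seed, da, db):
        rng = np.random.default_rng(seed)
        a = matrix_from_pairs([], n=20)
        b = matrix_from_pairs([], n=20)
        a.S = (rng.random((20, 20)) < da).astype(float)
        b.S = (rng.random((20, 20)) < db).astype(float)
        si = similarity_index(a, b)
        if connection_count(a) == 0 or connection_count(b) == 0:
            assert np.isnan(si)
        else:
            assert 0.0 <= si <= 1.0
            assert si == similarity_index(b, a)

    def test_series_excludes_blocks_below_30_connections(self):
        big = matrix_from_pairs([(i, (i + 1) % 60) for i in range(40)], index=0)
        small = matrix_from_pairs([(i, (i + 2) % 60) for i in range(10)], index=1)
        df = si_series([big, small], reference=big, min_connections=30)
        assert not df.loc[df["block"] == 0, "excluded"].item()
        assert df.loc[df["block"] == 1, "excluded"].item()
        assert np.isnan(df.loc[df["block"] == 1, "si"].item())


class TestNormalizeStrengths:
    def test_constant_strengths_normalize_to_one(self):
        ms = [matrix_from_pairs([(0, 1)], index=k, strength=0.4) for k in range(3)]
        df = normalize_strengths(ms, baseline_blocks=[0])
        np.testing.assert_allclose(df["S_norm"], 1.0)

    def test_halved_strength_gives_half(self):
        base = matrix_from_pairs([(0, 1)], index=0, strength=0.4)
        hyp = matrix_from_pairs([(0, 1)], index=1, strength=0.2)
        df = normalize_strengths([base, hyp], baseline_blocks=[0])
        assert df.loc[df["block"] == 1, "S_norm"].item() == pytest.approx(0.5)

    def test_new_connection_flagged(self):
        base = matrix_from_pairs([(0, 1)], index=0)
        later = matrix_from_pairs([(0, 1), (5, 6)], index=1)
        df = normalize_strengths([base, later], baseline_blocks=[0])
        row = df[(df["block"] == 1) & (df["i"] == 5)]
        assert row["is_new"].item() and np.isnan(row["S_norm"].item())

    def test_no_baseline_blocks_rejected(self):
        with pytest.raises(ValueError):
            normalize_strengths([matrix_from_pairs([(0, 1)], index=5)], [0])


class TestConnectionCount:
    def test_zero_and_planted_counts(self):
        assert connection_count(matrix_from_pairs([])) == 0
        pairs = [(i, j) for i in range(10) for j in range(10) if i != j][:36]
        assert connection_count(matrix_from_pairs(pairs)) == 36
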