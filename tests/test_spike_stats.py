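"""Windowed spike-count statistics and the raster-processing rules."""

import numpy as np
import pandas as pd
import pytest

from obpcnet.spike_stats import (
    SpikeRaster,
    count_statistics,
    dedup_spikes,
    synth_correlated_trains,
    unit_rate_filter,
    window_counts,
    window_starts,
)


def make_raster(rows, trial_length=30.0, evoked_end=2.0):
    return SpikeRaster(pd.DataFrame(rows, columns=["unit", "trial", "time"]),
                       trial_length=trial_length, evoked_end=evoked_end)


class TestDedup:
    def test_near_coincident_pair_keeps_first(self):
        r = make_raster([(0, 0, 0.0000), (0, 0, 0.00005), (0, 0, 0.01)])
        out = dedup_spikes(r)
        assert out.table["time"].tolist() == [0.0, 0.01]

    def test_no_close_pairs_identity(self):
        times = [0.0, 0.01, 0.5, 1.0]
        r = make_raster([(0, 0, t) for t in times])
        assert dedup_spikes(r).table["time"].tolist() == times

    def test_burst_leaves_single_survivor(self):
        # sequential rule: all spikes within 0.1 ms of the running survivor go
        times = [0.1, 0.10004, 0.10008, 0.2]
        r = make_raster([(0, 0, t) for t in times])
        out = dedup_spikes(r)
        # brute-force oracle
        survivors, last = [], -np.inf
        for t in times:
            if t - last >= 1e-4:
                survivors.append(t)
                last = t
        assert out.table["time"].tolist() == survivors
        assert len(survivors) == 2

    def test_units_and_trials_independent(self):
        r = make_raster([(0, 0, 0.1), (1, 0, 0.10001), (0, 1, 0.10002)])
        assert len(dedup_spikes(r).table) == 3


class TestRateFilter:
    def test_boundaries_are_strict(self):
        # 10 trials x 30 s = 300 s of data per unit
        rows = []
        rows += [(0, tr, 0.5) for tr in range(10)][:1]            # ~0.0033 Hz -> drop
        rows += [(1, tr, t) for tr in range(10) for t in np.linspace(0.1, 29.9, 150)]
        rows += [(2, tr, t) for tr in range(10)
                 for t in np.linspace(0.01, 29.99, 1470)]          # exactly 49 Hz
        r = make_raster(rows)
        out = unit_rate_filter(r)
        kept = set(out.units)
        assert 0 not in kept          # 1/300 Hz < 0.008 Hz
        assert 1 in kept              # 5 Hz
        assert 2 in kept              # exactly 49 Hz: "above" is strict

    def test_too_fast_unit_removed(self):
        rows = [(0, tr, t) for tr in range(2)
                for t in np.linspace(0.001, 29.999, 1600)]         # ~53 Hz
        rows += [(1, 0, 1.0), (1, 1, 2.0)]
        out = unit_rate_filter(make_raster(rows))
        assert set(out.units) == {1}


class TestWindows:
    def test_three_windows_for_half_overlap(self):
        starts = window_starts(0.0, 2.0, 1.0, overlap="half")
        assert starts.tolist() == [0.0, 0.5, 1.0]

    def test_single_window_when_twin_equals_segment(self):
        assert window_starts(0.0, 2.0, 2.0).tolist() == [0.0]

    def test_too_large_window_rejected(self):
        with pytest.raises(ValueError):
            window_starts(0.0, 2.0, 2.5)

    def test_empty_train_gives_zero_counts(self):
        r = make_raster([(0, 0, 5.0)])   # spike in the spontaneous segment only
        units, counts = window_counts(r, "evoked", 1.0)
        assert counts.shape == (1, 3)
        assert np.all(counts == 0)

    def test_half_open_window_edges(self):
        # a spike exactly at t = 1.0 belongs to [1, 2) and [0.5, 1.5), not [0, 1)
        r = make_raster([(0, 0, 1.0)])
        _, counts = window_counts(r, "evoked", 1.0)
        assert counts[0].tolist() == [0, 1, 1]

    def test_counts_pooled_across_trials(self):
        rows = [(0, tr, 0.25) for tr in range(4)]
        _, counts = window_counts(make_raster(rows), "evoked", 1.0)
        assert counts.shape == (1, 12)
        assert counts.sum() == 4

    def test_disjoint_mode(self):
        starts = window_starts(0.0, 2.0, 0.5, overlap="none")
        assert len(starts) == 4


class TestCountStatistics:
    def test_hand_computed_covariance(self):
        # counts {2,4,6} and {1,2,3}: Cov = 2 (n-1 denominator), rho = 1
        counts = np.array([[2, 4, 6], [1, 2, 3]])
        cs = count_statistics(counts, t_win=1.0)
        assert cs.cov[0] == pytest.approx(2.0)
        assert cs.rho[0] == pytest.approx(1.0)
        assert cs.mean.tolist() == [4.0, 2.0]

    def test_identical_sequences_fully_correlated(self):
        counts = np.tile(np.array([3, 1, 4, 1, 5]), (2, 1))
        cs = count_statistics(counts, t_win=0.5)
        assert cs.rho[0] == pytest.approx(1.0)
        assert cs.rate.tolist() == [2.8 / 0.5] * 2

    def test_zero_variance_unit_gives_nan_rho(self):
        counts = np.array([[2, 2, 2], [1, 2, 3]])
        cs = count_statistics(counts, t_win=1.0)
        assert np.isnan(cs.rho[0])
        assert cs.cov[0] == pytest.approx(0.0)

    def test_requires_two_instances(self):
        with pytest.raises(ValueError):
            count_statistics(np.array([[1], [2]]), t_win=1.0)


class TestSyntheticTrains:
    def test_independent_poisson_fano_near_one_rho_near_zero(self):
        r = synth_correlated_trains(rate=5.0, rho_target=0.0, n_units=8,
                                    n_trials=60, seed=2)
        _, counts = window_counts(r, "spontaneous", 1.0)
        cs = count_statistics(counts, t_win=1.0)
        n = counts.shape[1]
        # Poisson: FF = 1 with SE ~ sqrt(2/n) per unit (overlap inflates
        # slightly); rho = 0 with SE ~ 1/sqrt(n)
        assert cs.ff.mean() == pytest.approx(1.0, abs=3 * np.sqrt(2 / n))
        assert abs(np.nanmean(cs.rho)) < 3 / np.sqrt(n)

    def test_target_correlation_recovered(self):
        r = synth_correlated_trains(rate=5.0, rho_target=0.3, n_units=6,
                                    n_trials=120, seed=7)
        _, counts = window_counts(r, "spontaneous", 1.0)
        cs = count_statistics(counts, t_win=1.0)
        assert np.nanmean(cs.rho) == pytest.approx(0.3, abs=0.03)

    def test_rates_match_request(self):
        r = synth_correlated_trains(rate=4.0, rho_target=0.2, n_units=5,
                                    n_trials=50, seed=3)
        total_time = 50 * 30.0
        rates = r.table.groupby("unit").size() / total_time
        assert rates.to_numpy() == pytest.approx([4.0] * 5, rel=0.05)

    def test_same_seed_identical(self):
        a = synth_correlated_trains(5.0, 0.3, 3, 5, seed=9)
        b = synth_correlated_trains(5.0, 0.3, 3, 5, seed=9)
        assert a.table.equals(b.table)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synth_correlated_trains(-1.0, 0.3, 2, 2, seed=0)
        with pytest.raises(ValueError):
            synth_correlated_trains(5.0, 1.0, 2, 2, seed=0)


class TestInvariances:
    def test_disjoint_vs_overlapping_same_orderings(self):
        """The qualitative comparisons are insensitive to window overlap."""
        lo = synth_correlated_trains(3.0, 0.1, 6, 80, seed=21)
        hi = synth_correlated_trains(3.0, 0.4, 6, 80, seed=22)
        outcome = {}
        for mode in ("half", "none"):
            rhos = []
            for r in (lo, hi):
                _, counts = window_counts(r, "spontaneous", 1.0, overlap=mode)
                rhos.append(np.nanmean(count_statistics(counts, 1.0).rho))
            outcome[mode] = bool(rhos[1] > rhos[0])
        assert outcome["half"] and outcome["none"]

    def test_count_scaling_leaves_rho_and_ff_ordering(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4.0, size=(4, 300))
        a = count_statistics(counts, 1.0)
        b = count_statistics(counts * 3, 1.0)
        assert b.rho == pytest.approx(a.rho, abs=1e-12)
        # FF scales by the constant, preserving order across units
        assert np.argsort(b.ff).tolist() == np.argsort(a.ff).tolist()

    def test_poisson_variance_over_window_approaches_rate(self):
        r = synth_correlated_trains(5.0, 0.0, 3, 100, seed=5)
        _, counts = window_counts(r, "spontaneous", 2.0)
        cs = count_statistics(counts, 2.0)
        assert (cs.var / 2.0).mean() == pytest.approx(5.0, rel=0.1)
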