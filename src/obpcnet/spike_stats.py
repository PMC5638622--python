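"""Windowed spike-count statistics from rasters.

Spike counts N_j are taken in (half-open) windows [t, t + T_win) that
overlap by half their length and tile each activity-state segment of a
trial; window instances are pooled across window positions and trials.
From the pooled counts: mean, variance, pairwise covariance (n-1
denominator), Fano factor FF = Var/mean, Pearson correlation rho_T, and
firing rate nu = mean count / T_win.

Rasters are plain tables (unit id, trial id, spike time in seconds on
the within-trial clock).  Each trial is segmented into an evoked part
(first 2 s by default) and a spontaneous part (the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpikeRaster",
    "CountStats",
    "dedup_spikes",
    "unit_rate_filter",
    "window_starts",
    "window_counts",
    "count_statistics",
    "synth_correlated_trains",
]


@dataclass
class SpikeRaster:
    """Spike trains with trial structure.

    ``table`` columns: unit (int), trial (int), time (float, seconds,
    within-trial clock).  ``trial_length`` is the full trial duration and
    ``evoked_end`` the boundary between the evoked segment [0, evoked_end)
    and the spontaneous segment [evoked_end, trial_length).
    """

    table: pd.DataFrame
    trial_length: float = 30.0
    evoked_end: float = 2.0

    def __post_init__(self):
        need = {"unit", "trial", "time"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"raster table must have columns {need}")
        if (self.table["time"] < 0).any():
            raise ValueError("spike times must be non-negative")
        self.table = self.table.sort_values(
            ["unit", "trial", "time"], kind="stable").reset_index(drop=True)

    @property
    def units(self) -> np.ndarray:
        return np.unique(self.table["unit"].to_numpy())

    @property
    def trials(self) -> np.ndarray:
        return np.unique(self.table["trial"].to_numpy())

    def segment(self, state: str) -> tuple[float, float]:
        """(start, end) of the given activity state within a trial."""
        if state == "evoked":
            return 0.0, self.evoked_end
        if state == "spontaneous":
            return self.evoked_end, self.trial_length
        raise ValueError("state must be 'spontaneous' or 'evoked'")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "SpikeRaster":
        return cls(pd.read_csv(Path(path)), **kw)


@dataclass
class CountStats:
    """Count statistics for one (state, T_win): per-unit and per-pair arrays."""

    t_win: float
    units: np.ndarray
    mean: np.ndarray        # mean count per unit
    var: np.ndarray         # count variance per unit (ddof=1)
    ff: np.ndarray          # Fano factor; NaN for zero-mean units
    rate: np.ndarray        # mean/T_win
    pairs: np.ndarray       # (n_pairs, 2) unit-index pairs
    cov: np.ndarray         # pairwise covariance (ddof=1)
    rho: np.ndarray         # Pearson correlation; NaN if either var is 0
    n_instances: int


def dedup_spikes(raster: SpikeRaster, min_isi: float = 1e-4) -> SpikeRaster:
    """Remove near-duplicate spikes within each unit-trial.

    Of any spikes closer than ``min_isi`` (default 0.1 ms) only the first
    is kept; the rule is applied sequentially so a burst of several
    near-coincident spikes leaves a single survivor.
    """
    t = raster.table
    keep = np.ones(len(t), dtype=bool)
    for _, idx in t.groupby(["unit", "trial"], sort=False).indices.items():
        times = t["time"].to_numpy()[idx]
        last = -np.inf
        for i, ti in enumerate(times):
            if ti - last < min_isi:
                keep[idx[i]] = False
            else:
                last = ti
    return SpikeRaster(t[keep].reset_index(drop=True),
                       raster.trial_length, raster.evoked_end)


def unit_rate_filter(raster: SpikeRaster, min_rate: float = 0.008,
                     max_rate: float = 49.0) -> SpikeRaster:
    """Drop units whose whole-trial average firing rate is strictly below
    ``min_rate`` or strictly above ``max_rate`` (boundary values are kept)."""
    n_trials = len(raster.trials)
    total_time = n_trials * raster.trial_length
    counts = raster.table.groupby("unit").size()
    rates = counts / total_time
    bad = rates.index[(rates < min_rate) | (rates > max_rate)]
    t = raster.table[~raster.table["unit"].isin(bad)].reset_index(drop=True)
    return SpikeRaster(t, raster.trial_length, raster.evoked_end)


def window_starts(seg_start: float, seg_end: float, t_win: float,
                  overlap: str = "half") -> np.ndarray:
    """Start times of windows tiling [seg_start, seg_end].

    ``overlap='half'`` advances by T_win/2 (e.g. a 2 s segment with
    T_win = 1 s gives starts 0, 0.5, 1.0 → 3 windows); ``'none'`` gives
    disjoint windows.
    """
    if t_win <= 0:
        raise ValueError("t_win must be positive")
    if t_win > seg_end - seg_start + 1e-12:
        raise ValueError("t_win exceeds the segment length")
    step = t_win / 2 if overlap == "half" else t_win
    n = int(np.floor((seg_end - seg_start - t_win) / step + 1e-9)) + 1
    return seg_start + step * np.arange(n)


def window_counts(raster: SpikeRaster, state: str, t_win: float,
                  overlap: str = "half",
                  units: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per (unit, window instance), pooled across trials.

    Windows are half-open [t, t + T_win).  Returns (units, counts) with
    ``counts`` of shape (n_units, n_windows * n_trials).  Units with no
    spikes anywhere still get all-zero rows when listed in ``units``.
    """
    seg0, seg1 = raster.segment(state)
    starts = window_starts(seg0, seg1, t_win, overlap)
    units = raster.units if units is None else np.asarray(units)
    trials = raster.trials
    u_index = {u: i for i, u in enumerate(units)}
    t_index = {tr: i for i, tr in enumerate(trials)}
    counts = np.zeros((len(units), len(starts), len(trials)), dtype=np.int64)

    tab = raster.table
    mask = (tab["time"] >= seg0) & (tab["time"] < seg1) & tab["unit"].isin(units)
    sub = tab[mask]
    ui = sub["unit"].map(u_index).to_numpy()
    ti = sub["trial"].map(t_index).to_numpy()
    times = sub["time"].to_numpy()
    for w, s in enumerate(starts):
        inw = (times >= s) & (times < s + t_win)
        np.add.at(counts, (ui[inw], w, ti[inw]), 1)
    return units, counts.reshape(len(units), -1)


def count_statistics(counts: np.ndarray, t_win: float,
                     units: np.ndarray | None = None,
                     pairs: np.ndarray | None = None) -> CountStats:
    """First/second-order statistics of pooled window counts.

    ``counts``: (n_units, n_instances).  Covariances use the n-1
    denominator.  Correlations involving a zero-variance unit are
    reported as NaN (undefined) so they can be excluded from averages.
    ``pairs`` restricts the pair statistics to the given index pairs
    (default: all unordered pairs).
    """
    counts = np.asarray(counts, dtype=float)
    n_units, n = counts.shape
    if n < 2:
        raise ValueError("need at least 2 window instances")
    units = np.arange(n_units) if units is None else np.asarray(units)
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(mean > 0, var / mean, np.nan)
    if pairs is None:
        pairs = np.array([(j, k) for j in range(n_units)
                          for k in range(j + 1, n_units)], dtype=int)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    dev = counts - mean[:, None]
    cov = np.einsum("pn,pn->p", dev[pairs[:, 0]], dev[pairs[:, 1]]) / (n - 1)
    sd = np.sqrt(var)
    denom = sd[pairs[:, 0]] * sd[pairs[:, 1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, cov / denom, np.nan)
    return CountStats(t_win=t_win, units=units, mean=mean, var=var, ff=ff,
                      rate=mean / t_win, pairs=pairs, cov=cov, rho=rho,
                      n_instances=n)


def synth_correlated_trains(rate: float, rho_target: float, n_units: int,
                            n_trials: int, seed: int,
                            trial_length: float = 30.0,
                            evoked_end: float = 2.0) -> SpikeRaster:
    """Synthetic stationary Poisson trains with a known count correlation.

    Common-source thinning: each unit keeps every spike of a shared mother
    Poisson train (rate ``rate``) independently with probability
    sqrt(rho_target) and adds an independent Poisson train at rate
    rate*(1 - sqrt(rho_target)).  Counts in any window are then Poisson
    with mean rate*T and pairwise count correlation exactly
    ``rho_target`` at every window size.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not 0 <= rho_target < 1:
        raise ValueError("rho_target must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p = np.sqrt(rho_target)
    indep_rate = rate * (1 - p)
    rows = []
    for trial in range(n_trials):
        n_mother = rng.poisson(rate * trial_length)
        mother = np.sort(rng.uniform(0, trial_length, n_mother))
        for u in range(n_units):
            kept = mother[rng.random(n_mother) < p] if p > 0 else np.empty(0)
            n_ind = rng.poisson(indep_rate * trial_length)
            own = rng.uniform(0, trial_length, n_ind)
            times = np.sort(np.concatenate([kept, own]))
            rows.append(pd.DataFrame(
                {"unit": u, "trial": trial, "time": times}))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        {"unit": [], "trial": [], "time": []})
    return SpikeRaster(table, trial_length=trial_length, evoked_end=evoked_end)
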