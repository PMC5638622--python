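"""Conductance-based leaky integrate-and-fire network of the OB-PC circuit.

Two heterogeneous populations of 100 neurons each: OB with 20 excitatory
mitral/tufted (M/T) cells and 80 inhibitory granule cells, PC with 80
excitatory and 20 inhibitory cells.  Scaled voltages obey

  tau_m dv/dt = mu - v - g_I (v - E_I) - g_E (v - E_E) - g_X(t - delay)(v - E_E)
                + sigma (sqrt(1-c) eta_k + sqrt(c) xi_region)

with threshold crossing -> spike -> refractory clamp -> reset to 0.
Synapses are two-stage low-pass filters (A then G, with E/I kinetics set
by the presynaptic type); cross-region excitation is delayed.  Each of
the twelve connection classes (two regions x two postsynaptic types x
three presynaptic sources) is an independent Erdos-Renyi graph with
connection probability p = 0.30, and the summed conductance is
normalized by p times the presynaptic pool size.  Thresholds are an
evenly sampled log-normal (mean 1) between its 5th and 95th percentiles.

Graphs and thresholds are quenched: drawn once per network instance and
held fixed across realizations (trial repeats); both activity states
share the same instance and differ only in drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps

from .constraints import RegionStateStats, evaluate_table1, summarize_population
from .spike_stats import SpikeRaster, count_statistics, window_counts

__all__ = [
    "LIFNetworkSpec",
    "ConnectivityGraphs",
    "sample_thresholds",
    "build_connectivity",
    "simulate_lif",
    "lif_statistics",
    "run_named_test",
    "NAMED_TESTS",
]

#: coupling overrides for the violation experiments (baseline: 7, 10, 20, 15)
NAMED_TESTS = {
    "baseline": {},
    "test1": {"gIO": 20.0, "gIP": 7.0},
    "test2": {"gEO": 15.0, "gEP": 1.0},
    "test3": {"gEP": 10.0, "gIP": 10.0},
}


@dataclass(frozen=True)
class RegionParams:
    """Per-region LIF parameters (Table-4 style)."""

    n: int
    n_exc: int
    mu_spont: float
    mu_evoked: float         # applies to all cells (PC) or E cells only (OB)
    sigma: float
    c_common: float          # within-region common-noise fraction
    gamma_ee: float
    gamma_ie: float
    gamma_ii: float
    delay_out: float         # conduction delay of this region's output (s)


@dataclass(frozen=True)
class LIFNetworkSpec:
    """Full parameterization of the two-region spiking network."""

    # membrane / synapse constants (shared by both regions); times in seconds
    tau_m: float = 0.020
    tau_ref: float = 0.002
    e_i: float = -2.5
    e_e: float = 6.5
    tau_d_i: float = 0.010
    tau_r_i: float = 0.002
    tau_d_e: float = 0.005
    tau_r_e: float = 0.001
    alpha_i: float = 2.0
    alpha_e: float = 1.0
    p_conn: float = 0.30
    sigma_theta: float = 0.1
    # the four varied conductance scale factors
    gIO: float = 7.0     # OB  gamma_EI (granule -> M/T)
    gIP: float = 20.0    # PC  gamma_EI
    gEO: float = 10.0    # OB -> PC excitation
    gEP: float = 15.0    # PC -> OB excitation
    ob: RegionParams = field(default_factory=lambda: RegionParams(
        n=100, n_exc=20, mu_spont=0.6, mu_evoked=0.9, sigma=0.05, c_common=0.5,
        gamma_ee=2.0, gamma_ie=4.0, gamma_ii=2.0, delay_out=0.010))
    pc: RegionParams = field(default_factory=lambda: RegionParams(
        n=100, n_exc=80, mu_spont=0.0, mu_evoked=0.4, sigma=0.1, c_common=0.8,
        gamma_ee=5.0, gamma_ie=8.0, gamma_ii=6.0, delay_out=0.005))

    def __post_init__(self):
        for t in (self.tau_m, self.tau_ref, self.tau_d_i, self.tau_r_i,
                  self.tau_d_e, self.tau_r_e):
            if t <= 0:
                raise ValueError("time constants must be positive")
        if not self.e_i < 0 < self.e_e:
            raise ValueError("reversal potentials must satisfy E_I < 0 < E_E")
        for r in (self.ob, self.pc):
            if not 0 < r.n_exc < r.n:
                raise ValueError("region composition must sum to N with both types")

    def with_couplings(self, **kw) -> "LIFNetworkSpec":
        return replace(self, **kw)

    def mu_vector(self, region: str, state: str) -> np.ndarray:
        """Per-cell drive.  Evoked raises all PC cells but only OB E cells."""
        r = self.ob if region == "OB" else self.pc
        mu = np.full(r.n, r.mu_spont)
        if state == "evoked":
            if region == "OB":
                mu[:r.n_exc] = r.mu_evoked   # M/T cells only
            else:
                mu[:] = r.mu_evoked
        elif state != "spontaneous":
            raise ValueError("state must be 'spontaneous' or 'evoked'")
        return mu


def sample_thresholds(n: int, sigma_theta: float = 0.1,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Evenly sampled log-normal thresholds, randomly assigned to cells.

    theta = exp(q) with q the normal(-sigma_theta^2/2, sigma_theta)
    quantiles at n evenly spaced probabilities on [0.05, 0.95] inclusive,
    so the underlying (unclipped) law has mean exactly 1.  The assignment
    order is shuffled by ``rng``.
    """
    if n < 2:
        raise ValueError("need at least 2 cells")
    probs = np.linspace(0.05, 0.95, n)
    theta = np.exp(sps.norm.ppf(probs, loc=-sigma_theta ** 2 / 2,
                                scale=sigma_theta))
    if rng is not None:
        rng.shuffle(theta)
    return theta


@dataclass
class ConnectivityGraphs:
    """Twelve Erdos-Renyi adjacency blocks as weighted input matrices.

    For each region, three (N x pool) matrices give the synaptically
    normalized weight of every potential input: from the local E pool,
    the local I pool, and the other region's E pool (delayed).  Entries
    are gamma_XY/(p * pool) on existing edges and 0 otherwise; the
    diagonal of the within-region blocks is zero (no autapses).
    """

    ob_from_e: np.ndarray
    ob_from_i: np.ndarray
    ob_from_pc: np.ndarray
    pc_from_e: np.ndarray
    pc_from_i: np.ndarray
    pc_from_ob: np.ndarray

    def as_dict(self) -> dict:
        return self.__dict__


def _adjacency(n_post: int, n_pre: int, p: float, rng,
               self_offset: int | None = None) -> np.ndarray:
    a = (rng.random((n_post, n_pre)) < p).astype(np.float32)
    if self_offset is not None:
        for i in range(n_pre):
            post = self_offset + i
            if 0 <= post < n_post:
                a[post, i] = 0.0
    return a


def build_connectivity(spec: LIFNetworkSpec, seed: int) -> ConnectivityGraphs:
    """Draw the twelve connection graphs (reproducible by seed)."""
    rng = np.random.default_rng(seed)
    p = spec.p_conn
    out = {}
    for name, region, other in (("ob", spec.ob, spec.pc), ("pc", spec.pc, spec.ob)):
        n, ne = region.n, region.n_exc
        ni = n - ne
        g_ei = spec.gIO if name == "ob" else spec.gIP
        g_x = spec.gEP if name == "ob" else spec.gEO
        # rows: postsynaptic cells ordered E then I
        w_e = np.empty(n, dtype=np.float32)   # weight of local-E input per post
        w_e[:ne] = region.gamma_ee
        w_e[ne:] = region.gamma_ie
        w_i = np.empty(n, dtype=np.float32)
        w_i[:ne] = g_ei
        w_i[ne:] = region.gamma_ii
        # cross-region excitation targets one postsynaptic type: PC feedback
        # synapses onto OB granule (I) cells; OB output synapses onto PC E
        # cells (the lateral olfactory tract drive)
        w_x = np.zeros(n, dtype=np.float32)
        if name == "ob":
            w_x[ne:] = g_x
        else:
            w_x[:ne] = g_x
        a_e = _adjacency(n, ne, p, rng, self_offset=0)
        a_i = _adjacency(n, ni, p, rng, self_offset=ne)
        a_x = _adjacency(n, other.n_exc, p, rng)
        out[f"{name}_from_e"] = a_e * (w_e / (p * ne))[:, None]
        out[f"{name}_from_i"] = a_i * (w_i / (p * ni))[:, None]
        key = "ob_from_pc" if name == "ob" else "pc_from_ob"
        out[key] = a_x * (w_x / (p * other.n_exc))[:, None]
    return ConnectivityGraphs(**out)


@njit(cache=True)
def _lif_kernel(WL, WX, mu, theta, sfac, aind, acom, regidx, is_e, alpha,
                delay_steps, dt_tau, e_i, e_e, ref_steps, n_steps, n_equil,
                R, rng, fe, fi, ae, ai_dec,
                sp_cell, sp_real, sp_step, ring_c, ring_r, ring_n):
    """Event-driven forward-Euler integration of the two-region LIF network.

    Postsynaptic conductance sums are tracked directly as three filtered
    variables per cell (local-E, local-I, delayed cross-E input); spikes
    scatter their weighted jumps into the postsynaptic A variables, and
    cross-region jumps are delayed through a ring buffer of spike events.
    This is algebraically identical to filtering each presynaptic train
    separately and summing, because the synaptic filters are linear.
    """
    n = mu.size
    v = rng.random((n, R))
    refr = np.zeros((n, R), np.int32)
    GE = np.zeros((n, R))
    AE = np.zeros((n, R))
    GI = np.zeros((n, R))
    AI = np.zeros((n, R))
    GX = np.zeros((n, R))
    AX = np.zeros((n, R))
    fired_c = np.empty(n * R, np.int64)
    fired_r = np.empty(n * R, np.int64)
    ringlen = ring_n.size
    cap = ring_c.shape[1]
    nsp = 0
    err = 0

    for step in range(n_steps):
        eta = rng.standard_normal(n * R)
        com = rng.standard_normal(2 * R)
        # deliver cross-region spikes whose delay elapses now
        slot = step % ringlen
        for e in range(ring_n[slot]):
            c = ring_c[slot, e]
            r = ring_r[slot, e]
            a = alpha[c]
            for i in range(n):
                AX[i, r] += a * WX[i, c]
        ring_n[slot] = 0

        nf = 0
        for i in range(n):
            mui = mu[i]
            th = theta[i]
            sf_i = sfac[i] * aind[i]
            sf_c = sfac[i] * acom[i]
            co = regidx[i] * R
            base = i * R
            for r in range(R):
                if refr[i, r] == 0:
                    vv = v[i, r]
                    ge = GE[i, r] + GX[i, r]
                    gi = GI[i, r]
                    vv += dt_tau * (mui - vv - gi * (vv - e_i) - ge * (vv - e_e)) \
                        + sf_i * eta[base + r] + sf_c * com[co + r]
                    if vv >= th:
                        refr[i, r] = ref_steps
                        fired_c[nf] = i
                        fired_r[nf] = r
                        nf += 1
                        if step >= n_equil:
                            if nsp < sp_cell.size:
                                sp_cell[nsp] = i
                                sp_real[nsp] = r
                                sp_step[nsp] = step - n_equil
                                nsp += 1
                            else:
                                err = 1
                    v[i, r] = vv
                else:
                    refr[i, r] -= 1
                    if refr[i, r] == 0:
                        v[i, r] = 0.0   # reset at refractory release
        # two-stage synaptic filters: G relaxes toward A, A decays ...
        for i in range(n):
            for r in range(R):
                GE[i, r] += fe * (AE[i, r] - GE[i, r])
                GI[i, r] += fi * (AI[i, r] - GI[i, r])
                GX[i, r] += fe * (AX[i, r] - GX[i, r])
                AE[i, r] -= ae * AE[i, r]
                AI[i, r] -= ai_dec * AI[i, r]
                AX[i, r] -= ae * AX[i, r]
        # ... then this step's spikes jump the postsynaptic A variables
        for f in range(nf):
            c = fired_c[f]
            r = fired_r[f]
            a = alpha[c]
            if is_e[c]:
                for i in range(n):
                    AE[i, r] += a * WL[i, c]
                slot2 = (step + delay_steps[c]) % ringlen
                k = ring_n[slot2]
                if k < cap:
                    ring_c[slot2, k] = c
                    ring_r[slot2, k] = r
                    ring_n[slot2] = k + 1
                else:
                    err = 2
            else:
                for i in range(n):
                    AI[i, r] += a * WL[i, c]
        if step % 2000 == 0:
            tot = 0.0
            for i in range(n):
                for r in range(R):
                    tot += v[i, r]
            if not np.isfinite(tot):
                err = 3
                break
    return nsp, err


def _assemble_weights(spec: LIFNetworkSpec, graphs: ConnectivityGraphs):
    """Dense (2N x 2N) local and cross weight matrices in global indexing.

    Global cells: OB 0..N_OB-1 (E first), then PC (E first).
    """
    n_ob, n_pc = spec.ob.n, spec.pc.n
    ne_ob, ne_pc = spec.ob.n_exc, spec.pc.n_exc
    n = n_ob + n_pc
    WL = np.zeros((n, n))
    WX = np.zeros((n, n))
    WL[:n_ob, :ne_ob] = graphs.ob_from_e
    WL[:n_ob, ne_ob:n_ob] = graphs.ob_from_i
    WL[n_ob:, n_ob:n_ob + ne_pc] = graphs.pc_from_e
    WL[n_ob:, n_ob + ne_pc:] = graphs.pc_from_i
    WX[:n_ob, n_ob:n_ob + ne_pc] = graphs.ob_from_pc
    WX[n_ob:, :ne_ob] = graphs.pc_from_ob
    return WL, WX


def simulate_lif(spec: LIFNetworkSpec, state: str, n_real: int,
                 T: float = 2.0, dt: float = 1e-4, t_equil: float = 0.5,
                 seed: int = 0,
                 graphs: ConnectivityGraphs | None = None,
                 thresholds: tuple[np.ndarray, np.ndarray] | None = None,
                 max_mean_rate: float = 60.0) -> SpikeRaster:
    """Simulate ``n_real`` trial repeats of the quenched network.

    Forward-Euler at step ``dt`` (0.1 ms); each realization runs
    ``t_equil`` of unscored equilibration followed by ``T`` seconds of
    scored biology time (``t_equil=0`` scores from the fresh start).
    Realizations are integrated in parallel with independent noise but
    shared graphs/thresholds (drawn from ``seed`` when not supplied).
    Returns a raster with unit ids 0..N_OB-1 for OB (E cells first) and
    N_OB.. for PC, trial = realization index, times in [0, T).
    Non-finite voltages abort with a FloatingPointError.
    """
    if state not in ("spontaneous", "evoked"):
        raise ValueError("state must be 'spontaneous' or 'evoked'")
    rng = np.random.default_rng(seed)
    if graphs is None:
        graphs = build_connectivity(spec, seed=int(rng.integers(2 ** 31)))
    if thresholds is None:
        th_ob = sample_thresholds(spec.ob.n, spec.sigma_theta, rng)
        th_pc = sample_thresholds(spec.pc.n, spec.sigma_theta, rng)
    else:
        th_ob, th_pc = thresholds

    n_ob, n_pc = spec.ob.n, spec.pc.n
    n = n_ob + n_pc
    n_steps = int(round((t_equil + T) / dt))
    n_equil = int(round(t_equil / dt))
    R = int(n_real)

    WL, WX = _assemble_weights(spec, graphs)
    mu = np.concatenate([spec.mu_vector("OB", state), spec.mu_vector("PC", state)])
    theta = np.concatenate([th_ob, th_pc]).astype(float)
    sfac = np.concatenate([
        np.full(n_ob, spec.ob.sigma), np.full(n_pc, spec.pc.sigma)
    ]) / spec.tau_m * np.sqrt(dt)
    aind = np.concatenate([np.full(n_ob, np.sqrt(1 - spec.ob.c_common)),
                           np.full(n_pc, np.sqrt(1 - spec.pc.c_common))])
    acom = np.concatenate([np.full(n_ob, np.sqrt(spec.ob.c_common)),
                           np.full(n_pc, np.sqrt(spec.pc.c_common))])
    regidx = np.concatenate([np.zeros(n_ob, np.int64), np.ones(n_pc, np.int64)])
    is_e = np.zeros(n, np.bool_)
    is_e[:spec.ob.n_exc] = True
    is_e[n_ob:n_ob + spec.pc.n_exc] = True
    alpha = np.where(is_e, spec.alpha_e, spec.alpha_i).astype(float)
    # conduction delay of each cell's cross-region output
    delay_steps = np.where(np.arange(n) < n_ob,
                           int(round(spec.ob.delay_out / dt)),
                           int(round(spec.pc.delay_out / dt))).astype(np.int64)
    ringlen = int(delay_steps.max()) + 1
    ring_c = np.zeros((ringlen, 32768), np.int64)
    ring_r = np.zeros((ringlen, 32768), np.int64)
    ring_n = np.zeros(ringlen, np.int64)
    cap_spikes = int(n * R * (T + 0.1) * max_mean_rate)
    sp_cell = np.zeros(cap_spikes, np.int32)
    sp_real = np.zeros(cap_spikes, np.int32)
    sp_step = np.zeros(cap_spikes, np.int32)

    nsp, errcode = _lif_kernel(
        WL, WX, mu, theta, sfac, aind, acom, regidx, is_e, alpha, delay_steps,
        dt / spec.tau_m, float(spec.e_i), float(spec.e_e),
        int(round(spec.tau_ref / dt)), n_steps, n_equil, R,
        np.random.default_rng(int(rng.integers(2 ** 31))),
        dt / spec.tau_d_e, dt / spec.tau_d_i,
        dt / spec.tau_r_e, dt / spec.tau_r_i,
        sp_cell, sp_real, sp_step, ring_c, ring_r, ring_n)
    if errcode == 3:
        raise FloatingPointError("non-finite voltage during LIF integration")
    if errcode in (1, 2):
        raise RuntimeError("spike buffer overflow; raise max_mean_rate")

    table = pd.DataFrame({
        "unit": sp_cell[:nsp].astype(int),
        "trial": sp_real[:nsp].astype(int),
        "time": sp_step[:nsp] * dt,
    })
    evoked_end = T if state == "evoked" else 0.0
    return SpikeRaster(table, trial_length=T, evoked_end=evoked_end)


def _region_units(spec: LIFNetworkSpec, region: str) -> np.ndarray:
    return (np.arange(spec.ob.n) if region == "OB"
            else spec.ob.n + np.arange(spec.pc.n))


def lif_statistics(rasters: dict[str, SpikeRaster], spec: LIFNetworkSpec,
                   t_win: float = 1.0, n_pairs: int = 1000, seed: int = 0,
                   t_win_grid: tuple = (), overlap: str = "half") -> dict:
    """Population-averaged spike statistics per (region, state).

    ``rasters`` maps state -> raster from :func:`simulate_lif`.  Counts
    are pooled over half-overlapping windows and realizations; pair
    statistics use ``n_pairs`` pairs sampled uniformly without
    replacement per region (seeded).  Returns
    {'summaries': {(region, state): RegionStateStats},
     'curves': DataFrame over t_win_grid ∪ {t_win}}.
    """
    rng = np.random.default_rng(seed)
    pair_idx = {}
    for region in ("OB", "PC"):
        n = spec.ob.n if region == "OB" else spec.pc.n
        allp = np.array([(j, k) for j in range(n) for k in range(j + 1, n)])
        take = min(n_pairs, len(allp))
        pair_idx[region] = allp[rng.choice(len(allp), size=take, replace=False)]

    wins = sorted(set(t_win_grid) | {t_win})
    summaries = {}
    rows = []
    for state, raster in rasters.items():
        for region in ("OB", "PC"):
            units = _region_units(spec, region)
            for w in wins:
                _, counts = window_counts(raster, state, w, overlap=overlap,
                                          units=units)
                cs = count_statistics(counts, w, units=units,
                                      pairs=pair_idx[region])
                summary = summarize_population(
                    {"rate": cs.rate, "var": cs.var, "ff": cs.ff},
                    {"cov": cs.cov, "rho": cs.rho}, region, state)
                rows.append({"region": region, "state": state, "t_win": w,
                             "rate": summary.rate, "var": summary.var,
                             "cov": summary.cov, "ff": summary.ff,
                             "rho": summary.rho})
                if w == t_win:
                    summaries[(region, state)] = summary
    return {"summaries": summaries, "curves": pd.DataFrame(rows)}


def run_named_test(test_id: str, n_real: int = 500, t_win: float = 1.0,
                   seed: int = 0, spec: LIFNetworkSpec | None = None,
                   dt: float = 1e-4, T: float = 2.0, t_equil: float = 0.5,
                   n_pairs: int = 1000, t_win_grid: tuple = ()) -> dict:
    """Run one violation experiment (or the baseline) end to end.

    Applies the coupling override, simulates both activity states on the
    same quenched network, evaluates the 12 constraints at the designated
    window, and reports the violated-constraint identities.
    """
    if test_id not in NAMED_TESTS:
        raise ValueError(f"unknown test id {test_id!r}; choose from {sorted(NAMED_TESTS)}")
    spec = (spec or LIFNetworkSpec()).with_couplings(**NAMED_TESTS[test_id])
    rng = np.random.default_rng(seed)
    graphs = build_connectivity(spec, seed=int(rng.integers(2 ** 31)))
    thresholds = (sample_thresholds(spec.ob.n, spec.sigma_theta, rng),
                  sample_thresholds(spec.pc.n, spec.sigma_theta, rng))
    rasters = {}
    for st in ("spontaneous", "evoked"):
        rasters[st] = simulate_lif(spec, st, n_real, T=T, dt=dt,
                                   t_equil=t_equil,
                                   seed=int(rng.integers(2 ** 31)),
                                   graphs=graphs, thresholds=thresholds)
    stats = lif_statistics(rasters, spec, t_win=t_win, n_pairs=n_pairs,
                           seed=int(rng.integers(2 ** 31)),
                           t_win_grid=t_win_grid)
    s = stats["summaries"]
    report = evaluate_table1(s[("OB", "spontaneous")], s[("PC", "spontaneous")],
                             s[("OB", "evoked")], s[("PC", "evoked")])
    return {"test_id": test_id, "spec": spec, "report": report,
            "violated": report.violated_ids(), "summaries": s,
            "curves": stats["curves"], "rasters": rasters}
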