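"""Exhaustive classification of the 4-D coupling space.

Every coupling tuple (|gIO|, |gEO|, |gIP|, |gEP|) on a grid is solved by
the moment closure in both activity states; tuples whose firing-rate
statistics satisfy all 12 data constraints (with converged, valid
solutions in both states) form the admissible set.  Monte Carlo
re-simulation of the admissible set provides a conservative validation.
The admissible set is characterized by its mean (signed) tuple, an SVD
of the mean-centered tuple matrix, per-constraint satisfaction profiles
and constraint-subset analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import (
    CONSTRAINT_IDS,
    COVARIABILITY_IDS,
    RATE_IDS,
    evaluate_table1,
    region_stats_from_rates,
)
from .moment_closure import solve_moments
from .quadrature import QuadratureGrid, default_grid
from .rate_model import CouplingTuple, RateNetworkSpec, simulate_rate_mc, spec_pair

__all__ = ["SweepGrid", "SweepResult", "region_summaries", "run_grid", "mc_validate",
           "svd_structure", "subset_sweep", "per_constraint_profile"]


@dataclass(frozen=True)
class SweepGrid:
    """Grid of coupling magnitudes, identical per axis by default.

    The full-scale reference grid is 0.1 to 2.0 inclusive in steps of 0.1
    (20 points per axis, 20^4 = 160000 tuples).
    """

    gIO: tuple = ()
    gEO: tuple = ()
    gIP: tuple = ()
    gEP: tuple = ()

    def __post_init__(self):
        for name in ("gIO", "gEO", "gIP", "gEP"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                vals = tuple(np.round(np.arange(0.1, 2.0001, 0.1), 10))
            if any(v <= 0 for v in vals):
                raise ValueError("grid points must be positive")
            object.__setattr__(self, name, vals)

    @classmethod
    def with_step(cls, step: float, lo: float = None, hi: float = 2.0) -> "SweepGrid":
        lo = step if lo is None else lo
        vals = tuple(np.round(np.arange(lo, hi + step / 2, step), 10))
        return cls(vals, vals, vals, vals)

    @property
    def n_tuples(self) -> int:
        return len(self.gIO) * len(self.gEO) * len(self.gIP) * len(self.gEP)

    def tuples(self):
        """Deterministic lexicographic enumeration of coupling tuples."""
        for a in self.gIO:
            for b in self.gEO:
                for c in self.gIP:
                    for d in self.gEP:
                        yield CouplingTuple(gIO=a, gEO=b, gIP=c, gEP=d)


def region_summaries(report, state, stats_mode: str = "rates"):
    """(OB, PC) RegionStateStats from a converged SolveReport or RateMCResult.

    ``stats_mode='rates'`` (default) summarizes the firing-rate statistics
    F(x); ``'activity'`` summarizes the activity statistics x themselves.
    """
    if stats_mode == "activity":
        src = report.state if hasattr(report, "state") else report
        rmean, rvar, rcov = src.mean, src.var, src.cov
    elif stats_mode == "rates":
        rs = report.rate_stats if hasattr(report, "rate_stats") else report
        if hasattr(rs, "rate_mean"):    # Monte Carlo result
            rmean, rvar, rcov = rs.rate_mean, rs.rate_var, rs.rate_cov
        else:
            rmean, rvar, rcov = rs.mean, rs.var, rs.cov
    else:
        raise ValueError("stats_mode must be 'rates' or 'activity'")
    ob = region_stats_from_rates(rmean[:3], rvar[:3], rcov[:3], "OB", state)
    pc = region_stats_from_rates(rmean[3:], rvar[3:], rcov[3:], "PC", state)
    return ob, pc


@dataclass
class SweepResult:
    """Per-tuple sweep records plus lazily computed aggregates.

    ``table`` has one row per tuple: the four magnitudes, solver status in
    each state, the 12 constraint booleans (False where not evaluable),
    the analytic ``admissible`` flag, and ``mc_validated`` after Monte
    Carlo validation (NaN/False before).
    """

    table: pd.DataFrame
    grid: SweepGrid
    mc_done: bool = False

    @property
    def n_tuples(self) -> int:
        return len(self.table)

    @property
    def admissible_fraction(self) -> float:
        return float(self.table["admissible"].mean())

    @property
    def mc_validated_fraction(self) -> float:
        if not self.mc_done:
            raise ValueError("Monte Carlo validation has not been run")
        return float(self.table["mc_validated"].mean())

    def admissible_matrix(self, signed: bool = True) -> np.ndarray:
        """Matrix A with one admissible tuple (gIO, gEO, gIP, gEP) per row;
        inhibitory entries negative when ``signed``."""
        sub = self.table.loc[self.table["admissible"],
                             ["gIO", "gEO", "gIP", "gEP"]].to_numpy(float)
        if signed:
            sub = sub * np.array([-1.0, 1.0, -1.0, 1.0])
        return sub

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)


def _solve_tuple(ct: CouplingTuple, base_sp: RateNetworkSpec,
                 base_ev: RateNetworkSpec, grid: QuadratureGrid,
                 stats_mode: str = "rates"):
    """Solve both states for one tuple; returns (row dict)."""
    row = {"gIO": ct.gIO, "gEO": ct.gEO, "gIP": ct.gIP, "gEP": ct.gEP}
    rep_sp = solve_moments(base_sp.with_coupling(ct), grid, coupling=ct)
    rep_ev = solve_moments(base_ev.with_coupling(ct), grid, coupling=ct)
    row["status_sp"] = rep_sp.status
    row["status_ev"] = rep_ev.status
    solver_ok = rep_sp.ok and rep_ev.ok
    if solver_ok:
        sp_ob, sp_pc = region_summaries(rep_sp, "spontaneous", stats_mode)
        ev_ob, ev_pc = region_summaries(rep_ev, "evoked", stats_mode)
        report = evaluate_table1(sp_ob, sp_pc, ev_ob, ev_pc)
        for cid, ok in report.as_dict().items():
            row[f"c{cid}"] = bool(ok)
        row["admissible"] = report.all_satisfied
    else:
        for cid in CONSTRAINT_IDS:
            row[f"c{cid}"] = False
        row["admissible"] = False
    return row


def run_grid(grid: SweepGrid,
             base_spec_pair: tuple[RateNetworkSpec, RateNetworkSpec] | None = None,
             quad: QuadratureGrid | None = None,
             checkpoint_path: str | Path | None = None,
             checkpoint_every: int = 5000,
             progress: bool = False,
             stats_mode: str = "rates") -> SweepResult:
    """Solve and classify every tuple on the grid (deterministic, resumable).

    The two base specs must differ only in the OB mean inputs (evoked
    doubles them).  Solver failures are recorded per tuple and never abort
    the sweep.  With ``checkpoint_path`` the per-tuple table is flushed
    periodically and a partial file is resumed on re-entry.
    """
    if base_spec_pair is None:
        base_spec_pair = spec_pair()
    base_sp, base_ev = base_spec_pair
    if not (base_sp.mu[3:] == base_ev.mu[3:]
            and np.allclose(np.asarray(base_ev.mu[:3]), 2 * np.asarray(base_sp.mu[:3]))):
        raise ValueError("spec pair must differ only by doubled OB mean inputs")
    quad = quad or default_grid()

    rows = []
    done = 0
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        prev = pd.read_csv(checkpoint_path)
        rows = prev.to_dict("records")
        done = len(rows)

    iterator = enumerate(grid.tuples())
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, total=grid.n_tuples)
    for i, ct in iterator:
        if i < done:
            continue
        rows.append(_solve_tuple(ct, base_sp, base_ev, quad, stats_mode))
        if checkpoint_path is not None and (i + 1) % checkpoint_every == 0:
            pd.DataFrame(rows).to_csv(checkpoint_path, index=False)
    table = pd.DataFrame(rows)
    table["mc_validated"] = False
    if checkpoint_path is not None:
        table.to_csv(checkpoint_path, index=False)
    return SweepResult(table=table, grid=grid)


def mc_validate(result: SweepResult,
                base_spec_pair: tuple[RateNetworkSpec, RateNetworkSpec] | None = None,
                n_real: int = 3000, dt: float = 0.01, t_end: float = 500.0,
                t_equil: float = 100.0, seed: int = 0,
                max_tuples: int | None = None,
                margin: float = 0.0,
                stats_mode: str = "rates") -> SweepResult:
    """Re-simulate the analytic admissible set and re-check the constraints.

    Monte Carlo runs only on tuples that already passed the analytic
    classification (the conservative approach), so ``mc_validated`` is a
    subset of ``admissible`` by construction.  Divergent simulations mark
    the tuple not validated.  ``max_tuples`` randomly subsamples the
    admissible set (seeded) for reduced-scale runs.
    """
    if base_spec_pair is None:
        base_spec_pair = spec_pair()
    base_sp, base_ev = base_spec_pair
    idx = result.table.index[result.table["admissible"]].to_numpy()
    rng = np.random.default_rng(seed)
    if max_tuples is not None and len(idx) > max_tuples:
        idx = np.sort(rng.choice(idx, size=max_tuples, replace=False))
    table = result.table.copy()
    table["mc_validated"] = False
    for n, i in enumerate(idx):
        row = table.loc[i]
        ct = CouplingTuple(gIO=row["gIO"], gEO=row["gEO"],
                           gIP=row["gIP"], gEP=row["gEP"])
        seeds = rng.integers(0, 2 ** 31 - 1, size=2)
        ok = True
        summaries = {}
        for state, base, s in (("spontaneous", base_sp, seeds[0]),
                               ("evoked", base_ev, seeds[1])):
            mc = simulate_rate_mc(base.with_coupling(ct), dt=dt, t_end=t_end,
                                  n_real=n_real, t_equil=t_equil, seed=int(s))
            if mc.diverged or mc.n_samples < 2:
                ok = False
                break
            summaries[state] = region_summaries(mc, state, stats_mode)
        if ok:
            sp_ob, sp_pc = summaries["spontaneous"]
            ev_ob, ev_pc = summaries["evoked"]
            rep = evaluate_table1(sp_ob, sp_pc, ev_ob, ev_pc, margin=margin)
            table.loc[i, "mc_validated"] = rep.all_satisfied
    return SweepResult(table=table, grid=result.grid, mc_done=True)


def svd_structure(result: SweepResult) -> dict:
    """Mean signed tuple and SVD of the mean-centered admissible matrix.

    Variance fractions use squared singular values (standard variance
    accounting).
    """
    A = result.admissible_matrix(signed=True)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 admissible tuples for the SVD")
    mean = A.mean(axis=0)
    U, s, Vt = np.linalg.svd(A - mean, full_matrices=False)
    total = np.sum(s ** 2)
    frac = s ** 2 / total if total > 0 else np.zeros_like(s)
    return {"mean": mean, "singular_values": s,
            "variance_fractions": frac,
            "top2_variance_fraction": float(frac[:2].sum()),
            "right_singular_vectors": Vt}


def subset_sweep(result: SweepResult, constraint_ids) -> float:
    """Fraction of all tuples admissible under a subset of the constraints.

    Recomputed from the stored per-tuple constraint booleans (no
    re-solving); solver status requirements are unchanged.
    """
    ids = list(constraint_ids)
    for cid in ids:
        if cid not in CONSTRAINT_IDS:
            raise ValueError(f"unknown constraint id {cid}")
    t = result.table
    ok = (t["status_sp"] == "converged") & (t["status_ev"] == "converged")
    for cid in ids:
        ok &= t[f"c{cid}"]
    return float(ok.mean())


def drop_covariability_ids():
    """The 8 constraints remaining when the co-variability row is dropped."""
    return tuple(cid for cid in CONSTRAINT_IDS if cid not in COVARIABILITY_IDS)


def rates_only_ids():
    """The 4 firing-rate constraints."""
    return RATE_IDS


def per_constraint_profile(result: SweepResult, mc: bool = False) -> dict:
    """Fraction of all tuples satisfying each constraint individually.

    With ``mc`` the fractions are for tuples satisfying the constraint in
    the analytic method *and* surviving Monte Carlo validation of the full
    set (the conservative pipeline only re-simulates the admissible set,
    so these are analytic∧MC fractions of the whole grid).
    """
    t = result.table
    out = {}
    for cid in CONSTRAINT_IDS:
        col = t[f"c{cid}"]
        if mc:
            if not result.mc_done:
                raise ValueError("Monte Carlo validation has not been run")
            col = col & t["mc_validated"]
        out[cid] = float(col.mean())
    return out
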