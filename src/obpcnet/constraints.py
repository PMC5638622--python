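"""The twelve experimentally observed relationships between OB and PC statistics.

Population-averaged firing statistics (rate, variance, covariance, Fano
factor, pairwise correlation) are compared between regions (OB vs PC) and
between activity states (spontaneous vs evoked).  Twelve strict
inequalities held across all odors in the recordings; any candidate
model is admissible only if its statistics satisfy all of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CONSTRAINT_IDS",
    "CONSTRAINT_LABELS",
    "RegionStateStats",
    "ConstraintReport",
    "summarize_population",
    "evaluate_table1",
    "region_stats_from_rates",
]

CONSTRAINT_IDS = tuple(range(1, 13))

#: fixed, documented ordering of the 12 constraints
CONSTRAINT_LABELS = {
    1: "rate: nu_PC < nu_OB (spontaneous)",
    2: "rate: nu_PC < nu_OB (evoked)",
    3: "rate: nu_PC^Sp < nu_PC^Ev",
    4: "rate: nu_OB^Sp < nu_OB^Ev",
    5: "variability: FF_PC > FF_OB (spontaneous)",
    6: "variability: Var_PC < Var_OB (evoked)",
    7: "variability: Var_OB^Sp < Var_OB^Ev",
    8: "variability: FF_PC^Sp > FF_PC^Ev",
    9: "co-variability: Cov_PC < Cov_OB (evoked)",
    10: "co-variability: rho_PC > rho_OB (spontaneous)",
    11: "co-variability: rho_PC < rho_OB (evoked)",
    12: "co-variability: rho_PC^Sp > rho_PC^Ev",
}

#: constraint subsets by statistic family (rows of the constraint table)
RATE_IDS = (1, 2, 3, 4)
VARIABILITY_IDS = (5, 6, 7, 8)
COVARIABILITY_IDS = (9, 10, 11, 12)


@dataclass(frozen=True)
class RegionStateStats:
    """Population-averaged statistics for one region in one activity state."""

    region: str      # "OB" | "PC"
    state: str       # "spontaneous" | "evoked"
    rate: float      # mean firing rate across cells
    var: float       # mean (count or rate) variance across cells
    cov: float       # mean pairwise covariance
    ff: float        # mean Fano factor
    rho: float       # mean pairwise correlation

    def __post_init__(self):
        if self.region not in ("OB", "PC"):
            raise ValueError("region must be 'OB' or 'PC'")
        if self.state not in ("spontaneous", "evoked"):
            raise ValueError("state must be 'spontaneous' or 'evoked'")
        for f in ("rate", "var", "cov", "ff", "rho"):
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"statistic {f} must be finite")


@dataclass(frozen=True)
class ConstraintReport:
    """Ordered boolean outcome for the 12 constraints."""

    results: tuple  # 12 booleans keyed positionally by CONSTRAINT_IDS

    def __post_init__(self):
        if len(self.results) != 12:
            raise ValueError("exactly 12 constraint results required")

    @property
    def all_satisfied(self) -> bool:
        return all(self.results)

    def satisfied(self, cid: int) -> bool:
        return self.results[CONSTRAINT_IDS.index(cid)]

    def violated_ids(self) -> tuple:
        return tuple(cid for cid, ok in zip(CONSTRAINT_IDS, self.results) if not ok)

    def as_dict(self) -> dict:
        return dict(zip(CONSTRAINT_IDS, self.results))


def summarize_population(per_cell_stats, per_pair_stats, region: str,
                         state: str) -> RegionStateStats:
    """Arithmetic population averages across cells and pairs.

    ``per_cell_stats`` maps 'rate', 'var', 'ff' to per-cell arrays;
    ``per_pair_stats`` maps 'cov', 'rho' to per-pair arrays.  Non-finite
    pair entries (e.g. correlations involving zero-variance units) are
    excluded from the averages.
    """
    cells = {k: np.atleast_1d(np.asarray(v, dtype=float))
             for k, v in per_cell_stats.items()}
    pairs = {k: np.atleast_1d(np.asarray(v, dtype=float))
             for k, v in per_pair_stats.items()}
    for k in ("rate", "var", "ff"):
        if k not in cells or cells[k].size == 0:
            raise ValueError(f"per-cell statistic '{k}' missing or empty")
    for k in ("cov", "rho"):
        if k not in pairs or pairs[k].size == 0:
            raise ValueError(f"per-pair statistic '{k}' missing or empty")

    def _mean(a):
        a = a[np.isfinite(a)]
        if a.size == 0:
            raise ValueError("no finite entries to average")
        return float(a.mean())

    return RegionStateStats(
        region=region, state=state,
        rate=_mean(cells["rate"]), var=_mean(cells["var"]), ff=_mean(cells["ff"]),
        cov=_mean(pairs["cov"]), rho=_mean(pairs["rho"]))


def region_stats_from_rates(rate_mean, rate_var, rate_cov, region: str,
                            state: str) -> RegionStateStats:
    """RegionStateStats from per-cell rate means/variances and per-pair covariances
    (the rate-model analog, FF_j := Var(F_j)/E[F_j])."""
    rate_mean = np.asarray(rate_mean, dtype=float)
    rate_var = np.asarray(rate_var, dtype=float)
    rate_cov = np.asarray(rate_cov, dtype=float)
    n = rate_mean.size
    ff = rate_var / rate_mean
    # pairwise correlations from the covariances
    idx_pairs = [(j, k) for j in range(n) for k in range(j + 1, n)]
    if len(idx_pairs) != rate_cov.size:
        raise ValueError("rate_cov must contain one entry per unordered cell pair")
    rho = np.array([rate_cov[p] / np.sqrt(rate_var[j] * rate_var[k])
                    for p, (j, k) in enumerate(idx_pairs)])
    return summarize_population(
        {"rate": rate_mean, "var": rate_var, "ff": ff},
        {"cov": rate_cov, "rho": rho}, region, state)


def evaluate_table1(sp_ob: RegionStateStats, sp_pc: RegionStateStats,
                    ev_ob: RegionStateStats, ev_pc: RegionStateStats,
                    margin: float = 0.0) -> ConstraintReport:
    """Evaluate the 12 strict inequalities on the four population summaries.

    ``margin`` (default 0, i.e. plain strict inequality) requires each
    inequality to hold by at least that amount; useful for noisy Monte
    Carlo inputs.
    """
    for s, (r, st) in ((sp_ob, ("OB", "spontaneous")), (sp_pc, ("PC", "spontaneous")),
                       (ev_ob, ("OB", "evoked")), (ev_pc, ("PC", "evoked"))):
        if (s.region, s.state) != (r, st):
            raise ValueError(f"summary labeled {s.region}/{s.state}, expected {r}/{st}")
    gt = lambda a, b: (a - b) > margin  # noqa: E731  strict 'a > b'
    results = (
        gt(sp_ob.rate, sp_pc.rate),    # 1
        gt(ev_ob.rate, ev_pc.rate),    # 2
        gt(ev_pc.rate, sp_pc.rate),    # 3
        gt(ev_ob.rate, sp_ob.rate),    # 4
        gt(sp_pc.ff, sp_ob.ff),        # 5
        gt(ev_ob.var, ev_pc.var),      # 6
        gt(ev_ob.var, sp_ob.var),      # 7
        gt(sp_pc.ff, ev_pc.ff),        # 8
        gt(ev_ob.cov, ev_pc.cov),      # 9
        gt(sp_pc.rho, sp_ob.rho),      # 10
        gt(ev_ob.rho, ev_pc.rho),      # 11
        gt(sp_pc.rho, ev_pc.rho),      # 12
    )
    return ConstraintReport(results)
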