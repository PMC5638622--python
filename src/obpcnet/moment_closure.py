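"""Self-consistent Gaussian moment closure for the 6-cell rate network.

The stationary statistics of the coupled stochastic rate model are
approximated by assuming every within-region pair of activities
(x_j, x_k) is bivariate normal.  Eighteen statistics — 6 means, 6
variances and the 6 within-region covariances — are then solved
self-consistently by fixed-point iteration of the closed moment update
equations, replacing Monte Carlo simulation.  Cross-region covariances
are not modeled: there is no common input across regions, so any
cross-region covariance is a pure coupling effect outside the
weak-perturbation regime of the closure.

A key detail of the scheme: the correlation inside every bivariate
density is the *fixed background* noise correlation c_jk in
{0, c_OB, c_PC}, never the evolving covariance estimate (a fully
iterative variant can produce non-positive-definite pair covariances).
Firing-rate statistics are computed after convergence from the solved
activity statistics, using the same pairwise-normal assumption with the
solved pair correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quadrature import QuadratureGrid, default_grid
from .rate_model import (
    CouplingTuple,
    RateNetworkSpec,
    WITHIN_PAIRS,
    expand_coupling,
)
from .transfer import TransferFunction

__all__ = [
    "MomentState",
    "RateStats",
    "SolveReport",
    "uncoupled_moments",
    "expect_F",
    "expect_yF",
    "covariance_correction_C",
    "update_moments",
    "solve_moments",
]

_EPS = 1e-12


@dataclass
class MomentState:
    """The 18 closure statistics: means, variances and within-region covariances.

    ``cov`` is ordered as WITHIN_PAIRS: (1,2),(1,3),(2,3),(4,5),(4,6),(5,6)
    in 1-based cell labels.
    """

    mean: np.ndarray
    var: np.ndarray
    cov: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.mean, self.var, self.cov])

    def correlations(self) -> np.ndarray:
        """Implied pair correlations Cov(j,k)/sqrt(var_j var_k)."""
        out = np.empty(6)
        for p, (j, k) in enumerate(WITHIN_PAIRS):
            denom = np.sqrt(self.var[j] * self.var[k])
            out[p] = self.cov[p] / denom if denom > 0 else np.nan
        return out

    def is_valid(self) -> bool:
        """All variances positive and every pair correlation within [-1, 1]."""
        if not np.all(np.isfinite(self.as_vector())):
            return False
        if np.any(self.var <= 0):
            return False
        r = self.correlations()
        return bool(np.all(np.isfinite(r)) and np.all(np.abs(r) <= 1.0))


@dataclass
class RateStats:
    """First/second-order statistics of the firing rates F(x_j)."""

    mean: np.ndarray   # E[F(x_j)]
    var: np.ndarray    # Var(F(x_j))
    cov: np.ndarray    # Cov(F_j, F_k) for WITHIN_PAIRS

    def fano(self) -> np.ndarray:
        """Variance-over-mean analog of the Fano factor, per cell."""
        return self.var / self.mean

    def correlations(self) -> np.ndarray:
        out = np.empty(6)
        for p, (j, k) in enumerate(WITHIN_PAIRS):
            out[p] = self.cov[p] / np.sqrt(self.var[j] * self.var[k])
        return out


@dataclass
class SolveReport:
    """Outcome of the self-consistent iteration."""

    status: str                      # converged | nonconverged | invalid_covariance
    n_iter: int
    state: MomentState
    rate_stats: RateStats | None = None

    @property
    def ok(self) -> bool:
        return self.status == "converged"


# ---------------------------------------------------------------------------
# Elementary Gaussian expectations
# ---------------------------------------------------------------------------

def expect_F(m: float, s2: float, tf: TransferFunction,
             grid: QuadratureGrid | None = None, power: int = 1) -> float:
    """E[F^power(x)] for x ~ N(m, s2), on the clipped quadrature domain."""
    if s2 < 0:
        raise ValueError("variance must be non-negative")
    if power not in (1, 2):
        raise ValueError("power must be 1 or 2")
    grid = grid or default_grid()
    if s2 == 0:
        return float(tf(np.array([m]))[0] ** power)
    f = tf(np.sqrt(s2) * grid.y + m)
    return grid.gauss1d(f ** power)


def expect_yF(m: float, s2: float, tf: TransferFunction,
              grid: QuadratureGrid | None = None, c: float | None = None) -> float:
    """E[Y1 F(sqrt(s2) Y2 + m)] under the (bivariate) standard normal.

    With ``c is None`` the same-cell 1-D form  ∫ y F(sqrt(s2) y + m) ρ_SN dy
    is used; otherwise the bivariate integral with correlation ``c``
    (which vanishes at c = 0 by independence).
    """
    if s2 < 0:
        raise ValueError("variance must be non-negative")
    grid = grid or default_grid()
    f = tf(np.sqrt(s2) * grid.y + m)
    if c is None:
        return grid.stein1d(f)
    if abs(c) > 1:
        raise ValueError("|c| must be <= 1")
    if c == 1.0:
        return grid.stein1d(f)
    return grid.y1_expect(f, c)


def covariance_correction_C(mj: float, s2j: float, mk: float, s2k: float,
                            c: float, tf: TransferFunction,
                            grid: QuadratureGrid | None = None) -> float:
    """C(j,k): covariance of F(x_j), F(x_k) under the bivariate Gaussian with
    background correlation c."""
    if abs(c) > 1:
        raise ValueError("|c| must be <= 1")
    grid = grid or default_grid()
    fj = tf(np.sqrt(s2j) * grid.y + mj)
    fk = tf(np.sqrt(s2k) * grid.y + mk)
    if c == 1.0 and mj == mk and s2j == s2k:
        return grid.gauss1d(fj * fk) - grid.gauss1d(fj) * grid.gauss1d(fk)
    return grid.quadform(fj, fk, c) - grid.gauss1d(fj) * grid.gauss1d(fk)


# ---------------------------------------------------------------------------
# Moment updates
# ---------------------------------------------------------------------------

def uncoupled_moments(spec: RateNetworkSpec) -> MomentState:
    """Exact Ornstein-Uhlenbeck stationary statistics at zero coupling:
    mean mu_j, variance sigma_j^2/(2 tau), covariance c_jk sigma_j sigma_k/(2 tau)."""
    sig = spec.sigma
    mean = np.asarray(spec.mu, dtype=float).copy()
    var = sig ** 2 / (2 * spec.tau)
    cov = np.empty(6)
    for p, (j, k) in enumerate(WITHIN_PAIRS):
        cov[p] = spec.noise_corr(j, k) * sig[j] * sig[k] / (2 * spec.tau)
    return MomentState(mean, var, cov)


def _cell_integrals(state: MomentState, spec: RateNetworkSpec, grid: QuadratureGrid):
    """Per-cell 1-D integrals sharing one F evaluation per cell.

    Returns F vectors plus E_k = E[F_k], V_k = Var(F_k), S_k = E[y F_k].
    """
    s = np.sqrt(np.maximum(state.var, 0.0))
    X = s[:, None] * grid.y[None, :] + state.mean[:, None]   # (6, n_nodes)
    F = spec.transfer(X)
    B = grid.mehler_coeffs(F)                                # (6, n_mehler+1)
    E = F @ grid.w_sn
    V = (F * F) @ grid.w_sn - E ** 2
    S = F @ grid.wy_sn
    return F, B, E, V, S


def update_moments(state: MomentState, spec: RateNetworkSpec,
                   grid: QuadratureGrid | None = None) -> MomentState:
    """One full recomputation of the 18 statistics from the previous state.

    Implements the closed update equations for the 12-connection OB-PC
    topology: hub cells 1 and 4 receive from {2,3,5,6}; cells 2,3 receive
    only from cell 1; cells 5,6 only from cell 4.  All bivariate densities
    use the fixed background correlations.
    """
    grid = grid or default_grid()
    g = spec.g
    sig = spec.sigma
    tau = spec.tau
    c_ob, c_pc = spec.c_ob, spec.c_pc

    F, B, E, V, S = _cell_integrals(state, spec, grid)

    # B_k(c) = E[Y1 F(sigma(k) Y2 + mu(k))] under rho_2D(c); only the hub
    # cells' F enter these terms.
    B0 = grid.y1_expect(F[0], c_ob)
    B3 = grid.y1_expect(F[3], c_pc)

    # C(j,k) covariance corrections at the fixed background correlations.
    def C(j, k, c):
        return grid.quadform_from_coeffs(B[j], B[k], c) - E[j] * E[k]

    C12 = C(1, 2, c_ob)   # cells 2,3
    C45 = C(4, 5, c_pc)   # cells 5,6
    C10 = C(1, 0, c_ob)
    C20 = C(2, 0, c_ob)
    C43 = C(4, 3, c_pc)
    C53 = C(5, 3, c_pc)

    mean = np.asarray(spec.mu) + g @ E

    var = np.empty(6)
    # hub cells: no noise-input cross term; input-input covariance across the
    # two same-region (and two cross-region) source pairs
    var[0] = (sig[0] ** 2 / 2 + (g[0] ** 2) @ V / 2
              + g[0, 1] * g[0, 2] * C12 + g[0, 4] * g[0, 5] * C45) / tau
    var[3] = (sig[3] ** 2 / 2 + (g[3] ** 2) @ V / 2
              + g[3, 1] * g[3, 2] * C12 + g[3, 4] * g[3, 5] * C45) / tau
    # satellite cells: single input from the hub, noise-input cross term via
    # the bivariate integral at the background correlation
    var[1] = (sig[1] ** 2 / 2 + g[1, 0] ** 2 * V[0] / 2
              + sig[1] * g[1, 0] * B0 / 2) / tau
    var[2] = (sig[2] ** 2 / 2 + g[2, 0] ** 2 * V[0] / 2
              + sig[2] * g[2, 0] * B0 / 2) / tau
    var[4] = (sig[4] ** 2 / 2 + g[4, 3] ** 2 * V[3] / 2
              + sig[4] * g[4, 3] * B3 / 2) / tau
    var[5] = (sig[5] ** 2 / 2 + g[5, 3] ** 2 * V[3] / 2
              + sig[5] * g[5, 3] * B3 / 2) / tau

    cov = np.empty(6)
    # hub-satellite pairs within OB
    cov[0] = (c_ob * sig[0] * sig[1] / 2
              + sig[0] * g[1, 0] * S[0] / 4
              + sig[1] * g[0, 1] * S[1] / 4 + sig[1] * g[0, 2] * S[2] / 4
              + g[1, 0] * (g[0, 1] * C10 + g[0, 2] * C20) / 2) / tau
    cov[1] = (c_ob * sig[0] * sig[2] / 2
              + sig[0] * g[2, 0] * S[0] / 4
              + sig[2] * g[0, 1] * S[1] / 4 + sig[2] * g[0, 2] * S[2] / 4
              + g[2, 0] * (g[0, 1] * C10 + g[0, 2] * C20) / 2) / tau
    # satellite-satellite pair within OB
    cov[2] = (c_ob * sig[1] * sig[2] / 2
              + g[1, 0] * g[2, 0] * V[0] / 2
              + (sig[2] * g[1, 0] + sig[1] * g[2, 0]) * B0 / 4) / tau
    # and the PC mirror images
    cov[3] = (c_pc * sig[3] * sig[4] / 2
              + sig[3] * g[4, 3] * S[3] / 4
              + sig[4] * g[3, 4] * S[4] / 4 + sig[4] * g[3, 5] * S[5] / 4
              + g[4, 3] * (g[3, 4] * C43 + g[3, 5] * C53) / 2) / tau
    cov[4] = (c_pc * sig[3] * sig[5] / 2
              + sig[3] * g[5, 3] * S[3] / 4
              + sig[5] * g[3, 4] * S[4] / 4 + sig[5] * g[3, 5] * S[5] / 4
              + g[5, 3] * (g[3, 4] * C43 + g[3, 5] * C53) / 2) / tau
    cov[5] = (c_pc * sig[4] * sig[5] / 2
              + g[4, 3] * g[5, 3] * V[3] / 2
              + (sig[5] * g[4, 3] + sig[4] * g[5, 3]) * B3 / 4) / tau

    return MomentState(mean, var, cov)


def update_moments_specialized(state: MomentState, spec: RateNetworkSpec,
                               ct: CouplingTuple,
                               grid: QuadratureGrid | None = None) -> MomentState:
    """Symmetry-reduced update for the 4-parameter coupling tuple.

    With g21 = g31 = -gIO, g54 = g64 = -gIP, g42 = g43 = gEO,
    g15 = g16 = gEP and g12 = g13 = g45 = g46 = g_eps, the update has only
    12 distinct outputs (sigma2(3) = sigma2(2), Cov(1,3) = Cov(1,2) and the
    PC mirror images); this path computes each distinct quantity once and
    agrees with the general path to machine precision.
    """
    grid = grid or default_grid()
    sOB, sPC = spec.sigma_ob, spec.sigma_pc
    tau = spec.tau
    c_ob, c_pc = spec.c_ob, spec.c_pc
    gIO, gIP = -ct.gIO, -ct.gIP            # signed
    gEO, gEP, ge = ct.gEO, ct.gEP, ct.g_eps

    F, B, E, V, S = _cell_integrals(state, spec, grid)
    B0 = grid.y1_expect(F[0], c_ob)
    B3 = grid.y1_expect(F[3], c_pc)
    qf = grid.quadform_from_coeffs
    C12 = qf(B[1], B[2], c_ob) - E[1] * E[2]
    C45 = qf(B[4], B[5], c_pc) - E[4] * E[5]
    C10 = qf(B[1], B[0], c_ob) - E[1] * E[0]
    C20 = qf(B[2], B[0], c_ob) - E[2] * E[0]
    C43 = qf(B[4], B[3], c_pc) - E[4] * E[3]
    C53 = qf(B[5], B[3], c_pc) - E[5] * E[3]

    mu = np.asarray(spec.mu)
    mean = np.empty(6)
    mean[0] = mu[0] + gEP * (E[4] + E[5]) + ge * (E[1] + E[2])
    mean[1] = mu[1] + gIO * E[0]
    mean[2] = mu[2] + gIO * E[0]
    mean[3] = mu[3] + gEO * (E[1] + E[2]) + ge * (E[4] + E[5])
    mean[4] = mu[4] + gIP * E[3]
    mean[5] = mu[5] + gIP * E[3]

    var = np.empty(6)
    var[0] = (sOB ** 2 / 2 + gEP ** 2 * (V[4] + V[5] + 2 * C45) / 2
              + ge ** 2 * (V[1] + V[2] + 2 * C12) / 2) / tau
    var[1] = (sOB ** 2 / 2 + gIO ** 2 * V[0] / 2 + sOB * gIO * B0 / 2) / tau
    var[2] = var[1]
    var[3] = (sPC ** 2 / 2 + gEO ** 2 * (V[1] + V[2] + 2 * C12) / 2
              + ge ** 2 * (V[4] + V[5] + 2 * C45) / 2) / tau
    var[4] = (sPC ** 2 / 2 + gIP ** 2 * V[3] / 2 + sPC * gIP * B3 / 2) / tau
    var[5] = var[4]

    cov = np.empty(6)
    cov[0] = (c_ob * sOB ** 2 / 2 + sOB * gIO * S[0] / 4
              + sOB * ge * (S[1] + S[2]) / 4
              + gIO * ge * (C10 + C20) / 2) / tau
    cov[1] = cov[0]
    cov[2] = (c_ob * sOB ** 2 / 2 + gIO ** 2 * V[0] / 2 + sOB * gIO * B0 / 2) / tau
    cov[3] = (c_pc * sPC ** 2 / 2 + sPC * gIP * S[3] / 4
              + sPC * ge * (S[4] + S[5]) / 4
              + gIP * ge * (C43 + C53) / 2) / tau
    cov[4] = cov[3]
    cov[5] = (c_pc * sPC ** 2 / 2 + gIP ** 2 * V[3] / 2 + sPC * gIP * B3 / 2) / tau

    return MomentState(mean, var, cov)


# ---------------------------------------------------------------------------
# Fixed-point iteration
# ---------------------------------------------------------------------------

def _rate_statistics(state: MomentState, spec: RateNetworkSpec,
                     grid: QuadratureGrid) -> RateStats:
    """Firing-rate statistics from the solved activity statistics.

    Pairwise covariances use the bivariate normal with the *solved* pair
    correlation (not the background one) — only (x_j, x_k) is assumed
    normal, never (F_j, F_k)."""
    s = np.sqrt(np.maximum(state.var, 0.0))
    F = spec.transfer(s[:, None] * grid.y[None, :] + state.mean[:, None])
    B = grid.mehler_coeffs(F)
    E = F @ grid.w_sn
    V = (F * F) @ grid.w_sn - E ** 2
    r = state.correlations()
    cov = np.empty(6)
    for p, (j, k) in enumerate(WITHIN_PAIRS):
        rp = float(np.clip(r[p], -1.0, 1.0))
        if abs(rp) >= 1.0 - 1e-12:
            # degenerate: comonotone pair
            cov[p] = np.sign(rp) * np.sqrt(V[j] * V[k])
        elif abs(rp) > 0.98:
            # spectral series converges slowly near |r| = 1
            cov[p] = grid.quadform(F[j], F[k], rp) - E[j] * E[k]
        else:
            cov[p] = grid.quadform_from_coeffs(B[j], B[k], rp) - E[j] * E[k]
    return RateStats(E, V, cov)


def solve_moments(spec: RateNetworkSpec, grid: QuadratureGrid | None = None,
                  tol: float = 1e-6, max_iter: int = 50, damping: float = 1.0,
                  coupling: CouplingTuple | None = None,
                  compute_rate_stats: bool = True) -> SolveReport:
    """Solve the 18 closure statistics by plain fixed-point iteration.

    Starts from the exact uncoupled statistics and iterates the moment
    update until every statistic changes by a relative amount
    |Δ|/max(|value|, 1e-12) ≤ ``tol`` (converged), or ``max_iter``
    iterations elapse (nonconverged).  Covariance validity — every
    within-region pair correlation in [-1, 1] with positive variances —
    is classified after the convergence status; rate statistics are
    attached only for converged, valid solutions.

    ``coupling`` selects the symmetry-reduced specialized update (the
    spec's g matrix must equal its expansion); ``damping`` < 1 blends the
    update with the previous state.
    """
    grid = grid or default_grid()
    if coupling is not None and not np.array_equal(spec.g, expand_coupling(coupling)):
        raise ValueError("spec.g does not match the supplied coupling tuple")

    state = uncoupled_moments(spec)
    status = "nonconverged"
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if coupling is not None:
            new = update_moments_specialized(state, spec, coupling, grid)
        else:
            new = update_moments(state, spec, grid)
        if damping != 1.0:
            new = MomentState(
                damping * new.mean + (1 - damping) * state.mean,
                damping * new.var + (1 - damping) * state.var,
                damping * new.cov + (1 - damping) * state.cov)
        v_old, v_new = state.as_vector(), new.as_vector()
        if not np.all(np.isfinite(v_new)):
            return SolveReport("invalid_covariance", n_iter, new)
        delta = np.abs(v_new - v_old) / np.maximum(np.abs(v_old), _EPS)
        state = new
        if np.all(delta <= tol):
            status = "converged"
            break
    if status == "converged" and not state.is_valid():
        return SolveReport("invalid_covariance", n_iter, state)
    rs = None
    if status == "converged" and compute_rate_stats:
        rs = _rate_statistics(state, spec, grid)
    return SolveReport(status, n_iter, state, rs)
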