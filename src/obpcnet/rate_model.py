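"""Six-population stochastic firing-rate (Wilson-Cowan) model of the OB-PC circuit.

Two reciprocally coupled regions are modeled: the olfactory bulb (OB,
cells 0-2, cell 0 inhibitory granule) and the anterior piriform cortex
(PC, cells 3-5, cell 3 inhibitory).  Each cell obeys

    tau dx_j = (-x_j + mu_j + sum_k g_jk F(x_k)) dt + sigma_j dW_j

with white noise correlated *within* a region (c_OB, c_PC) and
uncorrelated across regions.  The transfer function F maps activity to
firing rate, nu_j = F(x_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .transfer import TransferFunction, sigmoid_transfer, eval_transfer

__all__ = [
    "OB_CELLS",
    "PC_CELLS",
    "WITHIN_PAIRS",
    "CouplingTuple",
    "RateNetworkSpec",
    "MU_SPONTANEOUS",
    "MU_EVOKED",
    "expand_coupling",
    "table2_spec",
    "spec_pair",
    "simulate_rate_mc",
    "trace_moments",
    "RateMCResult",
]

OB_CELLS = (0, 1, 2)
PC_CELLS = (3, 4, 5)
#: within-region cell pairs, OB first: (0,1),(0,2),(1,2),(3,4),(3,5),(4,5)
WITHIN_PAIRS = ((0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5))

# Default mean inputs; the evoked state doubles the three OB inputs.
MU_SPONTANEOUS = (13 / 60, 9 / 60, 7 / 60, 9 / 60, 5 / 60, 3 / 60)
MU_EVOKED = (26 / 60, 18 / 60, 14 / 60, 9 / 60, 5 / 60, 3 / 60)

# Allowed coupling topology: (post, pre) entries that may be nonzero.
TOPOLOGY = frozenset(
    [(0, 1), (0, 2), (0, 4), (0, 5), (1, 0), (2, 0),
     (3, 1), (3, 2), (3, 4), (3, 5), (4, 3), (5, 3)]
)


@dataclass(frozen=True)
class CouplingTuple:
    """The four variable coupling magnitudes plus the fixed weak E->I strength.

    Magnitudes are stored positive; the inhibitory ones (gIO, gIP) are
    applied with a negative sign when expanded into the 6x6 matrix.

    gIO : within-OB  I->E strength (granule onto M/T)
    gIP : within-PC  I->E strength
    gEO : OB->PC     E->I strength
    gEP : PC->OB     E->I strength
    g_eps : within-region E->I strength (fixed at 0.1)
    """

    gIO: float
    gIP: float
    gEO: float
    gEP: float
    g_eps: float = 0.1

    def __post_init__(self):
        for name in ("gIO", "gIP", "gEO", "gEP", "g_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"coupling magnitude {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.gIO, self.gEO, self.gIP, self.gEP])

    def signed(self) -> np.ndarray:
        """(gIO, gEO, gIP, gEP) with inhibitory entries negative."""
        return np.array([-self.gIO, self.gEO, -self.gIP, self.gEP])


def expand_coupling(ct: CouplingTuple) -> np.ndarray:
    """Expand a coupling tuple into the signed 6x6 matrix g[post, pre].

    Exactly twelve entries are nonzero when all magnitudes are positive:
    g[1,0] = g[2,0] = -gIO;  g[4,3] = g[5,3] = -gIP;
    g[3,1] = g[3,2] = +gEO;  g[0,4] = g[0,5] = +gEP;
    g[0,1] = g[0,2] = g[3,4] = g[3,5] = g_eps.
    """
    g = np.zeros((6, 6))
    g[1, 0] = g[2, 0] = -ct.gIO
    g[4, 3] = g[5, 3] = -ct.gIP
    g[3, 1] = g[3, 2] = ct.gEO
    g[0, 4] = g[0, 5] = ct.gEP
    g[0, 1] = g[0, 2] = ct.g_eps
    g[3, 4] = g[3, 5] = ct.g_eps
    return g


@dataclass(frozen=True)
class RateNetworkSpec:
    """Full parameterization of the 6-cell stochastic rate network."""

    mu: tuple = MU_SPONTANEOUS
    sigma_ob: float = 1.4
    sigma_pc: float = 2.0
    c_ob: float = 0.3
    c_pc: float = 0.35
    tau: float = 1.0
    g: np.ndarray = field(default_factory=lambda: np.zeros((6, 6)))
    transfer: TransferFunction = field(default_factory=sigmoid_transfer)

    def __post_init__(self):
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        if len(self.mu) != 6:
            raise ValueError("mu must have 6 entries")
        if g.shape != (6, 6):
            raise ValueError("g must be 6x6")
        if np.any(np.diag(g) != 0):
            raise ValueError("no autapses: diagonal of g must be zero")
        if self.sigma_ob <= 0 or self.sigma_pc <= 0:
            raise ValueError("noise amplitudes must be positive")
        for c in (self.c_ob, self.c_pc):
            if not 0 <= c < 1:
                raise ValueError("background noise correlations must lie in [0, 1)")
        bad = [(j, k) for j in range(6) for k in range(6)
               if g[j, k] != 0 and (j, k) not in TOPOLOGY]
        if bad:
            raise ValueError(f"coupling entries outside the supported topology: {bad}")

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma_ob] * 3 + [self.sigma_pc] * 3)

    def noise_corr(self, j: int, k: int) -> float:
        """Background noise correlation c_jk (0 across regions, 1 on the diagonal)."""
        if j == k:
            return 1.0
        if j in OB_CELLS and k in OB_CELLS:
            return self.c_ob
        if j in PC_CELLS and k in PC_CELLS:
            return self.c_pc
        return 0.0

    def with_coupling(self, ct: CouplingTuple) -> "RateNetworkSpec":
        return replace(self, g=expand_coupling(ct))


def table2_spec(state: str = "spontaneous",
                coupling: CouplingTuple | None = None) -> RateNetworkSpec:
    """Default network parameterization for one activity state.

    The evoked state doubles the three OB mean inputs; everything else is
    identical between states.
    """
    if state not in ("spontaneous", "evoked"):
        raise ValueError("state must be 'spontaneous' or 'evoked'")
    mu = MU_SPONTANEOUS if state == "spontaneous" else MU_EVOKED
    g = expand_coupling(coupling) if coupling is not None else np.zeros((6, 6))
    return RateNetworkSpec(mu=mu, g=g)


def spec_pair(coupling: CouplingTuple | None = None):
    """(spontaneous, evoked) spec pair differing only in OB mean inputs."""
    return table2_spec("spontaneous", coupling), table2_spec("evoked", coupling)


# ---------------------------------------------------------------------------
# Monte Carlo simulation (Euler-Maruyama)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mc_kernel(mu, sigma, c_ob, c_pc, g, tau, dt, n_steps, n_equil, n_real,
               rng, bound, thin, samples):
    """Euler-Maruyama integration with moment accumulation.

    Noise per cell: sigma_j*(sqrt(1-c)*eta_j + sqrt(c)*xi_region) with the
    common term shared only within a region; increments scale as sqrt(dt).
    Returns accumulated sums for activity and firing-rate first/second
    moments plus the count of diverged realizations.
    """
    sqdt = np.sqrt(dt)
    a_ob = np.sqrt(1.0 - c_ob)
    b_ob = np.sqrt(c_ob)
    a_pc = np.sqrt(1.0 - c_pc)
    b_pc = np.sqrt(c_pc)
    pairs = np.array([[0, 1], [0, 2], [1, 2], [3, 4], [3, 5], [4, 5]])

    sx = np.zeros(6)
    sxx = np.zeros(6)
    sxp = np.zeros(6)
    sf = np.zeros(6)
    sff = np.zeros(6)
    sfp = np.zeros(6)
    n_samp = 0
    n_div = 0
    store = samples.shape[0] > 0

    x = np.empty((n_real, 6))
    for r in range(n_real):
        for j in range(6):
            x[r, j] = mu[j]
    alive = np.ones(n_real, np.bool_)
    F = np.empty(6)
    kept = 0
    for step in range(n_steps):
        z = rng.standard_normal(n_real * 8)
        sample = step >= n_equil
        keep = store and sample and (step - n_equil) % thin == 0
        for r in range(n_real):
            if not alive[r]:
                continue
            for j in range(6):
                F[j] = 0.5 * (1.0 + np.tanh((x[r, j] - 0.5) / 0.1))
            xi_o = z[r * 8 + 6]
            xi_p = z[r * 8 + 7]
            for j in range(6):
                drive = -x[r, j] + mu[j]
                for k in range(6):
                    if g[j, k] != 0.0:
                        drive += g[j, k] * F[k]
                if j < 3:
                    eta = a_ob * z[r * 8 + j] + b_ob * xi_o
                else:
                    eta = a_pc * z[r * 8 + j] + b_pc * xi_p
                x[r, j] += dt * drive / tau + sigma[j] * sqdt * eta / tau
                if np.abs(x[r, j]) > bound:
                    alive[r] = False
            if sample and alive[r]:
                for j in range(6):
                    xv = x[r, j]
                    fv = 0.5 * (1.0 + np.tanh((xv - 0.5) / 0.1))
                    F[j] = fv
                    sx[j] += xv
                    sxx[j] += xv * xv
                    sf[j] += fv
                    sff[j] += fv * fv
                for pp in range(6):
                    sxp[pp] += x[r, pairs[pp, 0]] * x[r, pairs[pp, 1]]
                    sfp[pp] += F[pairs[pp, 0]] * F[pairs[pp, 1]]
                n_samp += 1
                if keep and kept < samples.shape[1]:
                    for j in range(6):
                        samples[r, kept, j] = x[r, j]
        if keep:
            kept += 1
    n_div = n_real - int(alive.sum())
    return sx, sxx, sxp, sf, sff, sfp, n_samp, n_div


@dataclass
class RateMCResult:
    """Accumulated Monte Carlo moment estimates for the rate network."""

    mean: np.ndarray         # activity mean per cell
    var: np.ndarray          # activity variance per cell
    cov: np.ndarray          # activity covariance, WITHIN_PAIRS order
    rate_mean: np.ndarray    # E[F(x_j)]
    rate_var: np.ndarray     # Var(F(x_j))
    rate_cov: np.ndarray     # Cov(F_j, F_k), WITHIN_PAIRS order
    n_samples: int
    n_diverged: int
    samples: np.ndarray | None = None  # optional thinned activity samples

    @property
    def diverged(self) -> bool:
        return self.n_diverged > 0


def simulate_rate_mc(spec: RateNetworkSpec, dt: float = 0.01, t_end: float = 500.0,
                     n_real: int = 3000, t_equil: float = 100.0, seed: int = 0,
                     thin: int | None = None,
                     divergence_bound: float = 1e3) -> RateMCResult:
    """Monte Carlo estimate of the stationary activity and rate statistics.

    Each realization starts at x_j(0) = mu_j, is integrated with
    Euler-Maruyama at step ``dt``, and is sampled at every step after the
    equilibration period ``t_equil``.  ``thin`` (in steps) additionally
    stores raw activity samples for distributional checks.  A realization
    whose activity exceeds ``divergence_bound`` is flagged divergent and
    excluded, never silently truncated.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_equil >= t_end:
        raise ValueError("t_equil must be smaller than t_end")
    if spec.transfer.kind != "sigmoid":
        raise NotImplementedError("Monte Carlo path is compiled for the sigmoid transfer")
    n_steps = int(round(t_end / dt))
    n_equil = int(round(t_equil / dt))
    if thin is not None:
        n_keep = (n_steps - n_equil + thin - 1) // thin
        samples = np.empty((n_real, n_keep, 6))
    else:
        samples = np.empty((0, 0, 6))
    sx, sxx, sxp, sf, sff, sfp, n, n_div = _mc_kernel(
        np.asarray(spec.mu, dtype=float), spec.sigma, spec.c_ob, spec.c_pc,
        np.asarray(spec.g, dtype=float), spec.tau, dt, n_steps, n_equil,
        n_real, np.random.default_rng(int(seed) % (2 ** 31)), divergence_bound,
        1 if thin is None else int(thin), samples)
    if n < 2:
        return RateMCResult(*(np.full(6, np.nan),) * 6, n_samples=int(n),
                            n_diverged=int(n_div))
    mean = sx / n
    var = (sxx - n * mean ** 2) / (n - 1)
    rmean = sf / n
    rvar = (sff - n * rmean ** 2) / (n - 1)
    cov = np.empty(6)
    rcov = np.empty(6)
    for p, (j, k) in enumerate(WITHIN_PAIRS):
        cov[p] = (sxp[p] - n * mean[j] * mean[k]) / (n - 1)
        rcov[p] = (sfp[p] - n * rmean[j] * rmean[k]) / (n - 1)
    return RateMCResult(mean, var, cov, rmean, rvar, rcov, int(n), int(n_div),
                        samples if thin is not None else None)


def trace_moments(samples: np.ndarray, transfer: TransferFunction | None = None):
    """Unbiased sample moments of activity traces, plus firing-rate statistics.

    ``samples`` has shape (n_observations, 6).  Firing-rate statistics are
    obtained by applying F pointwise to the samples before averaging.
    Returns a :class:`RateMCResult` (without raw samples).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 6:
        raise ValueError("samples must have shape (n, 6)")
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples per cell")
    tf = transfer if transfer is not None else sigmoid_transfer()
    rates = eval_transfer(tf, samples)
    mean = samples.mean(axis=0)
    var = samples.var(axis=0, ddof=1)
    rmean = rates.mean(axis=0)
    rvar = rates.var(axis=0, ddof=1)
    cov = np.empty(6)
    rcov = np.empty(6)
    for p, (j, k) in enumerate(WITHIN_PAIRS):
        cov[p] = np.cov(samples[:, j], samples[:, k], ddof=1)[0, 1]
        rcov[p] = np.cov(rates[:, j], rates[:, k], ddof=1)[0, 1]
    return RateMCResult(mean, var, cov, rmean, rvar, rcov,
                        n_samples=samples.shape[0], n_diverged=0)
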