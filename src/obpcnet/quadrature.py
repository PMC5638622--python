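"""Trapezoidal Gaussian quadrature on a clipped domain.

All expectations in the moment-closure solver are taken against the
standard normal density restricted to [-3, 3] with a uniform mesh of
0.01 and trapezoidal weights.  The Gaussian mass on the clipped domain
(~0.9973) is deliberately *not* rescaled; the clipped-domain convention
is part of the numerical scheme.  A wider domain and/or finer mesh can
be requested for oracle/refinement checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["QuadratureGrid", "default_grid"]


def _std_normal(y: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * y * y) / np.sqrt(2.0 * np.pi)


def _bivariate_normal(y1: np.ndarray, y2: np.ndarray, c: float) -> np.ndarray:
    """Standard bivariate normal density with correlation c on a tensor grid."""
    if abs(c) >= 1.0:
        raise ValueError("correlation must satisfy |c| < 1 for the bivariate density")
    d = 1.0 - c * c
    q = (y1[:, None] ** 2 - 2.0 * c * np.outer(y1, y2) + y2[None, :] ** 2) / (2.0 * d)
    return np.exp(-q) / (2.0 * np.pi * np.sqrt(d))


class QuadratureGrid:
    """Uniform grid with trapezoidal weights for 1-D and 2-D Gaussian integrals.

    Parameters
    ----------
    lo, hi : float
        Domain of the standard-normal variable(s).
    mesh : float
        Uniform mesh size (0.01 reproduces the reference scheme).
    """

    def __init__(self, lo: float = -3.0, hi: float = 3.0, mesh: float = 0.01):
        n = int(round((hi - lo) / mesh)) + 1
        self.lo, self.hi, self.mesh = float(lo), float(hi), float(mesh)
        self.y = np.linspace(lo, hi, n)
        w = np.full(n, mesh)
        w[0] = w[-1] = 0.5 * mesh
        self.w_trapz = w
        self.rho_sn = _std_normal(self.y)
        self.w_sn = w * self.rho_sn          # weights for  ∫ f(y) ρ_SN(y) dy
        self.wy_sn = self.w_sn * self.y      # weights for  ∫ y f(y) ρ_SN(y) dy
        self._w1: dict[float, np.ndarray] = {}
        self._W: dict[float, np.ndarray] = {}
        self._hermite: np.ndarray | None = None
        self._cpow: dict[float, np.ndarray] = {}
        self.n_mehler = 400

    # -- cached per-correlation structures ---------------------------------
    def _weight_matrix(self, c: float) -> np.ndarray:
        """W(c) with  f1ᵀ W f2 = ∬ f1(y1) f2(y2) ρ_2D(y1,y2;c) dy1 dy2  (trapz)."""
        c = float(c)
        if c not in self._W:
            rho = _bivariate_normal(self.y, self.y, c)
            self._W[c] = rho * np.outer(self.w_trapz, self.w_trapz)
        return self._W[c]

    def _y1_weights(self, c: float) -> np.ndarray:
        """w1(c) with  w1 · f = ∬ y1 f(y2) ρ_2D(y1,y2;c) dy1 dy2  (trapz)."""
        c = float(c)
        if c not in self._w1:
            rho = _bivariate_normal(self.y, self.y, c)
            self._w1[c] = ((self.w_trapz * self.y) @ rho) * self.w_trapz
        return self._w1[c]

    # -- public integral helpers -------------------------------------------
    @property
    def gauss_mass(self) -> float:
        """∫ ρ_SN over the clipped domain (≈ 0.9973 for [-3, 3])."""
        return float(self.w_sn.sum())

    def gauss1d(self, fvals: np.ndarray) -> float:
        """∫ f(y) ρ_SN(y) dy over the clipped domain."""
        return float(self.w_sn @ fvals)

    def stein1d(self, fvals: np.ndarray) -> float:
        """∫ y f(y) ρ_SN(y) dy over the clipped domain."""
        return float(self.wy_sn @ fvals)

    def y1_expect(self, fvals: np.ndarray, c: float) -> float:
        """∬ y1 f(y2) ρ_2D(y1, y2; c) dy1 dy2."""
        return float(self._y1_weights(c) @ fvals)

    def quadform(self, f1: np.ndarray, f2: np.ndarray, c: float) -> float:
        """∬ f1(y1) f2(y2) ρ_2D(y1, y2; c) dy1 dy2 (dense trapezoid)."""
        return float(f1 @ self._weight_matrix(c) @ f2)

    # -- spectral evaluation of the bivariate forms ------------------------
    def _hermite_matrix(self) -> np.ndarray:
        """Orthonormal (probabilists') Hermite polynomials on the grid.

        Mehler's expansion ρ_2D(y1,y2;c) = ρ_SN(y1)ρ_SN(y2) Σ_n cⁿ hₙ(y1)hₙ(y2)
        holds pointwise, so the dense trapezoidal quadform equals
        Σ_n cⁿ bₙ(f1) bₙ(f2) with bₙ(f) = Σ_i w_sn,i hₙ(y_i) f_i — exactly,
        up to series truncation.  This factorization makes the bivariate
        integrals at arbitrary correlation cheap.
        """
        if self._hermite is None:
            n = self.n_mehler
            H = np.empty((self.y.size, n + 1))
            H[:, 0] = 1.0
            H[:, 1] = self.y
            for k in range(1, n):
                H[:, k + 1] = (self.y * H[:, k] - np.sqrt(k) * H[:, k - 1]) / np.sqrt(k + 1)
            self._hermite = H
        return self._hermite

    def mehler_coeffs(self, f: np.ndarray) -> np.ndarray:
        """bₙ(f) = ∫ f(y) hₙ(y) ρ_SN(y) dy for n = 0..n_mehler (trapz).

        ``f`` may be (n_nodes,) or a stack (m, n_nodes); coefficients are
        returned along the last axis.
        """
        return (self.w_sn * f) @ self._hermite_matrix()

    def _powers(self, c: float) -> np.ndarray:
        c = float(c)
        if c not in self._cpow:
            self._cpow[c] = np.power(c, np.arange(self.n_mehler + 1))
        return self._cpow[c]

    def quadform_from_coeffs(self, b1: np.ndarray, b2: np.ndarray, c: float) -> float:
        """Σ_n cⁿ b1ₙ b2ₙ — the spectral quadform; b1[0] b2[0] is the c=0 term."""
        return float((self._powers(c) * b1) @ b2)


_DEFAULT: QuadratureGrid | None = None


def default_grid() -> QuadratureGrid:
    """The module-wide default grid ([-3, 3], mesh 0.01), built lazily."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = QuadratureGrid()
    return _DEFAULT
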