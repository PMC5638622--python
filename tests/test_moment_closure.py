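"""Gaussian moment closure: elementary expectations, updates, fixed point."""

import numpy as np
import pytest

from obpcnet.moment_closure import (
    covariance_correction_C,
    expect_F,
    expect_yF,
    solve_moments,
    uncoupled_moments,
    update_moments,
    update_moments_specialized,
)
from obpcnet.rate_model import CouplingTuple, RateNetworkSpec, simulate_rate_mc, table2_spec
from obpcnet.transfer import TransferFunction, sigmoid_transfer


class TestExpectF:
    def test_midpoint_symmetry_for_any_variance(self, grid, wide_grid):
        # F is symmetric about X = 0.5, so E[F] is half the Gaussian mass on
        # the (clipped, unrenormalized) domain: exactly 0.5 on a wide grid
        tf = sigmoid_transfer()
        for s2 in (0.5, 2.0):
            assert expect_F(0.5, s2, tf, grid) == pytest.approx(
                0.5 * grid.gauss_mass, abs=1e-9)
            assert expect_F(0.5, s2, tf, wide_grid) == pytest.approx(0.5, abs=1e-9)
        assert expect_F(0.5, 0.0, tf, grid) == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_degenerates_to_pointwise(self, grid):
        tf = sigmoid_transfer()
        assert expect_F(0.8, 0.0, tf, grid) == pytest.approx(
            float(tf(np.array([0.8]))[0]))

    def test_against_refined_mesh_oracle(self, grid):
        tf = sigmoid_transfer()
        oracle_grid = type(grid)(mesh=1e-4)
        val = expect_F(0.3, 0.98, tf, grid)
        oracle = expect_F(0.3, 0.98, tf, oracle_grid)
        assert val == pytest.approx(oracle, abs=1e-5)

    def test_negative_variance_rejected(self, grid):
        with pytest.raises(ValueError):
            expect_F(0.0, -1.0, sigmoid_transfer(), grid)


class TestExpectYF:
    def test_zero_correlation_vanishes(self, grid):
        assert expect_yF(0.5, 1.0, sigmoid_transfer(), grid, c=0.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_steins_identity_for_linear_transfer(self, wide_grid):
        # F = identity: E[Y (a Y + m)] = a = sqrt(s2)
        ident = TransferFunction(kind="custom", func=lambda x: x, rmax=np.inf)
        s2 = 1.7
        val = expect_yF(0.4, s2, ident, wide_grid)
        assert val == pytest.approx(np.sqrt(s2), rel=1e-6)

    def test_bivariate_against_refined_mesh_oracle(self, grid):
        tf = sigmoid_transfer()
        oracle_grid = type(grid)(mesh=1e-3)
        val = expect_yF(0.5, 1.0, tf, grid, c=0.3)
        oracle = expect_yF(0.5, 1.0, tf, oracle_grid, c=0.3)
        assert val == pytest.approx(oracle, abs=1e-5)

    def test_out_of_range_correlation_rejected(self, grid):
        with pytest.raises(ValueError):
            expect_yF(0.0, 1.0, sigmoid_transfer(), grid, c=1.5)


class TestCovarianceCorrection:
    def test_independence_gives_zero(self, grid):
        assert covariance_correction_C(0.3, 1.0, 0.4, 1.5, 0.0,
                                       sigmoid_transfer(), grid) == pytest.approx(
            0.0, abs=1e-12)

    def test_identical_cell_limit_is_variance(self, grid):
        tf = sigmoid_transfer()
        c = covariance_correction_C(0.3, 0.98, 0.3, 0.98, 1.0, tf, grid)
        var = expect_F(0.3, 0.98, tf, grid, power=2) - expect_F(0.3, 0.98, tf, grid) ** 2
        assert c == pytest.approx(var, rel=1e-10)

    def test_positive_for_symmetric_marginals(self, grid):
        tf = sigmoid_transfer()
        oracle_grid = type(grid)(mesh=1e-3)
        val = covariance_correction_C(0.5, 1.0, 0.5, 1.0, 0.35, tf, grid)
        oracle = covariance_correction_C(0.5, 1.0, 0.5, 1.0, 0.35, tf, oracle_grid)
        assert val > 0
        assert val == pytest.approx(oracle, abs=1e-5)


class TestUncoupledMoments:
    def test_closed_form_values(self, spont_spec):
        m = uncoupled_moments(spont_spec)
        assert m.var[:3] == pytest.approx([0.98] * 3)
        assert m.var[3:] == pytest.approx([2.0] * 3)
        assert m.cov[:3] == pytest.approx([0.294] * 3)
        assert m.cov[3:] == pytest.approx([0.7] * 3)

    def test_tau_scaling(self):
        import dataclasses
        spec = table2_spec("spontaneous")
        spec2 = dataclasses.replace(spec, tau=2.0)
        m1, m2 = uncoupled_moments(spec), uncoupled_moments(spec2)
        assert m2.var == pytest.approx(m1.var / 2)
        assert m2.cov == pytest.approx(m1.cov / 2)


class TestUpdateFixedPoint:
    def test_zero_coupling_fixed_point(self, spont_spec, grid):
        m0 = uncoupled_moments(spont_spec)
        m1 = update_moments(m0, spont_spec, grid)
        assert m1.as_vector() == pytest.approx(m0.as_vector(), abs=1e-14)

    def test_symmetric_satellite_cells(self, spont_spec, grid, weak_tuple):
        # with g21 = g31 the update gives sigma2(3) = sigma2(2) and
        # Cov(1,3) = Cov(1,2) exactly
        spec = spont_spec.with_coupling(weak_tuple)
        m = update_moments(uncoupled_moments(spec), spec, grid)
        assert m.var[2] == m.var[1]
        assert m.cov[1] == m.cov[0]
        assert m.var[5] == m.var[4]
        assert m.cov[4] == m.cov[3]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_general_equals_specialized(self, spont_spec, grid, seed):
        rng = np.random.default_rng(seed)
        ct = CouplingTuple(*rng.uniform(0.05, 1.5, size=4))
        spec = spont_spec.with_coupling(ct)
        state = uncoupled_moments(spec)
        for _ in range(3):
            a = update_moments(state, spec, grid)
            b = update_moments_specialized(state, spec, ct, grid)
            assert np.abs(a.as_vector() - b.as_vector()).max() <= 1e-10
            state = a


class TestSolve:
    def test_zero_coupling_exact_in_two_iterations(self, spont_spec):
        rep = solve_moments(spont_spec)
        assert rep.status == "converged"
        assert rep.n_iter <= 2
        exact = uncoupled_moments(spont_spec)
        assert rep.state.as_vector() == pytest.approx(exact.as_vector(), abs=1e-14)

    def test_weak_coupling_converges_with_valid_correlations(self, spont_spec,
                                                             weak_tuple):
        rep = solve_moments(spont_spec.with_coupling(weak_tuple),
                            coupling=weak_tuple)
        assert rep.status == "converged"
        assert np.all(np.abs(rep.state.correlations()) <= 1)
        assert rep.rate_stats is not None
        assert np.all((rep.rate_stats.mean > 0) & (rep.rate_stats.mean < 1))

    def test_extreme_coupling_never_silently_answers(self, spont_spec):
        ct = CouplingTuple(50, 50, 50, 50)
        rep = solve_moments(spont_spec.with_coupling(ct), coupling=ct)
        assert rep.status in ("nonconverged", "invalid_covariance")
        assert rep.rate_stats is None

    def test_mesh_halving_stability(self, spont_spec, grid, fine_grid):
        ct = CouplingTuple(0.5, 0.7, 0.9, 0.6)
        spec = spont_spec.with_coupling(ct)
        a = solve_moments(spec, grid, coupling=ct)
        b = solve_moments(spec, fine_grid, coupling=ct)
        assert np.abs(a.state.as_vector() - b.state.as_vector()).max() < 1e-5

    def test_mismatched_coupling_tuple_rejected(self, spont_spec, weak_tuple):
        with pytest.raises(ValueError):
            solve_moments(spont_spec, coupling=weak_tuple)

    def test_label_permutation_symmetry(self, grid):
        # swapping the parameters of cells 2 and 3 swaps their statistics
        ct = CouplingTuple(0.4, 0.6, 0.5, 0.3)
        spec = table2_spec("spontaneous", ct)
        mu = list(spec.mu)
        mu[1], mu[2] = mu[2], mu[1]
        import dataclasses
        spec_swapped = dataclasses.replace(spec, mu=tuple(mu))
        a = solve_moments(spec, grid, coupling=ct)
        b = solve_moments(spec_swapped, grid, coupling=ct)
        assert a.state.mean[1] == pytest.approx(b.state.mean[2], abs=1e-12)
        assert a.state.mean[2] == pytest.approx(b.state.mean[1], abs=1e-12)
        assert a.state.var[1] == pytest.approx(b.state.var[2], abs=1e-12)


class TestClosureAgainstMonteCarlo:
    """The closure is an approximation; at weak coupling it must agree with
    direct simulation (first order tightly, second order within ~10%)."""

    @pytest.mark.parametrize("seed", [0, 1])
    def test_weak_coupling_agreement(self, base_pair, seed):
        rng = np.random.default_rng(100 + seed)
        ct = CouplingTuple(*rng.uniform(0.05, 0.5, size=4))
        spec = base_pair[0].with_coupling(ct)
        rep = solve_moments(spec, coupling=ct)
        assert rep.status == "converged"
        mc = simulate_rate_mc(spec, dt=0.01, t_end=150.0, n_real=600,
                              t_equil=50.0, seed=seed)
        n_eff = mc.n_samples / 200.0   # ~2 tau decorrelation at dt = 0.01
        se_mean = np.sqrt(mc.var / n_eff)
        assert np.all(np.abs(rep.state.mean - mc.mean) < 3 * se_mean + 1e-3)
        se_rate = np.sqrt(mc.rate_var / n_eff)
        assert np.all(np.abs(rep.rate_stats.mean - mc.rate_mean)
                      < 3 * se_rate + 1e-3)
        assert rep.state.var == pytest.approx(mc.var, rel=0.10)
        # second-order accuracy degrades toward the top of the weak-coupling
        # range; covariances stay within ~20% there
        assert rep.state.cov == pytest.approx(mc.cov, rel=0.20)
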