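"""Rate-equation integrator, stationary oracle, summaries, FP terms."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from pwlid.population import (CellCycleConfig, PopulationState, StepSizeError,
                              classify_dynamics, distribution_moments,
                              equilibrate, fp_decompose, initial_state,
                              integrate, marginalise, partition_matrix,
                              stationary_distribution, step, summarise)
from pwlid.rates import (RateSystem, SetPointCurve, birth_death_system,
                         pwl_system)


def matched_rates(N):
    """P and D identical as functions (both rise from the (0,0) anchor)."""
    P = SetPointCurve("production", [0, N // 2, N], [0.0, 4.0, 2.0])
    D = SetPointCurve("degradation", [N // 2, N], [4.0, 2.0])
    return RateSystem(P, D, 0.0, N)


class TestStep:
    def test_zero_growth_conserves_cells(self, small_system, cfg):
        state = initial_state(10, cfg.k, histogram=np.ones(11))
        out = step(state, small_system, cfg)
        assert out.M == pytest.approx(state.M, abs=1e-14)

    def test_null_dynamics_is_identity(self, cfg):
        rs = pwl_system(10, [0, 0, 0], [0, 0, 0])
        state = initial_state(10, cfg.k, histogram=np.arange(11, dtype=float))
        out = step(state, rs, cfg)
        assert np.array_equal(out.F, state.F)

    def test_division_adds_cells_and_halves_molecules(self, cfg):
        # single cell mass at (n=4, phase k): divisions occur at rate g
        # and each daughter carries Binomial(4, 1/2) molecules
        g = 0.2
        rs = pwl_system(10, [0, 0, 0], [0, 0, 0], g_y=g)
        F = np.zeros((11, cfg.k))
        F[4, cfg.k - 1] = 1.0
        out = step(PopulationState(F), rs, cfg)
        # two daughters replace one mother: net +1 cell per division
        assert out.M == pytest.approx(1.0 + g * cfg.dt)
        # brute-force expectation of b(n | 4, 1/2): 2 molecules per daughter
        daughters = out.F[:, 0]
        expected = 2.0 * g * cfg.dt * stats.binom.pmf(np.arange(11), 4, 0.5)
        assert np.allclose(daughters, expected)
        assert np.arange(11) @ daughters / daughters.sum() == pytest.approx(2.0)

    def test_oversized_step_raises(self, small_system):
        cfg = CellCycleConfig(dt=1.0)  # (P+D) * dt > 1 somewhere
        state = initial_state(10, cfg.k, histogram=np.ones(11))
        with pytest.raises(StepSizeError):
            step(state, small_system, cfg)

    def test_cell_count_growth_matches_division_flux(self, cfg):
        rs = pwl_system(10, [4, 4, 4], [1, 2, 3], g_y=0.3)
        state = initial_state(10, cfg.k, histogram=np.ones(11))
        # spread mass over phases so phase k is populated
        state = PopulationState(np.tile(state.F.sum(1, keepdims=True) / cfg.k,
                                        (1, cfg.k)))
        tables = rs.rate_tables(cfg.k)
        expected_flux = float((tables["G"][:, -1] * state.F[:, -1]).sum())
        out = step(state, rs, cfg)
        assert (out.M - state.M) / cfg.dt == pytest.approx(expected_flux)


class TestIntegrate:
    def test_zero_horizon_is_identity(self, small_system, cfg):
        state = initial_state(10, cfg.k, histogram=np.ones(11))
        out = integrate(state, small_system, cfg, state.t)
        assert np.array_equal(out[-1].F, state.F)

    def test_fixed_step_semigroup(self, small_system, cfg):
        state = initial_state(10, cfg.k)
        once = integrate(state, small_system, cfg, 2.0)[-1]
        half = integrate(state, small_system, cfg, 1.0)[-1]
        twice = integrate(half, small_system, cfg, 2.0)[-1]
        assert np.allclose(once.F, twice.F, atol=1e-14)

    def test_birth_death_equilibrium_moments(self, cfg):
        # constant production / linear degradation with alpha/lambda = 6
        rs = birth_death_system(6.0, 1.0, 60)
        st = equilibrate(rs, cfg)
        mean, sd = distribution_moments(marginalise(st))
        assert mean == pytest.approx(6.0, abs=0.05)
        assert sd == pytest.approx(2.4, abs=0.05)


class TestStationaryOracle:
    def test_truncated_poisson_closed_form(self):
        rs = birth_death_system(6.0, 1.0, 40)
        pi = stationary_distribution(rs)
        ref = stats.poisson.pmf(np.arange(41), 6.0)
        ref /= ref.sum()
        assert np.allclose(pi, ref, atol=1e-12)

    def test_zero_production_is_point_mass_at_zero(self):
        rs = pwl_system(10, [0, 0, 0], [1, 2, 3])
        pi = stationary_distribution(rs)
        assert pi[0] == pytest.approx(1.0)

    def test_matches_long_run_integration(self, small_system, cfg):
        pi = stationary_distribution(small_system)
        st = equilibrate(small_system, cfg, tol=1e-12)
        assert np.abs(marginalise(st) - pi).sum() < 1e-6

    def test_growth_rejected(self):
        rs = pwl_system(10, [4, 4, 4], [1, 2, 3], g_y=0.2)
        with pytest.raises(Exception):
            stationary_distribution(rs)


class TestPartition:
    def test_modes_conserve_molecules_in_expectation(self):
        for mode in ("binomial", "halving"):
            B = partition_matrix(12, mode)
            m = np.arange(13)
            assert np.allclose(B.sum(axis=0), 1.0)
            assert np.allclose(2.0 * (np.arange(13) @ B), m)

    def test_halving_vs_binomial_equilibrium_means_close(self):
        # the partition model barely affects population-level equilibria
        rs_y = dict(p_y=[6, 6, 6], d_y=[2, 3, 5], g_y=0.2)
        means = {}
        for mode in ("binomial", "halving"):
            cfg = CellCycleConfig(partition_mode=mode, dt=1 / 30)
            rs = pwl_system(20, **rs_y)
            st = equilibrate(rs, cfg, tol=1e-12, max_hours=60.0)
            means[mode] = distribution_moments(marginalise(st))[0]
        rel = abs(means["halving"] - means["binomial"]) / means["binomial"]
        assert rel < 0.02


class TestMarginalise:
    def test_conservation(self, rng):
        F = rng.uniform(size=(11, 5))
        state = PopulationState(F)
        assert marginalise(state).sum() == pytest.approx(F.sum())

    def test_single_phase_profile(self):
        F = np.zeros((11, 5))
        F[:, 2] = np.arange(11)
        assert np.array_equal(marginalise(PopulationState(F)), np.arange(11))


class TestSummarise:
    def test_identical_rates_give_zero_drift_full_correlation(self, cfg):
        rs = matched_rates(10)
        state = initial_state(10, cfg.k, histogram=np.ones(11))
        s = summarise(state, rs)
        assert s.Abar == pytest.approx(0.0, abs=1e-12)
        assert s.corr_w == pytest.approx(1.0)

    def test_constant_rates_have_zero_slopes(self, cfg):
        # population held where both curves are flat (clear of the
        # D(0) = 0 anchor ramp even after dilution correction)
        rs = pwl_system(10, [4, 4, 4], [2, 2, 2])
        hist = np.zeros(11)
        hist[6:] = 1.0
        state = initial_state(10, cfg.k, histogram=hist)
        s = summarise(state, rs)
        assert s.dPbar == pytest.approx(0.0, abs=1e-12)
        assert s.dDbar == pytest.approx(0.0, abs=1e-12)

    def test_molecule_balance_dT_dt_equals_M_Abar(self, cfg):
        # finite-difference check of the total-molecule balance at zero
        # growth; N large enough that the reflecting-boundary mass (the
        # only deviation from the exact balance) is negligible
        rs = pwl_system(20, [4, 5, 2], [1, 3, 6])
        state = equilibrate(rs, cfg, max_hours=2.0, tol=0)
        s = summarise(state, rs)
        nxt = step(state, rs, cfg)
        n = np.arange(21)
        dT_dt = (n @ marginalise(nxt) - s.T) / cfg.dt
        assert dT_dt == pytest.approx(s.M * s.Abar, abs=1e-6)

    def test_empty_population_rejected(self, small_system):
        with pytest.raises(Exception):
            PopulationState(np.zeros((11, 5)))


class TestFPDecomposition:
    def _state(self, N, p=None):
        F = np.zeros((N + 1, 1))
        F[:, 0] = np.ones(N + 1) if p is None else p
        return PopulationState(F)

    def test_deterministic_term_vanishes_when_P_equals_D(self):
        rs = matched_rates(10)
        fp = fp_decompose(self._state(10), rs)
        interior = np.isfinite(fp.deterministic)
        assert np.allclose(fp.deterministic[interior], 0.0)
        assert fp.abs_A_mean == 0.0

    def test_regulated_noise_vanishes_for_constant_B(self):
        rs = pwl_system(10, [4, 4, 4], [2, 2, 2])
        p = np.zeros(11)
        p[4:] = 1.0  # mass clear of the anchor ramp, where B is constant
        fp = fp_decompose(self._state(10, p), rs)
        assert np.allclose(fp.regulated_noise[4:-2], 0.0)
        assert fp.abs_DB_mean == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_B_constant_density(self):
        # B(x) = x^2, p const: d/dx(B' p) - B''/2 p = 2p - p = p
        N = 12
        quad = SimpleNamespace(N=N,
                               P=lambda x: 0.5 * np.asarray(x, float) ** 2,
                               D=lambda x: 0.5 * np.asarray(x, float) ** 2)
        fp = fp_decompose(self._state(N), quad)
        p = 1.0 / (N + 1)
        inner = fp.regulated_noise[2:-2]  # double stencil needs 2 cells
        assert np.allclose(inner, p, atol=1e-12)

    def test_too_small_grid_rejected(self):
        rs = pwl_system(2, [1, 1, 1], [1, 1, 1], x_points=[0.5, 1, 1.5])
        with pytest.raises(Exception):
            fp_decompose(self._state(2), rs)


class TestClassifyDynamics:
    def test_equal_rates_are_noise_driven(self):
        rs = matched_rates(10)
        F = np.ones((11, 1))
        fp = fp_decompose(PopulationState(F), rs)
        assert classify_dynamics(fp, rs) == "noise_driven"

    def test_distinct_constants_are_deterministic_dominated(self):
        rs = pwl_system(10, [6, 6, 6], [2, 2, 2])
        F = np.zeros((11, 1))
        F[4:, 0] = 1.0  # constant-rate region, B flat: no regulated noise
        fp = fp_decompose(PopulationState(F), rs)
        assert classify_dynamics(fp, rs) == "deterministic_dominated"

    def test_matched_slopes_are_noise_regulation_dominated(self):
        # V-shaped rates with a tiny constant offset: A is small but B
        # varies strongly, so the regulated-noise average dominates
        rs_p = SetPointCurve("production", [2, 5, 8], [6, 1, 6])
        rs_d = SetPointCurve("degradation", [2, 5, 8], [6.01, 1.01, 6.01])
        from pwlid.rates import RateSystem

        rs = RateSystem(rs_p, rs_d, 0.0, 10)
        pi = stationary_distribution(rs)
        F = pi[:, None]
        fp = fp_decompose(PopulationState(F), rs)
        assert fp.abs_DB_mean > fp.abs_A_mean
        assert classify_dynamics(fp, rs) == "noise_regulation_dominated"
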