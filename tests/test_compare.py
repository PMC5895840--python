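"""Six identification error functionals and the comparison protocol."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from pwlid.compare import (METHODS, distance_profile, error_freq2d, error_rates,
                           estimate_rates_pav, evaluate_methods, make_reference,
                           method_error, parameter_distance, parameter_spread,
                           reconstruct_rates_sct, scale_to_reference,
                           sct_neg_loglik)
from pwlid.population import CellCycleConfig
from pwlid.rates import (ParameterVector, ValidationError, birth_death_system,
                         pwl_system, scale_parameters, unscale_parameters)
from pwlid.synth import (Event, LabellingDesign, SCTTrajectory,
                         equilibrium_histogram, random_rate_system,
                         simulate_labelling)


class TestErrorFreq2D:
    def test_identical_tables_score_zero(self):
        t = np.array([[1.0, 0], [2.0, 3.0]])
        assert error_freq2d([t], [t]) == 0.0

    def test_disjoint_mass_scores_one(self):
        a = np.array([[5.0, 0], [0, 0]])
        b = np.array([[0.0, 0], [0, 5.0]])
        assert error_freq2d([a], [b]) == pytest.approx(1.0)

    def test_single_cell_difference(self):
        ref = np.array([[4.0, 0], [2.0, 4.0]])
        sim = ref.copy()
        sim[0, 0] += 1.0
        # sim is rescaled to the reference total first
        scaled = sim * ref.sum() / sim.sum()
        expected = np.abs(scaled - ref).sum() / (2 * ref.sum())
        assert error_freq2d([sim], [ref]) == pytest.approx(expected)


class TestPAVEstimators:
    def test_half_life_closed_form(self):
        # U(1 h) / T0 = 0.5 -> decay constant ln 2
        P_hat, D_hat = estimate_rates_pav(L=1.0, U=0.5, T0=1.0, delta=1.0)
        assert D_hat == pytest.approx(np.log(2.0))

    def test_zero_degradation_limit(self):
        P_hat, D_hat = estimate_rates_pav(L=0.4, U=1.0, T0=1.0, delta=0.1)
        assert D_hat == 0.0
        assert P_hat == pytest.approx(4.0)

    def test_recovers_birth_death_rates(self, cfg):
        # constant-P / linear-D reference simulated with the extended
        # labelling equation: estimators recover the population-averaged
        # rates within 5% at a 6-minute pulse
        rs = birth_death_system(4.0, 0.8, 30)
        pi = equilibrium_histogram(rs)
        design = LabellingDesign(interval=0.1, times=(0.1,))
        dist = simulate_labelling(rs, design, cfg, init=pi)[-1]
        L, U, M = dist.totals()
        T0 = float(pi @ np.arange(31))
        P_hat, D_hat = estimate_rates_pav(L, U, T0, 0.1, M)
        n = np.arange(31)
        P_true = float(pi @ rs.P(n))
        D_true = float(pi @ rs.D(n))
        assert abs(P_hat - P_true) / P_true < 0.05
        assert abs(D_hat - D_true) / D_true < 0.05

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValidationError):
            estimate_rates_pav(1.0, 0.0, 1.0, 0.1)


class TestRatesSCTReconstruction:
    def test_event_rate_split_arithmetic(self):
        # 10 production + 5 degradation events during ~3 h occupancy at
        # n = 5: total rate 5/h split 2:1
        events = []
        t = 0.0
        for _ in range(5):
            events.append(Event(t + 0.1, "production", 5, 6, 1))
            events.append(Event(t + 0.2, "degradation", 6, 5, 1))
            events.append(Event(t + 0.3, "production", 5, 6, 1))
            events.append(Event(t + 0.4, "degradation", 6, 5, 1))
            t += 0.6
        tr = SCTTrajectory(0, 5, 3.0, events)
        P_hat, D_hat, _, occ = reconstruct_rates_sct([tr], 10)
        occ5 = occ[5]
        assert P_hat[5] == pytest.approx(10 / occ5)
        assert D_hat[6] == pytest.approx(10 / occ[6])

    def test_no_events_positive_occupancy_gives_zero(self):
        tr = SCTTrajectory(0, 4, 5.0, [])
        P_hat, D_hat, _, occ = reconstruct_rates_sct([tr], 10)
        assert P_hat[4] == 0.0 and D_hat[4] == 0.0
        assert np.isnan(P_hat[3])

    def test_frame_mode_pseudo_events(self):
        frames = [np.array([3, 4, 4, 3, 5])]
        P_hat, D_hat, _, occ = reconstruct_rates_sct(None, 10, frames=frames,
                                                     delta=0.5)
        # +1 at frame 0 (n=3), -1 at frame 2 (n=4), +2 at frame 3 (n=3)
        assert occ[3] == pytest.approx(1.0)
        assert P_hat[3] == pytest.approx(3 / 1.0)
        assert D_hat[4] == pytest.approx(1 / 1.0)

    def test_zero_observation_time_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct_rates_sct(None, 5, frames=[np.array([1])], delta=0.5)


class TestSCTNegLogLik:
    def test_single_event_closed_form(self, cfg):
        # one production at unit rate observed after exactly 1 h:
        # NLL = -log(1) + 1 * 1 = 1
        rs = pwl_system(10, [1, 1, 1], [0, 0, 0])
        tr = SCTTrajectory(0, 0, 1.0, [Event(1.0, "production", 0, 1, 1)])
        assert sct_neg_loglik(rs, [tr], cfg) == pytest.approx(1.0)

    def test_eventless_observation_adds_survival_term(self, cfg):
        rs = pwl_system(10, [2, 2, 2], [0, 0, 0])
        one = sct_neg_loglik(rs, [SCTTrajectory(0, 0, 1.0, [])], cfg)
        two = sct_neg_loglik(rs, [SCTTrajectory(0, 0, 2.0, [])], cfg)
        assert two - one == pytest.approx(2.0)  # rate 2/h for one extra hour

    def test_zero_rate_at_event_is_infinite(self, cfg):
        rs = pwl_system(10, [0, 0, 0], [0, 0, 0])
        tr = SCTTrajectory(0, 0, 1.0, [Event(0.5, "production", 0, 1, 1)])
        assert sct_neg_loglik(rs, [tr], cfg) == np.inf

    def test_constant_rate_mle_is_event_frequency(self, cfg):
        # analytic MLE for a constant production rate: events / time
        events = [Event(t, "production", i, i + 1, 1)
                  for i, t in enumerate(np.linspace(0.2, 7.8, 9))]
        tr = SCTTrajectory(0, 0, 10.0, events)

        def nll(alpha):
            rs = pwl_system(50, [alpha] * 3, [0, 0, 0])
            return sct_neg_loglik(rs, [tr], cfg)

        res = minimize_scalar(nll, bounds=(0.05, 5.0), method="bounded")
        assert res.x == pytest.approx(9 / 10.0, rel=1e-3)


class TestErrorRates:
    def test_exact_match_scores_zero(self, small_system):
        n = np.arange(11, dtype=float)
        est = (small_system.P(n), small_system.D(n))
        assert error_rates(est, small_system, np.ones(11)) == 0.0

    def test_constant_offset_uniform_weights(self, small_system):
        n = np.arange(11, dtype=float)
        est = (small_system.P(n) + 0.5, small_system.D(n) + 0.5)
        assert error_rates(est, small_system, np.ones(11)) == pytest.approx(0.5)

    def test_undefined_states_excluded(self, small_system):
        n = np.arange(11, dtype=float)
        P = small_system.P(n) + 1.0
        P[7:] = np.nan
        est = (P, small_system.D(n) + 1.0)
        w = np.ones(11)
        assert error_rates(est, small_system, w) == pytest.approx(1.0)


class TestScaling:
    def test_reference_method_is_identity(self):
        errors = {"Freq2D": np.array([0.1, 0.3, 0.2]),
                  "RatesPAV": np.array([1.0, 5.0, 3.0])}
        scaled = scale_to_reference(errors)
        assert np.allclose(scaled["Freq2D"], errors["Freq2D"])
        assert scaled["RatesPAV"].min() == pytest.approx(0.1)
        assert scaled["RatesPAV"].max() == pytest.approx(0.3)

    def test_ordering_preserved(self, rng):
        errors = {"Freq2D": rng.uniform(0, 1, 20),
                  "LogLikeSCT": rng.uniform(10, 500, 20)}
        scaled = scale_to_reference(errors)
        assert np.array_equal(np.argsort(scaled["LogLikeSCT"]),
                              np.argsort(errors["LogLikeSCT"]))

    def test_constant_errors_rejected(self):
        with pytest.raises(ValidationError):
            scale_to_reference({"Freq2D": np.array([1.0, 2.0]),
                                "RatesPAV": np.array([3.0, 3.0])})


NAMES = ("PY1", "PY2", "PY3", "DY1", "DY2", "DY3")


class TestProfilesAndSpread:
    def test_distance_zero_for_generating_parameters(self):
        pv = ParameterVector(NAMES, np.full(6, 0.4))
        assert parameter_distance(pv, pv) == 0.0

    def test_third_set_points_excluded_by_default(self):
        a = ParameterVector(NAMES, np.array([0.4, 0.4, 0.0, 0.4, 0.4, 0.0]))
        b = ParameterVector(NAMES, np.array([0.4, 0.4, 1.0, 0.4, 0.4, 1.0]))
        assert parameter_distance(a, b) == 0.0
        assert parameter_distance(a, b, exclude=None) == pytest.approx(np.sqrt(2))

    def test_single_candidate_profile(self):
        truth = ParameterVector(NAMES, np.full(6, 0.5))
        cand = ParameterVector(NAMES, np.full(6, 0.52))
        prof = distance_profile([cand], [0.07], truth)
        d = parameter_distance(cand, truth)
        j = np.nanargmin(np.abs(prof.centers - d))
        assert prof.values[j] == pytest.approx(0.07)

    def test_spread_zero_when_all_candidates_equal_truth(self):
        truth = ParameterVector(NAMES, np.full(6, 0.5))
        spread = parameter_spread([truth, truth, truth], [0.0, 0.0, 0.0], truth)
        assert np.allclose(spread["iqr"], 0.0)
        assert np.allclose(spread["bias"], 0.0)

    def test_spread_requires_sub_threshold_candidates(self):
        truth = ParameterVector(NAMES, np.full(6, 0.5))
        with pytest.raises(ValidationError):
            parameter_spread([truth], [0.5], truth, threshold=0.02)


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(21)
    rates = random_rate_system(15, rng)
    pv = scale_parameters(rates)
    return make_reference(rates, pv, seed=21, n_cells=40, duration=25.0)


class TestMethodBattery:

    def test_deterministic_methods_score_zero_at_truth(self, reference):
        truth = unscale_parameters(reference.true_params, reference.rates)
        for m in ("Freq1D", "Freq2D"):
            assert method_error(m, truth, reference) == pytest.approx(0.0, abs=1e-12)

    def test_all_methods_finite_for_perturbed_candidates(self, reference):
        rng = np.random.default_rng(3)
        pv = reference.true_params
        cand = ParameterVector(pv.names, np.clip(pv.values + 0.1, 0, 1))
        rs = unscale_parameters(cand, reference.rates)
        for m in METHODS:
            assert np.isfinite(method_error(m, rs, reference))

    def test_evaluate_methods_long_format(self, reference):
        pv = reference.true_params
        df = evaluate_methods([pv], reference, methods=("Freq1D", "RatesPAV"))
        assert set(df["method"]) == {"Freq1D", "RatesPAV"}
        assert len(df) == 2
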