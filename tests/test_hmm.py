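"""Unit and property tests for the covariate 2-state activity HMM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seascapes import hmm
from seascapes.synthetic import simulate_odba_hmm

from conftest import enumerate_loglik, enumerate_viterbi, random_inputs, random_spec


class TestTransitionMatrix:
    def test_zero_coefficients_give_half_half(self):
        tm = hmm.TransitionModel(np.zeros(3), np.zeros(3))
        mat = hmm.transition_matrix(tm, np.array([1.0, 0.3, -0.7]))
        assert np.allclose(mat, 0.5)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            tm = hmm.TransitionModel(rng.normal(size=4), rng.normal(size=4))
            mat = hmm.transition_matrix(tm, rng.normal(size=4))
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((mat > 0) & (mat < 1))

    def test_intercept_minus_two_evaluates_logistic(self):
        tm = hmm.TransitionModel(np.array([-2.0]), np.array([-2.0]))
        mat = hmm.transition_matrix(tm, np.array([1.0]))
        expected = 1.0 / (1.0 + np.exp(2.0))
        assert mat[0, 1] == pytest.approx(expected, rel=1e-12)
        assert mat[1, 0] == pytest.approx(expected, rel=1e-12)

    def test_mismatched_covariate_length_rejected(self):
        tm = hmm.TransitionModel(np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            hmm.transition_matrix(tm, np.zeros(2))


class TestLogLikelihood:
    def test_single_observation_is_mixture_density(self, homogeneous_spec):
        x = np.array([0.07])
        ll = hmm.log_likelihood(homogeneous_spec, x, np.array([3.0]))
        d = homogeneous_spec.densities
        mix = homogeneous_spec.delta @ np.exp(d.logpdf(x))[0]
        assert ll == pytest.approx(np.log(mix), rel=1e-12)

    def test_matches_enumeration_oracle_random_specs(self, rng):
        for _ in range(25):
            spec = random_spec(rng)
            T = int(rng.integers(2, 13))
            odba, hours, tide = random_inputs(rng, spec, T)
            fast = hmm.log_likelihood(spec, odba, hours, tide)
            slow = enumerate_loglik(spec, odba, hours, tide)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_invariant_under_state_relabelling(self, rng):
        spec = random_spec(rng, harmonic_order=1, with_tide=False)
        odba, hours, tide = random_inputs(rng, spec, 200)
        swapped = hmm.HMMSpec(
            densities=hmm.StateDensities(spec.densities.shape[::-1], spec.densities.rate[::-1]),
            transitions=hmm.TransitionModel(spec.transitions.beta21, spec.transitions.beta12),
            design=spec.design,
            delta=spec.delta[::-1],
        )
        assert hmm.log_likelihood(spec, odba, hours) == pytest.approx(
            hmm.log_likelihood(swapped, odba, hours), rel=1e-12
        )

    def test_nonfinite_observation_rejected_with_index(self, homogeneous_spec):
        odba = np.array([0.1, np.nan, 0.2])
        with pytest.raises(ValueError, match="index 1"):
            hmm.log_likelihood(homogeneous_spec, odba, np.zeros(3))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), T=st.integers(2, 12))
    def test_forward_equals_enumeration_property(self, seed, T):
        rng = np.random.default_rng(seed)
        spec = random_spec(rng)
        odba, hours, tide = random_inputs(rng, spec, T)
        fast = hmm.log_likelihood(spec, odba, hours, tide)
        slow = enumerate_loglik(spec, odba, hours, tide)
        assert fast == pytest.approx(slow, rel=1e-10)


class TestDecoding:
    def test_viterbi_matches_enumeration(self, rng):
        for _ in range(20):
            spec = random_spec(rng)
            T = int(rng.integers(2, 11))
            odba, hours, tide = random_inputs(rng, spec, T)
            path, _ = hmm.decode_states(spec, odba, hours, tide)
            oracle = enumerate_viterbi(spec, odba, hours, tide)
            assert np.array_equal(path - 1, oracle)

    def test_posteriors_sum_to_one(self, diel_spec, rng):
        series, _ = simulate_odba_hmm(diel_spec, rng.uniform(0, 24, 500), seed=5)
        _, p2 = hmm.decode_states(diel_spec, series.odba, (series.timestamps / 3600) % 24)
        assert np.all((p2 >= 0) & (p2 <= 1))

    def test_high_snr_recovers_true_path(self):
        # widely separated states: decoding must reproduce the simulation
        design = hmm.CovariateDesign(harmonic_order=0, tidal_levels=())
        spec = hmm.HMMSpec(
            densities=hmm.StateDensities(np.array([50.0, 50.0]), np.array([5000.0, 50.0])),
            transitions=hmm.TransitionModel(np.array([-2.0]), np.array([-2.0])),
            design=design,
        )
        series, states = simulate_odba_hmm(spec, np.zeros(2000), seed=11)
        path, _ = hmm.decode_states(spec, series.odba, np.zeros(2000))
        assert np.array_equal(path, states)


@pytest.fixture(scope="module")
def recovery_fit():
    design = hmm.CovariateDesign(harmonic_order=0, tidal_levels=())
    true = hmm.HMMSpec(
        densities=hmm.StateDensities(np.array([2.0, 3.0]), np.array([40.0, 15.0])),
        transitions=hmm.TransitionModel(np.array([-2.0]), np.array([-1.0])),
        design=design,
    )
    series, _ = simulate_odba_hmm(true, np.zeros(8000), seed=7)
    fit = hmm.fit_hmm(series.odba, np.zeros(8000), design=design, n_restarts=3, seed=1)
    return true, series, fit


class TestFit:
    def test_parameters_recovered(self, recovery_fit):
        true, _, fit = recovery_fit
        d = fit.spec.densities
        assert np.allclose(d.shape, true.densities.shape, rtol=0.15)
        assert np.allclose(d.rate, true.densities.rate, rtol=0.15)
        assert abs(fit.spec.transitions.beta12[0] - (-2.0)) < 0.3
        assert abs(fit.spec.transitions.beta21[0] - (-1.0)) < 0.3

    def test_ml_dominates_generating_parameters(self, recovery_fit):
        true, series, fit = recovery_fit
        at_truth = hmm.log_likelihood(
            hmm.HMMSpec(true.densities, true.transitions, true.design, fit.spec.delta),
            series.odba,
            np.zeros(len(series)),
        )
        assert fit.loglik >= at_truth

    def test_state_one_has_lower_mean(self, recovery_fit):
        _, _, fit = recovery_fit
        means = fit.spec.densities.means
        assert means[0] < means[1]

    def test_same_seed_bit_identical(self):
        design = hmm.CovariateDesign(harmonic_order=0, tidal_levels=())
        spec = hmm.HMMSpec(
            densities=hmm.StateDensities(np.array([2.0, 3.0]), np.array([40.0, 15.0])),
            transitions=hmm.TransitionModel(np.array([-2.0]), np.array([-1.0])),
            design=design,
        )
        series, _ = simulate_odba_hmm(spec, np.zeros(2000), seed=3)
        fits = [
            hmm.fit_hmm(series.odba, np.zeros(2000), design=design, n_restarts=2,
                        seed=9, compute_cov=False)
            for _ in range(2)
        ]
        assert fits[0].loglik == fits[1].loglik
        assert np.array_equal(fits[0].working_params, fits[1].working_params)

    def test_zeros_replaced_and_counted(self):
        design = hmm.CovariateDesign(harmonic_order=0, tidal_levels=())
        spec = hmm.HMMSpec(
            densities=hmm.StateDensities(np.array([2.0, 3.0]), np.array([40.0, 15.0])),
            transitions=hmm.TransitionModel(np.array([-2.0]), np.array([-1.0])),
            design=design,
        )
        series, _ = simulate_odba_hmm(spec, np.zeros(2000), seed=3)
        odba = series.odba.copy()
        odba[:5] = 0.0
        fit = hmm.fit_hmm(odba, np.zeros(2000), design=design, n_restarts=1,
                          seed=0, compute_cov=False)
        assert fit.n_zeros_replaced == 5


class TestActivityCurve:
    def test_homogeneous_model_gives_flat_stationary_curve(self, homogeneous_spec):
        fit = hmm.HMMFit(
            spec=homogeneous_spec, loglik=0.0, aic=0.0,
            cov=np.full((6, 6), np.nan), converged=True,
            n_restarts=1, seed=0, n_obs=1,
        )
        curve = hmm.activity_curve(fit, n_boot=0)
        g12 = 1 / (1 + np.exp(2.0))
        g21 = 1 / (1 + np.exp(1.0))
        expected = g12 / (g12 + g21)
        assert np.allclose(curve.p_state2, expected, atol=1e-12)

    def test_probabilities_complement(self, diel_spec):
        fit = hmm.HMMFit(
            spec=diel_spec, loglik=0.0, aic=0.0,
            cov=np.full((10, 10), np.nan), converged=True,
            n_restarts=1, seed=0, n_obs=1,
        )
        curve = hmm.activity_curve(fit, n_boot=0, hour_grid=np.linspace(0, 23.9, 100))
        assert np.all((curve.p_state2 >= 0) & (curve.p_state2 <= 1))

    def test_curve_matches_long_simulation(self, diel_spec):
        """Analytic periodic-stationary curve vs empirical hourly frequencies."""
        n = 200_000
        step_h = 10 / 60
        hours = (np.arange(n) * step_h) % 24.0
        series, states = simulate_odba_hmm(diel_spec, hours, seed=13)
        fit = hmm.HMMFit(
            spec=diel_spec, loglik=0.0, aic=0.0,
            cov=np.full((10, 10), np.nan), converged=True,
            n_restarts=1, seed=0, n_obs=n,
        )
        curve = hmm.activity_curve(fit, hour_grid=np.arange(24) + 0.5, n_boot=0)
        for h in range(24):
            sel = (hours >= h) & (hours < h + 1)
            emp = np.mean(states[sel] == 2)
            p = curve.p_state2[h]
            sigma = np.sqrt(p * (1 - p) / sel.sum())
            assert abs(emp - p) < 4 * sigma + 0.01


class TestSummaries:
    def test_alternating_path_unit_dwell(self):
        path = np.array([1, 2] * 50)
        out = hmm.dwell_time_summary(path)
        assert out[1]["mean_s"] == 1.0 and out[2]["mean_s"] == 1.0

    def test_single_state_run(self):
        out = hmm.dwell_time_summary(np.ones(100, dtype=int))
        assert out[1]["mean_s"] == 100.0
        assert out[2]["mean_s"] is None

    def test_hand_counted_bouts(self):
        out = hmm.dwell_time_summary(np.array([1, 1, 2, 2, 2, 1]))
        assert out[1]["mean_s"] == pytest.approx(1.5)
        assert out[2]["mean_s"] == pytest.approx(3.0)

    def test_occupancy_percentages(self):
        path = np.array([1] * 777 + [2] * 223)
        occ = hmm.state_occupancy(path)
        assert occ[1] == pytest.approx(77.7)
        assert occ[1] + occ[2] == pytest.approx(100.0)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            hmm.dwell_time_summary(np.array([]))


class TestSerialization:
    def test_round_trip(self, tmp_path, diel_spec):
        fit = hmm.HMMFit(
            spec=diel_spec, loglik=-123.4, aic=260.8,
            cov=np.eye(10), converged=True, n_restarts=5, seed=42, n_obs=1000,
        )
        path = tmp_path / "fit.json"
        hmm.save_fit(fit, path)
        back = hmm.load_fit(path)
        assert back.loglik == fit.loglik
        assert np.array_equal(back.working_params, fit.working_params)
        assert back.spec.design == fit.spec.design
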