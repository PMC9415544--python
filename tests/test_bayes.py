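"""Discrete Bayesian estimation: likelihood, posterior weights, hybrid fit."""

import math

import numpy as np
import pytest

import tobramipd.bayes as bayes
from tobramipd.bayes import (
    AssayErrorModel,
    DegenerateFitError,
    Observation,
    assay_sd,
    fit_metrics,
    hybrid_fit,
    log_likelihood,
    point_estimates,
    posterior_weights,
    preprocess_blq,
)
from tobramipd.pk import Regimen, SupportPoint, concentration_profile, individual_params
from tobramipd.priors import DiscretePrior

from conftest import two_point_prior


class TestAssayError:
    def test_linear_sd(self, err_model):
        assert assay_sd(25.0, err_model) == pytest.approx(1.1)
        assert assay_sd(0.0, err_model) == pytest.approx(0.1)

    def test_constant_sd_when_no_proportional_term(self):
        m = AssayErrorModel(c0=0.2, c1=0.0)
        assert assay_sd(0.0, m) == assay_sd(100.0, m) == pytest.approx(0.2)

    def test_rejects_degenerate_model(self):
        with pytest.raises(ValueError):
            AssayErrorModel(c0=0.0, c1=0.0)


class TestBLQ:
    def test_below_limit_substituted_at_half_lloq(self):
        out = preprocess_blq([Observation(time=24.0, concentration=0.15)])
        assert out[0].concentration == pytest.approx(0.1)
        assert out[0].blq

    def test_boundary_value_kept(self):
        out = preprocess_blq([Observation(time=24.0, concentration=0.2)])
        assert out[0].concentration == pytest.approx(0.2)
        assert not out[0].blq

    def test_quantifiable_unchanged(self):
        out = preprocess_blq([Observation(time=1.0, concentration=27.8)])
        assert out[0].concentration == pytest.approx(27.8)
        assert not out[0].blq


class TestLogLikelihood:
    point = SupportPoint(vs=0.25, ki=0.01, ks=0.003, k12=0.6, k21=0.9)

    def test_hand_computed_normal_density(self, adult, err_model):
        reg = Regimen.once_daily(500.0)
        mp = individual_params(self.point, adult)
        pred = concentration_profile(mp, reg, [1.0])[0]
        obs = [Observation(time=1.0, concentration=pred + 2.0)]
        sd = 0.1 + 0.04 * pred
        expected = -0.5 * (2.0 / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))
        got = log_likelihood(self.point, adult, reg, obs, err_model)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_hand_value_sd_09(self):
        # prediction 20, observed 22, SD = 0.1 + 0.04*20 = 0.9
        expected = -0.5 * (2 / 0.9) ** 2 - math.log(0.9 * math.sqrt(2 * math.pi))
        assert expected == pytest.approx(-3.283, abs=5e-4)

    def test_zero_residual(self, adult, err_model):
        reg = Regimen.once_daily(500.0)
        mp = individual_params(self.point, adult)
        pred = concentration_profile(mp, reg, [1.0])[0]
        obs = [Observation(time=1.0, concentration=pred)]
        sd = 0.1 + 0.04 * pred
        got = log_likelihood(self.point, adult, reg, obs, err_model)
        assert got == pytest.approx(-math.log(sd * math.sqrt(2 * math.pi)), rel=1e-12)

    def test_additivity_over_observations(self, adult, err_model):
        reg = Regimen.once_daily(500.0)
        o1 = Observation(time=1.0, concentration=20.0)
        o2 = Observation(time=24.0, concentration=0.4)
        joint = log_likelihood(self.point, adult, reg, [o1, o2], err_model)
        separate = log_likelihood(self.point, adult, reg, [o1], err_model) + \
            log_likelihood(self.point, adult, reg, [o2], err_model)
        assert joint == pytest.approx(separate, rel=1e-12)


class TestPosterior:
    def test_no_observations_returns_prior(self, small_prior, adult, err_model):
        post = posterior_weights(small_prior, adult, Regimen.once_daily(500.0), [], err_model)
        np.testing.assert_allclose(post.weights, small_prior.weights, atol=1e-15)
        assert post.log_evidence == 0.0

    def test_single_point_always_weight_one(self, adult, err_model):
        theta = np.array([[0.25, 0.01, 0.003, 0.6, 0.9]])
        prior = DiscretePrior(theta, np.array([1.0]),
                              np.column_stack([theta[0] * 0.5, theta[0] * 2]))
        obs = [Observation(time=1.0, concentration=12.0)]
        post = posterior_weights(prior, adult, Regimen.once_daily(500.0), obs, err_model)
        assert post.weights[0] == pytest.approx(1.0)

    def test_two_point_bayes_ratio(self, adult, err_model, monkeypatch):
        # equal priors, logL gap of ln 3 -> weights (0.75, 0.25)
        prior = two_point_prior([0.25, 0.01, 0.003, 0.6, 0.9],
                                [0.35, 0.01, 0.003, 0.6, 0.9])
        monkeypatch.setattr(
            bayes, "_log_likelihoods",
            lambda *a, **k: np.array([math.log(3.0), 0.0]),
        )
        obs = [Observation(time=1.0, concentration=12.0)]
        post = posterior_weights(prior, adult, Regimen.once_daily(500.0), obs, err_model)
        np.testing.assert_allclose(post.weights, [0.75, 0.25], atol=1e-14)

    def test_logsumexp_shift_invariance(self, adult, err_model, monkeypatch):
        prior = two_point_prior([0.25, 0.01, 0.003, 0.6, 0.9],
                                [0.35, 0.01, 0.003, 0.6, 0.9], w1=0.3)
        obs = [Observation(time=1.0, concentration=12.0)]
        base = np.array([-2.0, -5.0])
        weights = []
        for shift in (0.0, 512.0, -800.0):
            monkeypatch.setattr(bayes, "_log_likelihoods", lambda *a, s=shift, **k: base + s)
            post = posterior_weights(prior, adult, Regimen.once_daily(500.0), obs, err_model)
            weights.append(post.weights.copy())
        np.testing.assert_array_equal(weights[0], weights[1])
        np.testing.assert_array_equal(weights[0], weights[2])

    def test_weights_sum_to_one(self, small_prior, adult, err_model):
        obs = [Observation(time=1.0, concentration=25.0),
               Observation(time=24.0, concentration=0.3)]
        post = posterior_weights(small_prior, adult, Regimen.once_daily(500.0), obs, err_model)
        assert abs(post.weights.sum() - 1.0) < 1e-12

    def test_permutation_equivariance(self, adult, err_model):
        rng = np.random.default_rng(0)
        theta = np.exp(rng.uniform(np.log([0.15, 0.003, 0.0015, 0.05, 0.05]),
                                   np.log([0.55, 0.03, 0.005, 4.0, 4.0]), size=(20, 5)))
        bounds = np.column_stack([theta.min(0), theta.max(0)])
        w = np.full(20, 0.05)
        prior = DiscretePrior(theta, w, bounds)
        perm = rng.permutation(20)
        prior_p = DiscretePrior(theta[perm], w, bounds)
        obs = [Observation(time=1.0, concentration=25.0)]
        reg = Regimen.once_daily(500.0)
        post = posterior_weights(prior, adult, reg, obs, err_model)
        post_p = posterior_weights(prior_p, adult, reg, obs, err_model)
        np.testing.assert_allclose(post_p.weights, post.weights[perm], rtol=1e-12)

    def test_duplicate_point_mass_splitting(self, adult, err_model):
        p1 = [0.25, 0.01, 0.003, 0.6, 0.9]
        p2 = [0.35, 0.012, 0.004, 0.5, 0.8]
        prior = two_point_prior(p1, p2, w1=0.4)
        theta3 = np.array([p1, p1, p2])
        prior3 = DiscretePrior(theta3, np.array([0.2, 0.2, 0.6]), prior.bounds)
        obs = [Observation(time=1.0, concentration=25.0),
               Observation(time=24.0, concentration=0.3)]
        reg = Regimen.once_daily(500.0)
        post = posterior_weights(prior, adult, reg, obs, err_model)
        post3 = posterior_weights(prior3, adult, reg, obs, err_model)
        mean = post.weights @ post.theta
        mean3 = post3.weights @ post3.theta
        np.testing.assert_allclose(mean3, mean, rtol=1e-12)

    def test_likelihood_dominance_noiseless_data(self, small_prior, adult, err_model):
        truth_idx = 37
        truth = SupportPoint(*small_prior.theta[truth_idx])
        mp = individual_params(truth, adult)
        reg = Regimen.once_daily(500.0, n_doses=4)
        times = [73.0, 96.0]
        conc = concentration_profile(mp, reg, times)
        obs = preprocess_blq(
            [Observation(time=t, concentration=c) for t, c in zip(times, conc)]
        )
        post = posterior_weights(small_prior, adult, reg, obs, err_model)
        assert int(np.argmax(post.weights)) == truth_idx


class TestHybridFit:
    def test_well_specified_course_never_triggers(self, prior, adult, err_model):
        truth = SupportPoint(*prior.theta[100])
        mp = individual_params(truth, adult)
        reg = Regimen.once_daily(500.0, n_doses=4)
        times = [73.0, 96.0]
        conc = concentration_profile(mp, reg, times)
        obs = preprocess_blq([Observation(time=t, concentration=c)
                              for t, c in zip(times, conc)])
        post = posterior_weights(prior, adult, reg, obs, err_model)
        assert not bayes.fit_is_inadequate(post, adult, reg, obs)
        assert not post.hybrid_used

    def test_out_of_range_truth_improves_with_hybrid(self, small_prior, adult, err_model):
        # a patient whose true volume lies far above the prior's upper bound
        truth = SupportPoint(vs=0.9, ki=0.01, ks=0.003, k12=0.6, k21=0.9)
        assert truth.vs > small_prior.bounds[0, 1]
        mp = individual_params(truth, adult)
        reg = Regimen.once_daily(500.0, n_doses=4)
        times = [73.0, 96.0]
        conc = concentration_profile(mp, reg, times)
        obs = preprocess_blq([Observation(time=t, concentration=c)
                              for t, c in zip(times, conc)])
        post_std = posterior_weights(small_prior, adult, reg, obs, err_model)
        assert bayes.fit_is_inadequate(post_std, adult, reg, obs)
        post_hyb = hybrid_fit(small_prior, adult, reg, obs, err_model, seed=0)
        assert post_hyb.hybrid_used

        def mape(post):
            est = point_estimates(post, adult, reg, obs)
            return fit_metrics([o.concentration for o in obs],
                               list(est.predictions)).median_ape

        assert mape(post_hyb) < mape(post_std)

    def test_expanded_bounds_double_both_ways(self, small_prior):
        expanded = bayes._expanded_prior(small_prior, seed=0)
        np.testing.assert_allclose(expanded.bounds[:, 0], small_prior.bounds[:, 0] / 2)
        np.testing.assert_allclose(expanded.bounds[:, 1], small_prior.bounds[:, 1] * 2)
        assert len(expanded) == len(small_prior) + bayes.HYBRID_N_AUX
        # auxiliary grid carries half the prior mass
        aux_mass = expanded.weights[len(small_prior):].sum()
        assert aux_mass == pytest.approx(0.5, abs=1e-12)


class TestPointEstimates:
    def test_single_point_posterior_reproduces_point(self, adult, err_model):
        theta = np.array([[0.25, 0.01, 0.003, 0.6, 0.9]])
        prior = DiscretePrior(theta, np.array([1.0]),
                              np.column_stack([theta[0] * 0.5, theta[0] * 2]))
        reg = Regimen.once_daily(500.0)
        obs = [Observation(time=1.0, concentration=20.0)]
        post = posterior_weights(prior, adult, reg, obs, err_model)
        est = point_estimates(post, adult, reg, obs)
        mp = individual_params(SupportPoint(*theta[0]), adult)
        assert est.micro.v1 == pytest.approx(mp.v1)
        assert est.micro.ke == pytest.approx(mp.ke)
        assert est.clearance == pytest.approx(mp.ke * mp.v1)
        np.testing.assert_allclose(
            est.predictions, concentration_profile(mp, reg, [1.0]), rtol=1e-12
        )

    def test_symmetric_two_point_posterior_is_midpoint(self, adult):
        p1 = np.array([0.2, 0.008, 0.002, 0.4, 0.8])
        p2 = np.array([0.3, 0.012, 0.004, 0.6, 1.0])
        prior = two_point_prior(p1, p2, w1=0.5)
        post = bayes.Posterior(prior, np.array([0.5, 0.5]), log_evidence=0.0)
        est = point_estimates(post, adult, Regimen.once_daily(500.0), [])
        np.testing.assert_allclose(est.theta, (p1 + p2) / 2, rtol=1e-12)


class TestFitMetrics:
    def test_perfect_fit(self):
        m = fit_metrics([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert m.median_pe == 0.0
        assert m.median_ape == 0.0
        assert m.r2 == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = fit_metrics([10.0, 20.0], [11.0, 19.0])
        np.testing.assert_allclose(sorted(m.pe), [-1.0, 1.0])
        assert m.median_pe == pytest.approx(0.0)
        assert m.median_ape == pytest.approx(7.5)

    def test_constant_prediction_r2_zero(self):
        m = fit_metrics([10.0, 20.0, 30.0], [15.0, 15.0, 15.0])
        assert m.r2 == 0.0

    def test_zero_observation_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            m = fit_metrics([0.0, 20.0], [1.0, 22.0])
        assert m.n_excluded_zero == 0 or m.ape.size == 1  # one APE retained
        assert m.ape[0] == pytest.approx(10.0)

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            fit_metrics([1.0], [1.0, 2.0])


def test_degenerate_fit_raises(adult):
    # pure proportional error with a zero prediction (pre-dose sample) gives
    # SD = 0 and -inf log-likelihood for every support point
    theta = np.array([[0.2, 0.01, 0.003, 0.6, 0.9]])
    prior = DiscretePrior(theta, np.array([1.0]),
                          np.column_stack([theta[0] * 0.5, theta[0] * 2]))
    err = AssayErrorModel(c0=0.0, c1=0.04)
    obs = [Observation(time=0.0, concentration=5.0)]
    with pytest.raises(DegenerateFitError):
        posterior_weights(prior, adult, Regimen.once_daily(500.0), obs, err)
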