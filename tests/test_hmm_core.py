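"""Likelihood, fitting and decoding of the gamma-emission speed models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from shoalhmm import (
    GammaSpec,
    HMMSpec,
    NumericalDegeneracyError,
    SocialEmissionSpec,
    aic,
    fit_model,
    forward_loglik,
    gamma_logpdf,
    stationary_distribution,
    viterbi_decode,
)
from shoalhmm.hmm_core import N_PARAMS

from conftest import brute_force_loglik, brute_force_viterbi, make_series


def two_state_spec(means=(3.0, 0.3), sds=(1.0, 0.2), p=0.9):
    return HMMSpec("model2", [GammaSpec(*z) for z in zip(means, sds)],
                   transition=np.array([[p, 1 - p], [1 - p, p]]))


def three_state_spec(means=(3.0, 0.3), sds=(1.0, 0.2), sd3=0.5,
                     trans=None):
    if trans is None:
        trans = [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.3, 0.1, 0.6]]
    return HMMSpec("model3",
                   [GammaSpec(*z) for z in zip(means, sds)] + [SocialEmissionSpec(sd3)],
                   transition=np.array(trans))


def simulate_two_state(rng, n, means, sds, p=0.95):
    """Plain 2-state gamma HMM draws with ground-truth states (0-based)."""
    t = np.array([[p, 1 - p], [1 - p, p]])
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(2)
    u = rng.random(n)
    for i in range(1, n):
        states[i] = states[i - 1] if u[i] < p else 1 - states[i - 1]
    speeds = np.empty(n)
    for s in (0, 1):
        mask = states == s
        shape = means[s] ** 2 / sds[s] ** 2
        speeds[mask] = rng.gamma(shape, sds[s] ** 2 / means[s], size=mask.sum())
    return speeds, states


class TestGammaLogpdf:
    def test_exponential_special_case(self):
        # mean = sd = 1 is the unit-rate exponential: logpdf(1) = -1
        assert gamma_logpdf(1.0, GammaSpec(1.0, 1.0)) == pytest.approx(-1.0)

    def test_mean_sd_to_shape_scale(self):
        spec = GammaSpec(2.0, 1.0)
        assert spec.shape == pytest.approx(4.0)
        assert spec.scale == pytest.approx(0.5)

    def test_density_integrates_to_one(self):
        spec = GammaSpec(3.0, 2.0)
        val, _ = integrate.quad(lambda v: np.exp(gamma_logpdf(v, spec)), 1e-3, 200,
                                limit=200)
        # plus the censored mass below the resolution threshold
        val += np.exp(gamma_logpdf(0.0, spec)) * 1  # mass, not density
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_non_finite_speed_rejected(self):
        with pytest.raises(Exception):
            gamma_logpdf(np.nan, GammaSpec(1.0, 1.0))


class TestStationaryDistribution:
    def test_symmetric_two_state(self):
        pi = stationary_distribution([[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(pi, [0.5, 0.5])

    def test_detailed_balance_two_state(self):
        pi = stationary_distribution([[0.9, 0.1], [0.2, 0.8]])
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3])

    def test_reducible_chain_rejected(self):
        with pytest.raises(NumericalDegeneracyError):
            stationary_distribution(np.eye(3))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_random_chain_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.dirichlet(np.ones(3) * 2, size=3)
        pi = stationary_distribution(t)
        np.testing.assert_allclose(pi @ t, pi, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)
        # eigen-decomposition oracle
        vals, vecs = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(vals - 1)))
        oracle = np.real(vecs[:, i])
        oracle /= oracle.sum()
        np.testing.assert_allclose(pi, oracle, atol=1e-10)


class TestForwardLoglik:
    def test_model1_is_sum_of_logpdfs(self, rng):
        speeds = rng.gamma(2.0, 1.5, size=50)
        s = make_series(speeds, segments=[(0, 30), (30, 50)])
        spec = HMMSpec("model1", [GammaSpec(2.5, 1.2)])
        expect = gamma_logpdf(speeds, GammaSpec(2.5, 1.2)).sum()
        assert forward_loglik(s, spec) == pytest.approx(expect, abs=1e-9)

    def test_matches_exhaustive_enumeration_two_state(self, rng):
        speeds = rng.gamma(2.0, 1.5, size=3)
        s = make_series(speeds)
        spec = two_state_spec()
        assert forward_loglik(s, spec) == pytest.approx(
            brute_force_loglik(s, spec), abs=1e-10)

    def test_matches_exhaustive_enumeration_three_state_with_gaps(self, rng):
        speeds = rng.gamma(2.0, 1.5, size=5)
        speeds[2] = 0.0  # exercise the censored branch
        nn = rng.gamma(2.0, 1.5, size=5)
        s = make_series(speeds, nn_speeds=nn, segments=[(0, 3), (3, 5)])
        spec = three_state_spec()
        assert forward_loglik(s, spec) == pytest.approx(
            brute_force_loglik(s, spec), abs=1e-10)

    def test_segment_additivity(self, rng):
        speeds = rng.gamma(2.0, 1.5, size=8)
        nn = rng.gamma(2.0, 1.5, size=8)
        spec = three_state_spec()
        joint = make_series(speeds, nn_speeds=nn, segments=[(0, 5), (5, 8)])
        a = make_series(speeds[:5], nn_speeds=nn[:5])
        b = make_series(speeds[5:], nn_speeds=nn[5:])
        assert forward_loglik(joint, spec) == pytest.approx(
            forward_loglik(a, spec) + forward_loglik(b, spec), abs=1e-9)

    def test_no_underflow_on_long_series(self, rng):
        speeds = rng.gamma(2.0, 1.5, size=100_000)
        s = make_series(speeds)
        ll = forward_loglik(s, two_state_spec())
        assert np.isfinite(ll)

    def test_model3_nests_model2(self, rng):
        """Zero entry probability into the social state reproduces model 2."""
        speeds = rng.gamma(2.0, 1.5, size=200)
        nn = rng.gamma(2.0, 1.5, size=200)
        s = make_series(speeds, nn_speeds=nn, segments=[(0, 120), (120, 200)])
        p = 0.9
        m2 = two_state_spec(p=p)
        m3 = three_state_spec(
            trans=[[p, 1 - p, 0.0], [1 - p, p, 0.0], [0.45, 0.45, 0.1]])
        assert forward_loglik(s, m3) == pytest.approx(
            forward_loglik(s, m2), abs=1e-8)


class TestAIC:
    def test_arithmetic(self):
        assert aic(-100.0, 6) == pytest.approx(212.0)

    def test_parameter_counts(self):
        assert N_PARAMS == {"model1": 2, "model2": 6, "model3": 11}

    def test_penalty_bound_for_nested_models(self):
        # equal likelihoods: the larger model is worse by exactly 2*dk
        assert aic(-50.0, 11) - aic(-50.0, 6) == pytest.approx(10.0)


class TestViterbi:
    def test_one_state_model_trivial_path(self, rng):
        s = make_series(rng.gamma(2.0, 1.0, 10))
        d = viterbi_decode(s, HMMSpec("model1", [GammaSpec(2.0, 1.0)]))
        assert (d.states == 1).all()

    def test_matches_exhaustive_argmax(self, rng):
        for trial in range(5):
            speeds = rng.gamma(2.0, 1.5, size=4)
            s = make_series(speeds)
            spec = two_state_spec()
            np.testing.assert_array_equal(
                viterbi_decode(s, spec).states, brute_force_viterbi(s, spec))

    def test_matches_exhaustive_argmax_three_state(self, rng):
        speeds = rng.gamma(2.0, 1.5, size=5)
        nn = rng.gamma(2.0, 1.5, size=5)
        s = make_series(speeds, nn_speeds=nn, segments=[(0, 2), (2, 5)])
        spec = three_state_spec()
        np.testing.assert_array_equal(
            viterbi_decode(s, spec).states, brute_force_viterbi(s, spec))

    def test_recovers_well_separated_states(self, rng):
        speeds, states = simulate_two_state(
            rng, 5000, means=(10.0, 0.1), sds=(0.5, 0.5), p=0.95)
        s = make_series(speeds)
        spec = two_state_spec(means=(10.0, 0.1), sds=(0.5, 0.5), p=0.95)
        decoded = viterbi_decode(s, spec).states
        agreement = np.mean(decoded - 1 == states)
        assert agreement >= 0.99

    def test_beats_random_paths(self, rng):
        speeds = rng.gamma(2.0, 1.5, size=12)
        s = make_series(speeds)
        spec = two_state_spec()
        t = spec.transition
        pi = stationary_distribution(t)

        def path_logprob(path):
            lp = np.log(pi[path[0]]) + gamma_logpdf(speeds[0], spec.emissions[path[0]])
            for i in range(1, len(path)):
                lp += (np.log(t[path[i - 1], path[i]])
                       + gamma_logpdf(speeds[i], spec.emissions[path[i]]))
            return lp

        best = path_logprob(viterbi_decode(s, spec).states - 1)
        for _ in range(1000):
            rand = rng.integers(0, 2, size=12)
            assert path_logprob(rand) <= best + 1e-9


class TestFitModel:
    def test_model1_recovers_gamma_parameters(self, rng):
        n = 50_000
        truth = GammaSpec(3.0, 2.0)
        speeds = rng.gamma(truth.shape, truth.scale, size=n)
        s = make_series(speeds)
        fit = fit_model(s, "model1", n_starts=3, rng_seed=0)
        est = fit.spec.emissions[0]
        # parametric-bootstrap standard errors of the gamma MLE at this n
        boot_means, boot_sds = [], []
        for b in range(40):
            bs = rng.gamma(truth.shape, truth.scale, size=n)
            refit = fit_model(make_series(bs), "model1", n_starts=1, rng_seed=b)
            boot_means.append(refit.spec.emissions[0].mean)
            boot_sds.append(refit.spec.emissions[0].sd)
        assert abs(est.mean - truth.mean) < 3 * max(np.std(boot_means), 1e-3)
        assert abs(est.sd - truth.sd) < 3 * max(np.std(boot_sds), 1e-3)
        assert fit.n_params == 2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 4)

    def test_model2_recovers_two_states(self, rng):
        speeds, _ = simulate_two_state(rng, 20_000, means=(3.0, 0.2),
                                       sds=(1.0, 0.15), p=0.95)
        fit = fit_model(make_series(speeds), "model2", n_starts=5, rng_seed=1)
        m1, m2 = fit.spec.emissions[0].mean, fit.spec.emissions[1].mean
        assert m1 == pytest.approx(3.0, rel=0.05)
        assert m2 == pytest.approx(0.2, rel=0.05)
        assert m1 > m2  # relabelling: descending means
        np.testing.assert_allclose(fit.spec.transition.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_multi_start_stability(self, rng):
        speeds, _ = simulate_two_state(rng, 8000, means=(5.0, 0.3),
                                       sds=(1.0, 0.2), p=0.95)
        s = make_series(speeds)
        lls = [fit_model(s, "model2", n_starts=3, rng_seed=seed).loglik
               for seed in (1, 2)]
        assert abs(lls[0] - lls[1]) < 1e-4 * max(1, abs(lls[0]))

    def test_fitted_parameters_positive(self, rng):
        speeds, _ = simulate_two_state(rng, 2000, means=(3.0, 0.3),
                                       sds=(1.0, 0.2))
        fit = fit_model(make_series(speeds), "model2", n_starts=2, rng_seed=3)
        for e in fit.spec.emissions:
            assert e.mean > 0 and e.sd > 0
        assert (fit.spec.transition > 0).all()

    def test_fit_result_json_round_trip(self, rng, tmp_path):
        from shoalhmm import FitResult
        speeds, _ = simulate_two_state(rng, 1000, means=(3.0, 0.3),
                                       sds=(1.0, 0.2))
        fit = fit_model(make_series(speeds), "model2", n_starts=1, rng_seed=4)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        assert back.loglik == fit.loglik
        np.testing.assert_array_equal(back.spec.transition, fit.spec.transition)
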