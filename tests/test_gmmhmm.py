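import math

import numpy as np
import pytest

import seizhmm as sz
from conftest import brute_force_loglik, random_gmmhmm


class TestGaussianPdf:
    def test_standard_normal_mode(self):
        assert sz.gaussian_pdf([0.0], [0.0], [[1.0]]) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_bivariate_hand_value(self):
        val = sz.gaussian_pdf([1.0, 0.0], [0.0, 0.0], np.eye(2))
        assert val == pytest.approx(math.exp(-0.5) / (2 * math.pi))

    def test_symmetry_about_mean(self):
        mu = np.array([0.3, -1.2])
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        d = np.array([0.7, 0.4])
        assert sz.gaussian_pdf(mu + d, mu, sigma) == pytest.approx(
            sz.gaussian_pdf(mu - d, mu, sigma))

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            sz.gaussian_pdf([0.0, 0.0], [0.0, 0.0], np.zeros((2, 2)))


class TestEmissionProb:
    def test_single_component_equals_gaussian(self):
        rng = np.random.default_rng(0)
        m = random_gmmhmm(2, 1, 2, rng)
        x = rng.normal(size=2)
        for j in range(2):
            assert sz.emission_prob(x, m, j) == pytest.approx(
                sz.gaussian_pdf(x, m.mu[j, 0], m.sigma[j, 0]))

    def test_two_component_hand_value(self):
        m = sz.GmmHmmModel(a=[[1.0]], pi=[1.0], w=[[0.5, 0.5]],
                           mu=np.array([[[-1.0], [1.0]]]),
                           sigma=np.ones((1, 2, 1, 1)))
        phi1 = math.exp(-0.5) / math.sqrt(2 * math.pi)
        assert sz.emission_prob([0.0], m, 0) == pytest.approx(phi1)

    def test_mixture_dominates_each_weighted_component(self):
        rng = np.random.default_rng(1)
        m = random_gmmhmm(1, 3, 2, rng)
        x = rng.normal(size=2)
        b = sz.emission_prob(x, m, 0)
        for k in range(3):
            assert b >= m.w[0, k] * sz.gaussian_pdf(x, m.mu[0, k], m.sigma[0, k]) - 1e-12


class TestForwardBackward:
    def test_matches_exhaustive_path_sum(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Q = int(rng.integers(1, 4))
            M = int(rng.integers(1, 3))
            T = int(rng.integers(1, 7))
            m = random_gmmhmm(Q, M, 2, rng)
            x = rng.normal(size=(T, 2))
            post = sz.forward_backward(m, x)
            assert post.loglik == pytest.approx(brute_force_loglik(m, x), abs=1e-8)

    def test_single_state_collapse(self):
        rng = np.random.default_rng(2)
        m = random_gmmhmm(1, 2, 2, rng)
        x = rng.normal(size=(8, 2))
        post = sz.forward_backward(m, x)
        np.testing.assert_allclose(post.gamma, 1.0)
        direct = sum(math.log(sz.emission_prob(xt, m, 0)) for xt in x)
        assert post.loglik == pytest.approx(direct)

    def test_deterministic_chain_posterior(self):
        m = sz.GmmHmmModel(a=np.eye(2), pi=[1.0, 0.0], w=[[1.0], [1.0]],
                           mu=np.array([[[0.0]], [[5.0]]]),
                           sigma=np.ones((2, 1, 1, 1)))
        post = sz.forward_backward(m, np.random.default_rng(3).normal(size=(20, 1)))
        np.testing.assert_allclose(post.gamma[:, 0], 1.0, atol=1e-12)

    def test_posterior_consistency_invariants(self):
        rng = np.random.default_rng(4)
        m = random_gmmhmm(3, 2, 2, rng)
        post = sz.forward_backward(m, rng.normal(size=(50, 2)))
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(post.zeta.sum(axis=2), post.gamma[:-1], atol=1e-8)
        np.testing.assert_allclose(post.resp.sum(axis=2), post.gamma, atol=1e-8)

    def test_long_sequence_no_underflow(self):
        rng = np.random.default_rng(5)
        m = random_gmmhmm(2, 1, 2, rng)
        f, _ = sz.simulate_hmm_features(m, 100_000, seed=0)
        post = sz.forward_backward(m, f)
        assert np.isfinite(post.loglik)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        m = random_gmmhmm(2, 1, 2, np.random.default_rng(6))
        with pytest.raises(ValueError, match="dimension"):
            sz.forward_backward(m, np.zeros((5, 3)))

    def test_loglik_invariant_under_state_relabelling(self):
        rng = np.random.default_rng(7)
        m = random_gmmhmm(3, 2, 2, rng)
        x = rng.normal(size=(30, 2))
        perm = [2, 0, 1]
        mp = sz.GmmHmmModel(a=m.a[np.ix_(perm, perm)], pi=m.pi[perm], w=m.w[perm],
                            mu=m.mu[perm], sigma=m.sigma[perm])
        assert sz.forward_backward(mp, x).loglik == pytest.approx(
            sz.forward_backward(m, x).loglik, abs=1e-9)

    def test_agrees_with_hmmlearn(self):
        from hmmlearn.hmm import GMMHMM
        rng = np.random.default_rng(8)
        m = random_gmmhmm(3, 2, 2, rng)
        x = rng.normal(size=(60, 2))
        h = GMMHMM(n_components=3, n_mix=2, covariance_type="full", init_params="")
        h.startprob_, h.transmat_ = m.pi, m.a
        h.weights_, h.means_, h.covars_ = m.w, m.mu, m.sigma
        assert sz.forward_backward(m, x).loglik == pytest.approx(h.score(x), abs=1e-8)


class TestEmFit:
    def test_single_state_single_cluster_closed_form(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(500, 2)) @ np.array([[1.0, 0.3], [0.0, 0.7]]) + [1.0, -2.0]
        res = sz.em_fit(x, 1, 1, seed=0, n_restarts=1, standardize=False)
        np.testing.assert_allclose(res.model.mu[0, 0], x.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(res.model.sigma[0, 0], np.cov(x.T, ddof=0),
                                   atol=1e-4)

    def test_ll_trace_monotone(self, two_state_model):
        f, _ = sz.simulate_hmm_features(two_state_model, 800, seed=10)
        res = sz.em_fit(f, 2, 2, seed=1, n_restarts=2)
        assert np.all(np.diff(res.ll_trace) >= -1e-8)

    def test_parameter_recovery(self, two_state_model):
        f, _ = sz.simulate_hmm_features(two_state_model, 5000, seed=11)
        res = sz.em_fit(f, 2, 1, seed=2, n_restarts=1, standardize=False)
        m = res.model
        perm = [0, 1] if np.linalg.norm(m.mu[0, 0]) < np.linalg.norm(m.mu[1, 0]) else [1, 0]
        assert np.abs(m.a[np.ix_(perm, perm)] - two_state_model.a).max() < 0.05
        assert np.abs(m.mu[perm] - two_state_model.mu).max() < 0.1

    def test_multi_sequence_fit_spreads_initial_distribution(self, two_state_model):
        seqs = [sz.simulate_hmm_features(two_state_model, 300, seed=s)[0]
                for s in range(6)]
        res = sz.em_fit(seqs, 2, 1, seed=3, n_restarts=1, standardize=False)
        # several sequences start in each state, so pi must not be one-hot
        assert res.model.pi.max() < 1.0 - 1e-6

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            sz.em_fit(np.zeros((3, 2)), 2, 2, seed=0)

    def test_topology_bounds_enforced(self):
        x = np.random.default_rng(0).normal(size=(100, 2))
        with pytest.raises(ValueError, match="Q"):
            sz.em_fit(x, 11, 1)
        with pytest.raises(ValueError, match="M"):
            sz.em_fit(x, 2, 6)

    def test_standardize_stores_scaler(self, two_state_model):
        f, _ = sz.simulate_hmm_features(two_state_model, 300, seed=12)
        res = sz.em_fit(f, 2, 1, seed=4, n_restarts=1, standardize=True)
        sc = res.model.feature_scaler
        assert sc is not None
        np.testing.assert_allclose(sc.mean, f.x.mean(axis=0))


class TestDecode:
    def test_single_state_constant_trace(self):
        m = random_gmmhmm(1, 1, 2, np.random.default_rng(13))
        states, _ = sz.decode(m, np.random.default_rng(14).normal(size=(10, 2)))
        assert np.all(states == 0)

    def test_recovers_generating_path_when_separated(self, two_state_model):
        f, path = sz.simulate_hmm_features(two_state_model, 5000, seed=15)
        res = sz.em_fit(f, 2, 1, seed=5, n_restarts=1, standardize=False)
        states, _ = sz.decode(res.model, f)
        acc = max((states == path).mean(), (states == 1 - path).mean())
        assert acc >= 0.99


class TestSerialization:
    def test_json_round_trip_bit_exact(self, two_state_model, tmp_path):
        f, _ = sz.simulate_hmm_features(two_state_model, 400, seed=16)
        model = sz.em_fit(f, 2, 1, seed=6, n_restarts=1).model
        path = tmp_path / "model.json"
        model.to_json(path)
        back = sz.GmmHmmModel.from_json(path)
        for attr in ("a", "pi", "w", "mu", "sigma"):
            assert np.array_equal(getattr(model, attr), getattr(back, attr))
        np.testing.assert_array_equal(model.feature_scaler.mean, back.feature_scaler.mean)
        s1, _ = sz.decode(model, f)
        s2, _ = sz.decode(back, f)
        assert np.array_equal(s1, s2)
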