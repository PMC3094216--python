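import numpy as np
import pytest

import seizhmm as sz
from seizhmm.assignment import ChronicMarkError


def logistic_series(n=5000, x0=0.4):
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
    return x


class TestLyapunovExponent:
    def test_logistic_map_exponent(self):
        lam = sz.lyapunov_exponent(logistic_series(), fs=1.0, embed_dim=2,
                                   delay=1, horizon_s=4.0, min_separation=10)
        assert lam == pytest.approx(np.log(2.0), rel=0.10)

    def test_periodic_orbit_near_zero(self):
        fs = 1000.0
        t = np.arange(int(5 * fs)) / fs
        lam_sine = sz.lyapunov_exponent(np.sin(2 * np.pi * 10 * t), fs=fs)
        lam_noise = sz.lyapunov_exponent(
            np.random.default_rng(0).standard_normal(int(5 * fs)), fs=fs)
        assert abs(lam_sine) < 0.05 * lam_noise
        assert lam_noise > lam_sine

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            sz.lyapunov_exponent(np.sin(np.arange(60) / 3.0), fs=10.0, embed_dim=7)


class TestRosensteinTrace:
    def test_trace_shapes_and_params(self):
        fs = 1000.0
        t = np.arange(int(12 * fs)) / fs
        sig = sz.SignalRecord(np.sin(2 * np.pi * 8 * t), fs, preprocessed=True)
        trace = sz.rosenstein_lyapunov(sig, window_s=5.0, hop_s=2.0, embed_dim=5)
        assert trace.times_s.size == trace.lam.size == 4
        assert trace.params["embed_dim"] == 5


class TestMarkChronicInterval:
    def test_annotation_passthrough(self, sle_event):
        gt = sle_event["gt"]
        ecsot, end = sz.mark_chronic_interval(annotations=gt)
        assert ecsot == gt.ecsot_s == 110.0
        assert end == 184.0

    def test_sustained_lyapunov_drop_detected(self):
        rng = np.random.default_rng(1)
        times = np.arange(0.0, 214.0)
        lam = 1.0 + 0.05 * rng.standard_normal(times.size)
        ictal = (times >= 110.0) & (times < 184.0)
        lam[ictal] = 0.2 + 0.05 * rng.standard_normal(ictal.sum())
        ecsot, end = sz.mark_chronic_interval(trace=sz.LyapunovTrace(times, lam))
        assert abs(ecsot - 110.0) <= 3.0
        assert abs(end - 184.0) <= 5.0

    def test_flat_trace_raises(self):
        trace = sz.LyapunovTrace(np.arange(50.0), np.ones(50))
        with pytest.raises(ChronicMarkError):
            sz.mark_chronic_interval(trace=trace)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="provide"):
            sz.mark_chronic_interval()


def _posterior_from_states(states, Q):
    gamma = np.full((len(states), Q), 0.01 / max(Q - 1, 1))
    for t, s in enumerate(states):
        gamma[t] = 0.01 / max(Q - 1, 1)
        gamma[t, s] = 0.99
    return sz.PosteriorSet(log_alpha=np.log(gamma), log_beta=np.zeros_like(gamma),
                           gamma=gamma, zeta=np.zeros((len(states) - 1, Q, Q)),
                           resp=gamma[:, :, None], loglik=0.0)


def _chain_model(Q, order=None):
    """Near-unidirectional transition chain over the given state order."""
    order = list(order or range(Q))
    a = np.full((Q, Q), 1e-4)
    for i, s in enumerate(order):
        nxt = order[(i + 1) % len(order)]
        a[s, s] = 0.9
        a[s, nxt] = 0.1
    a /= a.sum(axis=1, keepdims=True)
    return sz.GmmHmmModel(a=a, pi=np.full(Q, 1.0 / Q), w=np.ones((Q, 1)),
                          mu=np.zeros((Q, 1, 2)), sigma=np.tile(np.eye(2), (Q, 1, 1, 1)))


class TestAssignStates:
    def test_three_block_progression(self):
        states = [0] * 40 + [1] * 20 + [2] * 50
        model = _chain_model(3)
        sa = sz.assign_states(model, _posterior_from_states(states, 3),
                              (60.0, 110.0), np.arange(110.0))
        assert sa.mapping == {2: "chronic", 1: "late_tonic", 0: "interictal"}
        assert sa.chronic_state == 2

    def test_five_state_chain_with_postictal_consolidation(self):
        # visited pre-chronic: S1 (baseline) then S3 (tonic); chronic S4;
        # S0 and S2 appear only after chronic offset -> consolidated postictal
        states = [1] * 40 + [3] * 20 + [4] * 50 + [0] * 10 + [2] * 10
        model = _chain_model(5, order=[1, 3, 4, 0, 2])
        sa = sz.assign_states(model, _posterior_from_states(states, 5),
                              (60.0, 110.0), np.arange(130.0))
        assert sa.mapping[4] == "chronic"
        assert sa.mapping[3] == "late_tonic"
        assert sa.mapping[1] == "interictal"
        assert sa.consolidated["postictal"] == [0, 2]

    def test_four_pre_chronic_states_include_early_tonic(self):
        states = [0] * 30 + [1] * 20 + [2] * 20 + [3] * 40
        model = _chain_model(4)
        sa = sz.assign_states(model, _posterior_from_states(states, 4),
                              (70.0, 110.0), np.arange(110.0))
        assert sa.mapping == {3: "chronic", 2: "late_tonic",
                              1: "early_tonic", 0: "interictal"}

    def test_single_state_model_all_chronic(self):
        states = [0] * 30
        model = _chain_model(1)
        sa = sz.assign_states(model, _posterior_from_states(states, 1),
                              (5.0, 25.0), np.arange(30.0))
        assert sa.mapping == {0: "chronic"}

    def test_single_pre_chronic_state_is_generic_tonic(self):
        states = [1] * 30 + [0] * 30
        model = _chain_model(2, order=[1, 0])
        sa = sz.assign_states(model, _posterior_from_states(states, 2),
                              (30.0, 60.0), np.arange(60.0))
        assert sa.mapping == {0: "chronic", 1: "tonic"}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        states = list(rng.integers(0, 4, size=80))
        states[50:70] = [3] * 20
        model = _chain_model(4)
        post = _posterior_from_states(states, 4)
        times = np.arange(80.0)
        sa = sz.assign_states(model, post, (50.0, 70.0), times)
        labels = sa.apply(np.asarray(states))

        perm = np.array([2, 0, 3, 1])  # new index of old state i
        inv = np.argsort(perm)
        pm = sz.GmmHmmModel(a=model.a[np.ix_(inv, inv)], pi=model.pi[inv],
                            w=model.w[inv], mu=model.mu[inv], sigma=model.sigma[inv])
        ppost = _posterior_from_states([perm[s] for s in states], 4)
        sa_p = sz.assign_states(pm, ppost, (50.0, 70.0), times)
        labels_p = sa_p.apply(np.asarray([perm[s] for s in states]))
        assert np.array_equal(labels, labels_p)

    def test_warns_without_dominant_chronic_state(self):
        Q = 3
        gamma = np.full((30, Q), 1.0 / Q)
        post = sz.PosteriorSet(np.log(gamma), np.zeros_like(gamma), gamma,
                               np.zeros((29, Q, Q)), gamma[:, :, None], 0.0)
        model = _chain_model(3)
        with pytest.warns(UserWarning, match="dominant"):
            sz.assign_states(model, post, (10.0, 20.0), np.arange(30.0))
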