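"""Baum-Welch training recovers a known Gaussian-mixture HMM.

Samples 5000 windows from a two-state model with well-separated emissions,
refits from scratch and compares the recovered transition matrix and means
against the generating truth (after aligning the arbitrary state labels).
"""

import numpy as np

import seizhmm as sz

truth = sz.GmmHmmModel(
    a=[[0.9, 0.1], [0.2, 0.8]], pi=[0.5, 0.5], w=[[1.0], [1.0]],
    mu=np.array([[[0.0, 0.0]], [[3.0, 3.0]]]),
    sigma=np.tile(np.eye(2), (2, 1, 1, 1)))

feats, path = sz.simulate_hmm_features(truth, n_windows=5000, seed=0)
fit = sz.em_fit(feats, Q=2, M=1, seed=1, n_restarts=1, standardize=False)
model = fit.model

# align state labels by distance of the fitted means to the true means
perm = [0, 1] if np.linalg.norm(model.mu[0, 0]) < np.linalg.norm(model.mu[1, 0]) \
    else [1, 0]

np.set_printoptions(precision=3, suppress=True)
print(f"EM converged in {fit.n_iter} iterations "
      f"(final log-likelihood {fit.ll_trace[-1]:.1f})")
print("true a:\n", np.asarray(truth.a))
print("fitted a:\n", model.a[np.ix_(perm, perm)])
print("fitted means:", model.mu[perm].squeeze().round(3).tolist())

states, _ = sz.decode(model, feats)
acc = max((states == path).mean(), (states == 1 - path).mean())
print(f"posterior-decoding accuracy against the generating path: {acc:.1%}")
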