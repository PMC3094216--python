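"""End-to-end unsupervised seizure-stage detection on synthetic events.

Simulates three seizure-like events, trains one Q=5/M=3 mixture-emission
HMM on their 14-D wavelet features (multi-sequence EM), anchors the state
labels on each event's annotated chronic interval, and scores detection:
sensitivity (TP), specificity (TN), onset delay (dT, positive = early) and
the optimality index O in [0, 1].
"""

import seizhmm as sz

events = []
for seed in (1, 2, 3):
    sig, truth = sz.simulate_sle_lfp(sz.default_stage_recipe(), seed=seed)
    feats = sz.append_rate_of_change(sz.cwt_band_coefficients(sz.preprocess(sig)))
    events.append((feats, truth))

fit = sz.em_fit([f for f, _ in events], Q=5, M=3, seed=0, n_restarts=2)
print(f"trained Q=5, M=3 model on {sum(f.T for f, _ in events)} windows "
      f"({fit.n_iter} EM iterations)")

traces, truths = [], []
for feats, truth in events:
    states, post = sz.decode(fit.model, feats)
    assign = sz.assign_states(fit.model, post, truth.chronic_interval(),
                              feats.times_s, feats.window_s)
    traces.append(sz.LabeledTrace(feats.times_s, assign.apply(states), feats.window_s))
    truths.append(truth)
print("state -> stage mapping of the last event:",
      dict(sorted(assign.mapping.items())))

report = sz.evaluate(traces, truths)
print(f"\nsensitivity (TP): {report.tp_percent:.1f} %")
print(f"specificity (TN): {report.tn_percent:.1f} %")
print(f"mean onset delay dT: {report.mean_delta_t_s:+.1f} s (positive = early)")
print(f"mean optimality index O: {report.mean_o:.3f}")
print("\nAn O near 1 means every chronic onset was caught within seconds "
      "without false alarms in the pre-ictal baseline.")
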