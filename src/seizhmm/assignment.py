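"""Expert-guided assignment of HMM states to electrographic stage labels.

Training is unsupervised, so the fitted states carry no labels.  Assignment
anchors on the chronic-seizure interval — either given by annotations or
marked by a drop in a short-time maximum Lyapunov exponent (Rosenstein's
nearest-neighbor divergence estimator), reflecting the lowered complexity
of synchronized ictal rhythms.  The most probable state inside that
interval becomes *chronic*; walking backward in time through the decoded
trace, the distinct states encountered become *late_tonic*, *early_tonic*
and finally *interictal* (the earliest pre-chronic state is always
interictal; a single pre-chronic state is labelled generic *tonic*).
States first appearing after chronic offset become *postictal*; any state
never visited is labelled by transition-matrix adjacency to a labelled one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .gmmhmm import GmmHmmModel, PosteriorSet
from .signals import GroundTruth, SignalRecord

__all__ = [
    "LyapunovTrace",
    "StateAssignment",
    "ChronicMarkError",
    "lyapunov_exponent",
    "rosenstein_lyapunov",
    "mark_chronic_interval",
    "assign_states",
]

log = logging.getLogger(__name__)


class ChronicMarkError(RuntimeError):
    """No ictal transition found; manual annotation required."""


@dataclass
class LyapunovTrace:
    times_s: np.ndarray
    lam: np.ndarray  # largest Lyapunov exponent per window, 1/s
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.times_s.size != self.lam.size:
            raise ValueError("times and lam must have the same length")


@dataclass
class StateAssignment:
    """Mapping from HMM state index to electrographic stage label."""

    mapping: dict[int, str]
    chronic_state: int
    consolidated: dict[str, list[int]]

    def apply(self, states: np.ndarray) -> np.ndarray:
        """Translate a decoded state trace into stage labels."""
        lut = np.array([self.mapping[i] for i in sorted(self.mapping)], dtype=object)
        return lut[np.asarray(states, dtype=int)]


# ---------------------------------------------------------------------------
# Rosenstein largest Lyapunov exponent


def _autocorr_zero_crossing(x: np.ndarray, max_lag: int) -> int:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    for lag in range(1, max_lag):
        if np.dot(x[:-lag], x[lag:]) / denom <= 0:
            return lag
    return max_lag


def _mean_period_samples(x: np.ndarray) -> float:
    """Mean period = 1 / power-weighted mean frequency, in samples."""
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size)  # cycles/sample
    power = spec[1:]
    if power.sum() == 0:
        return float(x.size)
    fmean = float(np.sum(freqs[1:] * power) / power.sum())
    return 1.0 / fmean if fmean > 0 else float(x.size)


def lyapunov_exponent(x: np.ndarray, fs: float = 1.0, embed_dim: int = 7,
                      delay: Optional[int] = None, horizon_s: float = 0.1,
                      min_separation: Optional[int] = None,
                      min_neighbor_dist: float = 1e-12) -> float:
    """Largest Lyapunov exponent of one window via Rosenstein's method.

    Delay-embeds ``x``, pairs every point with its nearest neighbor more
    than a mean period away in time, averages the log divergence of the
    pairs over a fixed horizon and fits a line; the slope (per second) is
    the exponent.  ``delay`` defaults to the first autocorrelation zero
    crossing; ``min_separation`` (Theiler window) to the mean period.
    """
    x = np.asarray(x, dtype=float).ravel()
    if delay is None:
        delay = max(1, _autocorr_zero_crossing(x, max_lag=min(x.size // 2, 500)))
    if min_separation is None:
        min_separation = max(1, int(round(_mean_period_samples(x))))
    n_embed = x.size - (embed_dim - 1) * delay
    horizon = max(2, int(round(horizon_s * fs)))
    if n_embed < 2 * (min_separation + horizon + 2):
        raise ValueError("too few embedded points for the requested window")

    idx = np.arange(n_embed)
    emb = np.empty((n_embed, embed_dim))
    for d in range(embed_dim):
        emb[:, d] = x[d * delay: d * delay + n_embed]

    tree = cKDTree(emb)
    # request enough neighbors to escape the Theiler exclusion zone
    k = min(n_embed, 2 * min_separation + 4)
    dists, nbrs = tree.query(emb, k=k)
    neighbor = np.full(n_embed, -1)
    for i in range(n_embed):
        for d, j in zip(dists[i], nbrs[i]):
            if abs(int(j) - i) > min_separation and d > min_neighbor_dist:
                neighbor[i] = int(j)
                break

    valid = (neighbor >= 0) & (idx + horizon < n_embed) & \
            (np.take(neighbor, idx, mode="clip") + horizon < n_embed)
    if valid.sum() < 10:
        raise ValueError("too few neighbor pairs to track divergence")
    i_idx = idx[valid]
    j_idx = neighbor[valid]

    ks = np.arange(horizon + 1)
    logd = np.empty(ks.size)
    for k_step in ks:
        d = np.linalg.norm(emb[i_idx + k_step] - emb[j_idx + k_step], axis=1)
        logd[k_step] = np.mean(np.log(np.maximum(d, 1e-300)))
    slope = np.polyfit(ks / fs, logd, 1)[0]
    return float(slope)


def rosenstein_lyapunov(sig: SignalRecord, window_s: float = 5.0, hop_s: float = 1.0,
                        embed_dim: int = 7, delay: Optional[int] = None,
                        horizon_s: float = 0.1) -> LyapunovTrace:
    """Short-time maximum Lyapunov exponent over sliding windows.

    Windows with too few usable neighbor pairs are reported as NaN with a
    warning.  Returns the per-window exponent (1/s) at window start times.
    """
    fs = sig.fs_hz
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if win < 10 * embed_dim * (delay or 1):
        raise ValueError("window too short for the embedding parameters")
    starts = np.arange(0, sig.n_samples - win + 1, hop)
    lam = np.empty(starts.size)
    n_bad = 0
    for i, s0 in enumerate(starts):
        try:
            lam[i] = lyapunov_exponent(sig.samples[s0: s0 + win], fs=fs,
                                       embed_dim=embed_dim, delay=delay,
                                       horizon_s=horizon_s)
        except ValueError:
            lam[i] = np.nan
            n_bad += 1
    if n_bad:
        log.warning("%d of %d Lyapunov windows skipped (NaN)", n_bad, starts.size)
    return LyapunovTrace(starts / fs, lam,
                         params={"embed_dim": embed_dim, "delay": delay,
                                 "window_s": window_s, "hop_s": hop_s,
                                 "horizon_s": horizon_s})


# ---------------------------------------------------------------------------
# chronic-interval marking


def _first_run(mask: np.ndarray, persistence: int) -> Optional[int]:
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def mark_chronic_interval(trace: Optional[LyapunovTrace] = None,
                          annotations: Optional[GroundTruth] = None,
                          direction: str = "drop",
                          baseline_quantile: float = 0.2,
                          persistence: int = 5) -> tuple[float, float]:
    """Locate the chronic interval: (EcSOT, chronic end) in seconds.

    With ``annotations`` the interval is read directly.  With a Lyapunov
    trace, onset is the first sustained (``persistence`` consecutive
    windows) excursion of the exponent past its own ``baseline_quantile``
    band — below it for ``direction='drop'`` (synchronized ictal rhythms
    lower complexity), above the mirrored band for ``'rise'`` — and the end
    is the first sustained recovery.
    """
    if annotations is not None:
        iv = annotations.chronic_interval()
        if iv is None:
            raise ChronicMarkError("annotations contain no chronic interval")
        return iv
    if trace is None:
        raise ValueError("provide either a Lyapunov trace or annotations")

    lam = trace.lam
    finite = np.isfinite(lam)
    if finite.sum() < persistence:
        raise ChronicMarkError("Lyapunov trace too short or all-NaN")
    if direction == "drop":
        thr = np.quantile(lam[finite], baseline_quantile)
        crossing = finite & (lam < thr)
    elif direction == "rise":
        thr = np.quantile(lam[finite], 1.0 - baseline_quantile)
        crossing = finite & (lam > thr)
    else:
        raise ValueError("direction must be 'drop' or 'rise'")

    onset_idx = _first_run(crossing, persistence)
    if onset_idx is None:
        raise ChronicMarkError(
            "no sustained Lyapunov transition found; provide annotations")
    after = ~crossing[onset_idx:]
    rec = _first_run(after, persistence)
    end_idx = onset_idx + rec if rec is not None else lam.size - 1
    return float(trace.times_s[onset_idx]), float(trace.times_s[end_idx])


# ---------------------------------------------------------------------------
# state-to-stage assignment


def assign_states(model: GmmHmmModel, post: PosteriorSet,
                  chronic_interval: tuple[float, float],
                  times_s: np.ndarray, window_s: float = 1.0) -> StateAssignment:
    """Map HMM states to stage labels anchored on the chronic interval.

    The state with the highest mean posterior inside the chronic interval is
    *chronic*.  Walking backward from chronic onset through the decoded
    trace, newly encountered states are labelled *late_tonic*, then
    *early_tonic*; the earliest pre-chronic state is *interictal* (with a
    single pre-chronic state it is generic *tonic*).  States first seen
    after chronic offset are *postictal*; still-unlabelled states inherit
    the label of their strongest transition-matrix neighbor.
    """
    times_s = np.asarray(times_s, dtype=float)
    gamma = post.gamma
    if times_s.size != gamma.shape[0]:
        raise ValueError("times_s must match the decoded trace length")
    start, end = chronic_interval
    Q = model.Q
    in_chronic = (times_s >= start - 1e-9) & (times_s < end - 1e-9)
    if not in_chronic.any():
        raise ValueError("decoded trace does not cover the chronic interval")

    mean_gamma = gamma[in_chronic].mean(axis=0)
    chronic_state = int(mean_gamma.argmax())
    if Q > 1 and mean_gamma.max() < 1.0 / Q + 0.05:
        warnings.warn("no clearly dominant state inside the chronic interval",
                      stacklevel=2)

    decoded = gamma.argmax(axis=1)
    mapping: dict[int, str] = {chronic_state: "chronic"}

    pre = decoded[times_s < start - 1e-9]
    pre_order: list[int] = []  # distinct states, nearest-to-chronic first
    for s in pre[::-1]:
        s = int(s)
        if s != chronic_state and s not in pre_order:
            pre_order.append(s)
    if len(pre_order) == 1:
        mapping[pre_order[0]] = "tonic"
    elif pre_order:
        mapping[pre_order[0]] = "late_tonic"
        mapping[pre_order[-1]] = "interictal"
        for s in pre_order[1:-1]:
            mapping[s] = "early_tonic"

    post_states = decoded[times_s >= end - 1e-9]
    for s in post_states:
        s = int(s)
        if s not in mapping:
            mapping[s] = "postictal"

    # unvisited states: inherit from the strongest-connected labelled state
    remaining = [s for s in range(Q) if s not in mapping]
    while remaining:
        progressed = False
        for s in list(remaining):
            labelled = [l for l in range(Q) if l in mapping]
            strengths = [max(model.a[s, l], model.a[l, s]) for l in labelled]
            if strengths and max(strengths) > 0:
                mapping[s] = mapping[labelled[int(np.argmax(strengths))]]
                remaining.remove(s)
                progressed = True
        if not progressed:
            for s in remaining:  # isolated states: default to interictal
                mapping[s] = "interictal"
            break

    consolidated: dict[str, list[int]] = {}
    for s, lbl in sorted(mapping.items()):
        consolidated.setdefault(lbl, []).append(s)
    return StateAssignment(mapping=mapping, chronic_state=chronic_state,
                           consolidated=consolidated)
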