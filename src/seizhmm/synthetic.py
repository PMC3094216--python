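"""Synthetic data: HMM feature sequences and seizure-like LFP traces.

Two generators back the test bench in place of undeposited slice
recordings:

* :func:`simulate_hmm_features` samples feature sequences from a known
  Gaussian-mixture HMM, the oracle for parameter-recovery and decoding
  tests.

* :func:`simulate_sle_lfp` synthesizes a multistage seizure-like event
  (SLE): per stage, band-limited noise mixed according to a seven-band
  spectral profile, plus Poisson-timed Morlet-like spike transients, scaled
  by a stage amplitude.  Ground-truth stage intervals (and the chronic
  onset time, EcSOT) are returned alongside the trace.

The default five-stage recipe follows the timing scale of in vitro
low-Mg2+ hippocampal SLEs: interictal 60 s, early tonic 30 s, late tonic
20 s (tonic total ~50 s), chronic 74 s, postictal 30 s, so EcSOT = 110 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .features import DEFAULT_BANDS, BandSet, FeatureMatrix
from .gmmhmm import GmmHmmModel
from .signals import GroundTruth, SignalRecord, STAGE_LABELS

__all__ = [
    "StageSpec",
    "default_stage_recipe",
    "simulate_hmm_features",
    "simulate_sle_lfp",
]


@dataclass
class StageSpec:
    """One electrographic stage of a synthetic SLE.

    ``band_power`` gives seven nonnegative amplitude weights over the default
    bands (delta .. fast ripple); ``spike_rate_hz`` the Poisson rate of
    broadband spike transients; ``amplitude_scale`` an overall gain.
    """

    label: str
    duration_s: float
    band_power: Sequence[float]
    spike_rate_hz: float = 0.0
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in STAGE_LABELS:
            raise ValueError(f"unknown stage label {self.label!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        self.band_power = np.asarray(self.band_power, dtype=float)
        if self.band_power.size != len(DEFAULT_BANDS):
            raise ValueError(f"band_power needs {len(DEFAULT_BANDS)} entries")
        if np.any(self.band_power < 0):
            raise ValueError("band_power must be nonnegative")
        if self.spike_rate_hz < 0:
            raise ValueError("spike_rate_hz must be nonnegative")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")


def default_stage_recipe() -> list[StageSpec]:
    """Five-stage SLE at the timing scale of low-Mg2+ slice events.

    Spectral profiles are plausible stage phenomenology, not measured
    values: interictal/postictal are slow-wave dominated, tonic stages
    shift power into theta-alpha then alpha-beta, and the chronic discharge
    concentrates power in 8-40 Hz with elevated amplitude and spike rate.
    """
    return [
        StageSpec("interictal", 60.0, [1.0, 0.40, 0.15, 0.05, 0.02, 0.01, 0.005],
                  spike_rate_hz=0.2, amplitude_scale=1.0),
        StageSpec("early_tonic", 30.0, [0.5, 1.0, 0.6, 0.2, 0.05, 0.02, 0.01],
                  spike_rate_hz=2.0, amplitude_scale=1.5),
        StageSpec("late_tonic", 20.0, [0.3, 0.6, 1.0, 0.6, 0.15, 0.05, 0.02],
                  spike_rate_hz=5.0, amplitude_scale=2.0),
        StageSpec("chronic", 74.0, [0.2, 0.4, 1.0, 1.2, 0.5, 0.15, 0.05],
                  spike_rate_hz=8.0, amplitude_scale=3.0),
        StageSpec("postictal", 30.0, [1.0, 0.2, 0.05, 0.02, 0.01, 0.005, 0.002],
                  spike_rate_hz=0.05, amplitude_scale=0.35),
    ]


def simulate_hmm_features(model: GmmHmmModel, n_windows: int, seed: int = 0,
                          window_s: float = 1.0) -> tuple[FeatureMatrix, np.ndarray]:
    """Sample a state path and observations from a Gaussian-mixture HMM.

    The path starts from ``pi`` and follows ``a``; each observation is drawn
    from the mixture of its state.  Bit-reproducible for a fixed seed.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    Q, M, D = model.Q, model.M, model.D

    a_cum = np.cumsum(model.a, axis=1)
    pi_cum = np.cumsum(model.pi)
    u = rng.random(n_windows)
    states = np.empty(n_windows, dtype=int)
    states[0] = np.searchsorted(pi_cum, u[0])
    for t in range(1, n_windows):
        states[t] = np.searchsorted(a_cum[states[t - 1]], u[t])
    states = np.minimum(states, Q - 1)

    w_cum = np.cumsum(model.w, axis=1)
    comps = np.minimum(
        (rng.random(n_windows)[:, None] > w_cum[states]).sum(axis=1), M - 1)

    chol = np.linalg.cholesky(model.sigma)          # (Q, M, D, D)
    z = rng.standard_normal((n_windows, D))
    L = chol[states, comps]
    x = model.mu[states, comps] + np.einsum("tij,tj->ti", L, z)

    labels = model.band_labels or [f"f{i}" for i in range(D)]
    fm = FeatureMatrix(x, window_s, list(labels), np.arange(n_windows) * window_s)
    return fm, states


def _band_limited_noise(n: int, fs: float, low: float, high: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise restricted to [low, high] Hz (4th-order Butterworth)."""
    pad = int(fs)  # 1 s of padding eaten by filter transients
    white = rng.standard_normal(n + 2 * pad)
    nyq = fs / 2.0
    hi = min(high, 0.99 * nyq)
    sos = sps.butter(4, [low, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, white)[pad: pad + n]
    rms = np.sqrt(np.mean(y ** 2))
    return y / rms if rms > 0 else y


def _spike_transient(width_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-enveloped oscillatory burst (Morlet-like), 50-150 ms wide."""
    n = max(int(round(width_s * fs)), 8)
    t = (np.arange(n) - n / 2) / fs
    sigma = width_s / 6.0
    f0 = rng.uniform(2.0, 4.0) / width_s  # a few cycles under the envelope
    return np.cos(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)) * \
        np.exp(-0.5 * (t / sigma) ** 2)


def simulate_sle_lfp(stages: Sequence[StageSpec], fs_hz: float = 1000.0,
                     seed: int = 0, bands: BandSet = DEFAULT_BANDS
                     ) -> tuple[SignalRecord, GroundTruth]:
    """Synthesize a multistage seizure-like LFP with exact ground truth.

    Each stage is a band-power-weighted sum of band-limited noise plus
    Poisson-timed spike transients, scaled by the stage amplitude; stages
    are concatenated in order.  Requires ``fs_hz`` of at least twice the
    highest band edge.
    """
    if not stages:
        raise ValueError("need at least one stage")
    max_edge = max(b.high_hz for b in bands)
    if fs_hz < 2.0 * max_edge:
        raise ValueError(
            f"fs_hz={fs_hz} below Nyquist for the {max_edge} Hz band edge")

    rng = np.random.default_rng(seed)
    pieces: list[np.ndarray] = []
    intervals: list[tuple[str, float, float]] = []
    t0 = 0.0
    for stage in stages:
        n = int(round(stage.duration_s * fs_hz))
        seg = np.zeros(n)
        for wgt, band in zip(stage.band_power, bands):
            if wgt > 0:
                seg += wgt * _band_limited_noise(n, fs_hz, band.low_hz, band.high_hz, rng)
        noise_std = max(seg.std(), 1e-12)
        n_spikes = rng.poisson(stage.spike_rate_hz * stage.duration_s)
        for _ in range(n_spikes):
            width = rng.uniform(0.05, 0.15)
            wave = _spike_transient(width, fs_hz, rng)
            amp = rng.uniform(2.0, 4.0) * noise_std * rng.choice([-1.0, 1.0])
            center = rng.integers(0, n)
            lo = max(0, center - wave.size // 2)
            hi = min(n, lo + wave.size)
            seg[lo:hi] += amp * wave[: hi - lo]
        pieces.append(stage.amplitude_scale * seg)
        intervals.append((stage.label, t0, t0 + stage.duration_s))
        t0 += stage.duration_s

    samples = np.concatenate(pieces)
    gt = GroundTruth(stage_intervals=intervals)
    sig = SignalRecord(samples, fs_hz, preprocessed=False, ground_truth=gt)
    return sig, gt
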