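"""Wavelet band-power features.

The detector's observation vector is built from a Morlet continuous wavelet
transform (CWT): for every non-overlapping 1-second window the mean absolute
wavelet coefficient is taken over a log-spaced grid of scales inside each of
seven physiologically motivated frequency bands (delta through fast ripple).
This yields a 7-dimensional coefficient vector ``c`` per window; appending
the first difference ``dc`` from the previous window doubles it to 14-D.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pywt

from .signals import SignalRecord

__all__ = [
    "Band",
    "BandSet",
    "DEFAULT_BANDS",
    "FeatureMatrix",
    "cwt_band_coefficients",
    "append_rate_of_change",
]

log = logging.getLogger(__name__)

MORLET_OMEGA0 = 6.0  # standard Morlet center frequency parameter
ROC_PREFIX = "dc_"   # column prefix for rate-of-change features


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name!r}: need 0 < low < high")


@dataclass(frozen=True)
class BandSet:
    """Ordered, non-overlapping frequency bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        prev_high = 0.0
        prev_low = -1.0
        for b in self.bands:
            if b.low_hz < prev_low:
                raise ValueError("bands must be ordered by low edge")
            if b.low_hz < prev_high - 1e-9:
                raise ValueError(f"band {b.name!r} overlaps the previous band")
            prev_low, prev_high = b.low_hz, b.high_hz

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]


#: The seven-band feature space: delta (treated as 0.5-4 Hz), theta, alpha,
#: beta, gamma, super gamma and fast ripple.
DEFAULT_BANDS = BandSet((
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 15.0),
    Band("beta", 15.0, 40.0),
    Band("gamma", 40.0, 100.0),
    Band("super_gamma", 100.0, 250.0),
    Band("fast_ripple", 250.0, 400.0),
))


@dataclass
class FeatureMatrix:
    """T x D matrix of per-window feature vectors.

    ``x[t]`` is the observation for the window starting at ``times_s[t]``;
    ``band_labels`` names the D columns.
    """

    x: np.ndarray
    window_s: float
    band_labels: list[str]
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.x.shape[0] != self.times_s.size:
            raise ValueError("times_s length must match number of windows")
        if self.x.shape[1] != len(self.band_labels):
            raise ValueError("band_labels length must match feature dimension")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("features must be finite")

    @property
    def T(self) -> int:
        return self.x.shape[0]

    @property
    def D(self) -> int:
        return self.x.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset by feature name (used after mRMR reduction)."""
        idx = [self.band_labels.index(n) for n in names]
        return FeatureMatrix(self.x[:, idx], self.window_s, list(names), self.times_s)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.x, columns=self.band_labels)
        df.insert(0, "window_start_s", self.times_s)
        df.attrs["window_s"] = self.window_s
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window_s: Optional[float] = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        times = df["window_start_s"].to_numpy(float)
        cols = [c for c in df.columns if c != "window_start_s"]
        if window_s is None:
            window_s = float(np.median(np.diff(times))) if times.size > 1 else 1.0
        return cls(df[cols].to_numpy(float), window_s, cols, times)


def _morlet_wavelet(bandwidth: float = 2.0, omega0: float = MORLET_OMEGA0) -> pywt.ContinuousWavelet:
    # cmorB-C with B=2 and C=omega0/(2*pi) reproduces the analytic Morlet
    # psi(t) = pi^{-1/4} exp(i*omega0*t) exp(-t^2/2) up to normalization,
    # giving the scale-frequency map f = omega0 * fs / (2*pi*s).
    center = omega0 / (2.0 * math.pi)
    return pywt.ContinuousWavelet(f"cmor{bandwidth:.1f}-{center:.12f}")


def band_scale_grid(band: Band, fs_hz: float, n_scales: int = 8,
                    omega0: float = MORLET_OMEGA0) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced frequencies inside a band and the matching Morlet scales."""
    freqs = np.geomspace(band.low_hz, band.high_hz, n_scales)
    scales = omega0 * fs_hz / (2.0 * math.pi * freqs)
    return freqs, scales


def cwt_band_coefficients(sig: SignalRecord, bands: BandSet = DEFAULT_BANDS,
                          window_s: float = 1.0, n_scales_per_band: int = 8) -> FeatureMatrix:
    """Morlet-CWT band features per non-overlapping window.

    For each band the CWT is evaluated on a log-spaced grid of
    ``n_scales_per_band`` scales spanning the band; the feature is the mean
    absolute coefficient over those scales and the window's samples.  Bands
    whose upper edge exceeds Nyquist are dropped with a warning.  The signal
    is expected to be preprocessed (normalized to [-1, 1]).
    """
    fs = sig.fs_hz
    win_len = window_s * fs
    if abs(win_len - round(win_len)) > 1e-9 or round(win_len) < 1:
        raise ValueError("window_s * fs_hz must be a positive integer")
    win_len = int(round(win_len))
    n_win = sig.n_samples // win_len
    if n_win < 1:
        raise ValueError("signal shorter than one analysis window")

    kept = [b for b in bands]
    dropped = [b for b in kept if b.high_hz > fs / 2.0]
    if dropped:
        for b in dropped:
            log.warning("band %s (%.0f-%.0f Hz) above Nyquist %.0f Hz; dropped",
                        b.name, b.low_hz, b.high_hz, fs / 2.0)
        kept = [b for b in kept if b.high_hz <= fs / 2.0]
    if not kept:
        raise ValueError("no band below Nyquist; empty scale grid")
    if n_scales_per_band < 1:
        raise ValueError("n_scales_per_band must be >= 1")

    wavelet = _morlet_wavelet()
    x = sig.samples[: n_win * win_len]
    feats = np.empty((n_win, len(kept)))
    for col, band in enumerate(kept):
        _, scales = band_scale_grid(band, fs, n_scales_per_band)
        coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs, method="fft")
        mag = np.abs(coef)                         # (n_scales, n_samples)
        mag = mag.reshape(len(scales), n_win, win_len)
        feats[:, col] = mag.mean(axis=(0, 2))
    times = np.arange(n_win) * window_s
    return FeatureMatrix(feats, window_s, [b.name for b in kept], times)


def append_rate_of_change(f: FeatureMatrix) -> FeatureMatrix:
    """Append first-difference columns ``dc_t = c_t - c_{t-1}`` (first row 0).

    Doubles the feature dimension; raises if rate-of-change columns are
    already present.
    """
    if any(lbl.startswith(ROC_PREFIX) for lbl in f.band_labels):
        raise ValueError("rate-of-change columns already present")
    dc = np.zeros_like(f.x)
    if f.T > 1:
        dc[1:] = np.diff(f.x, axis=0)
    labels = f.band_labels + [ROC_PREFIX + lbl for lbl in f.band_labels]
    return FeatureMatrix(np.hstack([f.x, dc]), f.window_s, labels, f.times_s)
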