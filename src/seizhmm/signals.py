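"""Single-channel electrophysiology records and preprocessing.

A :class:`SignalRecord` holds one channel of a local field potential (LFP)
recording together with its sampling rate and, when known, a
:class:`GroundTruth` annotation of seizure-stage intervals.  Preprocessing
removes the DC offset and mains interference (60 Hz and harmonics) with a
zero-phase FIR notch cascade and rescales the trace to the dimensionless
range [-1, 1], which is the form the wavelet feature extractor expects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "GroundTruth",
    "SignalRecord",
    "notch_filter",
    "preprocess",
    "read_signal_csv",
    "write_signal_csv",
    "read_signal_edf",
]

#: Seizure-stage labels recognised throughout the package, in electrographic
#: order of a typical seizure-like event (SLE).
STAGE_LABELS = ("interictal", "early_tonic", "late_tonic", "chronic", "postictal")


@dataclass
class GroundTruth:
    """Annotated stage intervals for one recording.

    Parameters
    ----------
    stage_intervals
        ``(label, start_s, end_s)`` triples, contiguous, non-overlapping and
        time ordered, partitioning ``[0, total_duration)``.
    ecsot_s
        Electrographical chronic seizure onset time: the annotated start of
        the chronic interval, in seconds.  ``None`` for seizure-free records.
    """

    stage_intervals: list[tuple[str, float, float]]
    ecsot_s: Optional[float] = None

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, end in self.stage_intervals:
            if end <= start:
                raise ValueError(f"empty or reversed interval for {label!r}")
            if prev_end is not None and not math.isclose(start, prev_end, abs_tol=1e-9):
                raise ValueError("stage intervals must be contiguous and ordered")
            prev_end = end
        chronic = [iv for iv in self.stage_intervals if iv[0] == "chronic"]
        if chronic and self.ecsot_s is None:
            self.ecsot_s = chronic[0][1]
        if chronic and not math.isclose(self.ecsot_s, chronic[0][1], abs_tol=1e-9):
            raise ValueError("ecsot_s must equal the start of the chronic interval")

    @property
    def total_duration_s(self) -> float:
        return self.stage_intervals[-1][2] if self.stage_intervals else 0.0

    def chronic_interval(self) -> Optional[tuple[float, float]]:
        """(start, end) of the first chronic interval, or ``None``."""
        for label, start, end in self.stage_intervals:
            if label == "chronic":
                return (start, end)
        return None

    def label_at(self, t_s: float) -> Optional[str]:
        for label, start, end in self.stage_intervals:
            if start <= t_s < end:
                return label
        return None

    def to_dict(self) -> dict:
        return {
            "stage_intervals": [list(iv) for iv in self.stage_intervals],
            "ecsot_s": self.ecsot_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            stage_intervals=[(str(l), float(a), float(b)) for l, a, b in d["stage_intervals"]],
            ecsot_s=None if d.get("ecsot_s") is None else float(d["ecsot_s"]),
        )


@dataclass
class SignalRecord:
    """One channel of an electrophysiology recording.

    ``samples`` are in arbitrary units until :func:`preprocess` rescales them
    to [-1, 1] and sets ``preprocessed``.
    """

    samples: np.ndarray
    fs_hz: float
    preprocessed: bool = False
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


def _notch_kernel(fs_hz: float, notch_hz: Sequence[float], half_width_hz: float = 1.5,
                  transition_hz: float = 1.5) -> np.ndarray:
    """Linear-phase FIR kernel with zero gain at each notch frequency."""
    numtaps = 2 * int(round(0.5 * fs_hz)) + 1  # ~1 s kernel -> ~1 Hz resolution
    nyq = fs_hz / 2.0
    pts: list[tuple[float, float]] = [(0.0, 1.0)]
    for f0 in notch_hz:
        lo, hi = f0 - half_width_hz, f0 + half_width_hz
        pts += [(lo - transition_hz, 1.0), (lo, 0.0), (hi, 0.0), (hi + transition_hz, 1.0)]
    pts.append((nyq, 1.0))
    freqs = [max(0.0, min(nyq, f)) for f, _ in pts]
    gains = [g for _, g in pts]
    # firwin2 requires strictly increasing interior frequencies
    freqs, gains = zip(*sorted(zip(freqs, gains)))
    f_arr, g_arr = [freqs[0]], [gains[0]]
    for f, g in zip(freqs[1:], gains[1:]):
        if f <= f_arr[-1]:
            f = f_arr[-1] + 1e-6
        f_arr.append(f)
        g_arr.append(g)
    f_arr[-1] = nyq
    return sps.firwin2(numtaps, f_arr, g_arr, fs=fs_hz)


def notch_filter(x: np.ndarray, fs_hz: float, mains_hz: float = 60.0) -> np.ndarray:
    """Zero-phase FIR notch of the mains frequency and harmonics below Nyquist."""
    harmonics = [h * mains_hz for h in range(1, int(fs_hz / 2 / mains_hz) + 1)
                 if h * mains_hz < fs_hz / 2 - 5.0]
    if not harmonics:
        return np.asarray(x, dtype=float)
    kernel = _notch_kernel(fs_hz, harmonics)
    # symmetric (linear-phase) kernel + centered convolution = zero phase
    return sps.fftconvolve(x, kernel, mode="same")


def preprocess(raw: SignalRecord, mains_hz: float = 60.0) -> SignalRecord:
    """Remove DC and mains interference, then normalize amplitude to [-1, 1].

    The mean is subtracted, a zero-phase FIR notch removes ``mains_hz`` and
    every harmonic below Nyquist, and the trace is rescaled so that
    ``max |sample| = 1``.  Raises for signals shorter than 2 s, sampled below
    800 Hz, or constant (zero range cannot be normalized).
    """
    if raw.duration_s < 2.0:
        raise ValueError("signal too short: need at least 2 s for preprocessing")
    if raw.fs_hz < 800.0:
        raise ValueError("sampling rate below 800 Hz is not supported")
    x = raw.samples - raw.samples.mean()
    if np.max(np.abs(x)) == 0.0:
        raise ValueError("constant signal: zero range cannot be normalized")
    x = notch_filter(x, raw.fs_hz, mains_hz)
    x = x - x.mean()
    peak = np.max(np.abs(x))
    if peak == 0.0:
        raise ValueError("signal vanished after filtering; cannot normalize")
    x = x / peak
    return SignalRecord(x, raw.fs_hz, preprocessed=True, ground_truth=raw.ground_truth)


def read_signal_csv(path: str | Path, fs_hz: Optional[float] = None) -> SignalRecord:
    """Read a two-column (time_s, amplitude) CSV; fs inferred from time stamps."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: time_s, amplitude")
    t = df.iloc[:, 0].to_numpy(float)
    x = df.iloc[:, 1].to_numpy(float)
    if fs_hz is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ValueError("time column must be increasing")
        fs_hz = 1.0 / dt
    return SignalRecord(x, fs_hz)


def write_signal_csv(sig: SignalRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": sig.times_s, "amplitude": sig.samples}).to_csv(path, index=False)


def read_signal_edf(path: str | Path, channel: int | str = 0) -> SignalRecord:
    """Read one channel from an EDF file (requires the optional ``mne`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires mne; install seizhmm[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, str):
        idx = raw.ch_names.index(channel)
    else:
        idx = int(channel)
    data = raw.get_data(picks=[idx])[0]
    return SignalRecord(data, float(raw.info["sfreq"]))
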