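"""Detection statistics: sensitivity, specificity, delay and optimality.

An event is *detected* (TP) when any chronic-labelled window starts within
30 s after the annotated chronic onset (EcSOT).  Specificity (TN) is the
per-window fraction of non-chronic labels among windows ending at least
30 s before any EcSOT (seizure-free recordings contribute all windows).
The approximated onset (AcSOT) is the first chronic label inside a 1-min
horizon centered on the EcSOT; the delay is ``dT = EcSOT - AcSOT`` (positive
= early detection).  The optimality index combines the three:

    O = (TP + TN)/2 * (1 - min(|dT|, d)/d)

with ``d`` the chronic duration of the event; a missed event has delay
factor 0.  O lies in [0, 1]; larger is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signals import GroundTruth

__all__ = [
    "LabeledTrace",
    "EventScore",
    "DetectionReport",
    "sensitivity",
    "specificity",
    "detection_delay",
    "optimality_index",
    "evaluate",
]

DETECTION_HORIZON_S = 30.0  # half-width of the onset detection horizon


@dataclass
class LabeledTrace:
    """Per-window stage labels at window start times."""

    times_s: np.ndarray
    labels: np.ndarray
    window_s: float = 1.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.times_s.size != self.labels.size:
            raise ValueError("times and labels must have the same length")

    @property
    def chronic_mask(self) -> np.ndarray:
        return self.labels == "chronic"


@dataclass
class EventScore:
    event_id: int
    tp: int
    ecsot_s: float
    acsot_s: Optional[float]
    delta_t_s: Optional[float]
    chronic_duration_s: float
    o_index: float = float("nan")


@dataclass
class DetectionReport:
    per_event: list[EventScore]
    tp_percent: float
    tn_percent: float
    mean_delta_t_s: Optional[float]
    mean_o: float

    def to_dict(self) -> dict:
        return {
            "tp_percent": self.tp_percent,
            "tn_percent": self.tn_percent,
            "mean_delta_t_s": self.mean_delta_t_s,
            "mean_o": self.mean_o,
            "per_event": [vars(e) for e in self.per_event],
        }


def sensitivity(trace: LabeledTrace, events: Sequence[float],
                horizon_s: float = DETECTION_HORIZON_S) -> float:
    """Percent of events with a chronic label within ``horizon_s`` after onset."""
    if not len(events):
        raise ValueError("no events to score")
    chronic_times = trace.times_s[trace.chronic_mask]
    detected = 0
    for ecsot in events:
        hit = (chronic_times >= ecsot - 1e-9) & (chronic_times <= ecsot + horizon_s + 1e-9)
        detected += int(hit.any())
    return 100.0 * detected / len(events)


def _specificity_counts(trace: LabeledTrace, events: Sequence[float],
                        horizon_s: float = DETECTION_HORIZON_S) -> tuple[int, int]:
    """(non-chronic windows, qualifying windows) ending >= 30 s before any onset."""
    ends = trace.times_s + trace.window_s
    if len(events):
        qualify = np.ones(trace.times_s.size, dtype=bool)
        for ecsot in events:
            qualify &= ends <= ecsot - horizon_s + 1e-9
    else:  # seizure-free recording: every window qualifies
        qualify = np.ones(trace.times_s.size, dtype=bool)
    n_qual = int(qualify.sum())
    n_correct = int((qualify & ~trace.chronic_mask).sum())
    return n_correct, n_qual


def specificity(trace: LabeledTrace, events: Sequence[float],
                horizon_s: float = DETECTION_HORIZON_S) -> float:
    """Percent of qualifying pre-ictal / non-ictal windows not labelled chronic."""
    n_correct, n_qual = _specificity_counts(trace, events, horizon_s)
    if n_qual == 0:
        raise ValueError("no windows end 30 s or more before an onset")
    return 100.0 * n_correct / n_qual


def detection_delay(trace: LabeledTrace, ecsot_s: float,
                    horizon_s: float = DETECTION_HORIZON_S) -> Optional[float]:
    """Delay dT = EcSOT - AcSOT within the +-30 s horizon; None if missed.

    AcSOT is the first chronic-labelled window start inside
    ``[EcSOT - horizon, EcSOT + horizon]``.  A horizon truncated by the
    recording edge is evaluated on the available part with a warning.
    """
    lo, hi = ecsot_s - horizon_s, ecsot_s + horizon_s
    if trace.times_s[0] > lo + 1e-9 or trace.times_s[-1] + trace.window_s < hi - 1e-9:
        warnings.warn("detection horizon truncated by recording edge", stacklevel=2)
    in_h = (trace.times_s >= lo - 1e-9) & (trace.times_s <= hi + 1e-9) & trace.chronic_mask
    if not in_h.any():
        return None
    acsot = float(trace.times_s[in_h][0])
    return ecsot_s - acsot


def optimality_index(tp_frac: float, tn_frac: float,
                     delta_t_s: Optional[float], d_s: float) -> float:
    """O = mean(TP, TN) * delay penalty; in [0, 1], larger is better.

    ``d_s`` is the chronic duration; a missed detection (``delta_t_s`` None)
    zeroes the delay factor.
    """
    if d_s <= 0:
        raise ValueError("chronic duration d must be positive")
    if not (0 <= tp_frac <= 1 and 0 <= tn_frac <= 1):
        raise ValueError("tp_frac and tn_frac must lie in [0, 1]")
    if delta_t_s is None:
        penalty = 0.0
    else:
        penalty = 1.0 - min(abs(delta_t_s), d_s) / d_s
    return 0.5 * (tp_frac + tn_frac) * penalty


def evaluate(traces: Sequence[LabeledTrace], truths: Sequence[GroundTruth],
             horizon_s: float = DETECTION_HORIZON_S) -> DetectionReport:
    """Score decoded traces against annotations; one event per seizure record.

    Sensitivity pools events across records, specificity pools qualifying
    windows; each event's optimality index uses the pooled TP/TN fractions
    with its own delay and chronic duration, and the aggregate O is the mean
    over events.
    """
    if len(traces) != len(truths):
        raise ValueError("need one ground truth per trace")

    n_detected = 0
    n_events = 0
    n_correct = 0
    n_qual = 0
    raw: list[tuple[int, float, bool, Optional[float], float]] = []
    for i, (trace, gt) in enumerate(zip(traces, truths)):
        events = [gt.ecsot_s] if gt.ecsot_s is not None else []
        c, q = _specificity_counts(trace, events, horizon_s)
        n_correct += c
        n_qual += q
        for ecsot in events:
            n_events += 1
            chronic_times = trace.times_s[trace.chronic_mask]
            hit = ((chronic_times >= ecsot - 1e-9)
                   & (chronic_times <= ecsot + horizon_s + 1e-9)).any()
            n_detected += int(hit)
            dt = detection_delay(trace, ecsot, horizon_s)
            iv = gt.chronic_interval()
            d = (iv[1] - iv[0]) if iv else float("nan")
            raw.append((i, ecsot, bool(hit), dt, d))
    if n_events == 0:
        raise ValueError("no annotated events to evaluate")
    if n_qual == 0:
        raise ValueError("no qualifying pre-ictal windows for specificity")

    tp_frac = n_detected / n_events
    tn_frac = n_correct / n_qual
    per_event = []
    for eid, ecsot, hit, dt, d in raw:
        acsot = None if dt is None else ecsot - dt
        o = optimality_index(tp_frac, tn_frac, dt, d)
        per_event.append(EventScore(eid, int(hit), ecsot, acsot, dt, d, o))
    delays = [e.delta_t_s for e in per_event if e.delta_t_s is not None]
    return DetectionReport(
        per_event=per_event,
        tp_percent=100.0 * tp_frac,
        tn_percent=100.0 * tn_frac,
        mean_delta_t_s=float(np.mean(delays)) if delays else None,
        mean_o=float(np.mean([e.o_index for e in per_event])),
    )
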