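"""Accuracy and Wolpaw information-transfer rate (ITR).

Accuracy is the percentage of correct selections among all selections issued,
corrective UNDO selections included.  Throughput uses Wolpaw's
bits-per-selection formula for an N-target interface,

    B = log2(N) + P*log2(P) + (1 - P)*log2((1 - P)/(N - 1)),

multiplied by selections per minute of *active stimulation time* (gaze-shift
and cue pauses excluded — the per-selection latencies reported by the online
decoder are exactly this clock).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ItrInput", "accuracy", "accuracy_from_counts", "wolpaw_bits",
           "itr_bits_per_min"]


@dataclass(frozen=True)
class ItrInput:
    """Inputs of the ITR computation for one run."""

    P: float
    N: int
    selections: int
    active_seconds: float


def accuracy_from_counts(n_correct: int, n_total: int) -> float:
    """Accuracy percentage; undefined (error) for zero selections."""
    if n_total <= 0:
        raise ValueError("accuracy undefined for zero selections")
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    return 100.0 * n_correct / n_total


def accuracy(events: Iterable) -> float:
    """Accuracy percentage over selection events (timeouts are not selections)."""
    sel = [e for e in events if getattr(e, "predicted", None) is not None]
    correct = sum(1 for e in sel if e.predicted == e.true_class)
    return accuracy_from_counts(correct, len(sel))


def wolpaw_bits(P: float, N: int = 4) -> float:
    """Wolpaw bits per selection; P*log2(P) -> 0 at the P -> 0 limit."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    bits = float(np.log2(N))
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1.0 - P) * np.log2((1.0 - P) / (N - 1))
    return float(bits)


def itr_bits_per_min(inp: ItrInput) -> float:
    """Wolpaw bits per selection times selections per minute of active time."""
    if inp.active_seconds <= 0:
        raise ValueError("active_seconds must be positive")
    return wolpaw_bits(inp.P, inp.N) * inp.selections * 60.0 / inp.active_seconds
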