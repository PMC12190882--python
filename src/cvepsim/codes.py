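"""m-sequence stimulus codes for cVEP stimulation.

A code-modulated VEP speller drives every selectable target with the same
pseudorandom binary flicker sequence, each target using a circularly shifted
copy.  The sequence is a maximal-length sequence (m-sequence) produced by a
linear-feedback shift register (LFSR): for register length ``r`` its period is
``2**r - 1`` and its periodic autocorrelation in +/-1 coding is two-valued
(``2**r - 1`` at lag zero, ``-1`` everywhere else), which makes time-shifted
copies of the code nearly orthogonal and therefore separable by a
correlation-based classifier.

The defaults reproduce a four-target speller: a 63-bit m-sequence (``r = 6``)
presented at 60 bits/s (1.05 s per cycle), with the four class codes obtained
by circular shifts of 0, 4, 8 and 12 bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StimulusCode",
    "SampleTimeline",
    "generate_m_sequence",
    "class_code",
    "code_to_timeline",
    "periodic_autocorrelation",
    "DEFAULT_TAPS",
    "DEFAULT_BIT_RATE",
]

#: Feedback polynomial x^6 + x^5 + 1 (primitive over GF(2)); the register
#: length and taps are configurable because any primitive polynomial of the
#: right degree yields a sequence with identical correlation properties.
DEFAULT_TAPS: tuple[int, ...] = (6, 5)

#: 63 bits per 1.05 s cycle = 60 bits/s (4 frames per bit on a 240 Hz monitor).
DEFAULT_BIT_RATE: float = 60.0


@dataclass(frozen=True)
class StimulusCode:
    """A binary stimulus code (0 = black, 1 = white) with presentation rate.

    ``class_index`` is 1-based; class ``k`` is the base code circularly
    shifted by ``(k - 1) * shift_step`` bits toward later positions.
    """

    bits: tuple[int, ...]
    bit_rate: float = DEFAULT_BIT_RATE
    class_index: int = 1
    shift_step: int = 4
    n_classes: int = 4
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("code bits must be 0 or 1")
        if self.bit_rate <= 0:
            raise ValueError("bit_rate must be positive")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def cycle_duration(self) -> float:
        """Duration of one code cycle in seconds."""
        return len(self.bits) / self.bit_rate

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.int8)

    def as_pm1(self) -> np.ndarray:
        """Bits in +/-1 coding (0 -> -1, 1 -> +1), used for correlations."""
        return self.as_array().astype(np.float64) * 2.0 - 1.0

    # -- plain-text / JSON round-tripping -----------------------------------

    def to_text(self) -> str:
        """One 0/1 character per bit."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_text(cls, text: str, **kwargs) -> "StimulusCode":
        stripped = text.strip()
        if not stripped or set(stripped) - {"0", "1"}:
            raise ValueError("text code must be a nonempty string of 0/1 characters")
        return cls(bits=tuple(int(c) for c in stripped), **kwargs)

    def to_json(self) -> str:
        payload = {
            "bits": self.to_text(),
            "bit_rate": self.bit_rate,
            "class_index": self.class_index,
            "shift_step": self.shift_step,
            "n_classes": self.n_classes,
            "meta": self.meta,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusCode":
        payload = json.loads(text)
        return cls.from_text(
            payload["bits"],
            bit_rate=payload["bit_rate"],
            class_index=payload.get("class_index", 1),
            shift_step=payload.get("shift_step", 4),
            n_classes=payload.get("n_classes", 4),
            meta=payload.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "StimulusCode":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class SampleTimeline:
    """A 0/1 stimulus timeline sampled at ``fs`` Hz.

    Each code bit spans ``fs / bit_rate`` consecutive samples and the code is
    repeated for ``n_cycles`` cycles, so the timeline is piecewise constant.
    """

    values: np.ndarray
    fs: float
    n_cycles: int
    cycle_duration: float

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_duration * self.fs))

    def __len__(self) -> int:
        return len(self.values)

    def as_pm1(self) -> np.ndarray:
        return self.values.astype(np.float64) * 2.0 - 1.0


def _lfsr_states(register_length: int, taps: Sequence[int], state: tuple[int, ...]):
    """Iterate Fibonacci-LFSR (output, next_state) pairs indefinitely."""
    taps = tuple(taps)
    while True:
        out = state[-1]
        feedback = 0
        for t in taps:
            feedback ^= state[t - 1]
        state = (feedback,) + state[:-1]
        yield out, state


def generate_m_sequence(
    register_length: int = 6,
    taps: Iterable[int] = DEFAULT_TAPS,
    initial_state: Sequence[int] | None = None,
    bit_rate: float = DEFAULT_BIT_RATE,
) -> StimulusCode:
    """Generate a maximal-length binary sequence from an LFSR.

    Parameters
    ----------
    register_length:
        Shift-register length ``r``; the sequence period is ``2**r - 1``.
    taps:
        1-based feedback tap positions, i.e. the exponents of the feedback
        polynomial (``(6, 5)`` encodes ``x**6 + x**5 + 1``).  The taps must
        define a primitive polynomial; otherwise the achieved period is
        shorter than ``2**r - 1`` and an error naming that period is raised.
    initial_state:
        Nonzero start state (any nonzero state yields a rotation of the same
        sequence).  Defaults to all ones.

    Returns
    -------
    StimulusCode
        The base code ``c1`` of one full period.
    """
    if register_length < 2:
        raise ValueError("register_length must be >= 2")
    taps = tuple(sorted(set(int(t) for t in taps), reverse=True))
    if not taps or max(taps) > register_length or min(taps) < 1:
        raise ValueError("taps must be 1-based positions within the register")
    if initial_state is None:
        initial_state = (1,) * register_length
    state = tuple(int(b) for b in initial_state)
    if len(state) != register_length or any(b not in (0, 1) for b in state):
        raise ValueError("initial_state must be a bit vector of register length")
    if not any(state):
        raise ValueError("initial_state must not be all zeros")

    period_target = 2**register_length - 1
    bits = []
    gen = _lfsr_states(register_length, taps, state)
    seen = state
    for i in range(period_target):
        out, seen = next(gen)
        bits.append(out)
        if seen == state and i + 1 < period_target:
            raise ValueError(
                f"taps {taps} are not primitive: achieved period {i + 1} "
                f"< {period_target}"
            )
    if seen != state:  # pragma: no cover - defensive; cannot happen for an LFSR
        raise ValueError(f"taps {taps} did not return to the initial state")
    return StimulusCode(
        bits=tuple(bits),
        bit_rate=bit_rate,
        class_index=1,
        meta={"register_length": register_length, "taps": list(taps),
              "initial_state": list(state)},
    )


def class_code(base: StimulusCode, k: int, shift_step: int | None = None) -> StimulusCode:
    """Code for target class ``k``: the base code shifted by ``(k-1)*shift_step`` bits.

    A positive shift rotates the sequence toward later positions: element ``i``
    of the base appears at position ``(i + shift) % len`` of the class code.
    """
    step = base.shift_step if shift_step is None else shift_step
    if not 1 <= k <= base.n_classes:
        raise ValueError(f"class index k={k} outside 1..{base.n_classes}")
    shift = (k - 1) * step
    rolled = tuple(np.roll(base.as_array(), shift).tolist())
    return replace(base, bits=rolled, class_index=k, shift_step=step)


def code_to_timeline(code: StimulusCode, fs: float = 600.0, n_cycles: int = 1) -> SampleTimeline:
    """Expand a code into a sample-rate 0/1 timeline.

    ``fs`` must be an integer multiple of the bit rate so that every bit spans
    an integer number of samples (600 Hz / 60 bits/s = 10 samples per bit at
    the defaults); no resampling is performed.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    ratio = fs / code.bit_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs={fs} is not divisible by bit_rate={code.bit_rate}; "
            "refusing to resample"
        )
    reps = int(round(ratio))
    one_cycle = np.repeat(code.as_array(), reps)
    values = np.tile(one_cycle, n_cycles)
    return SampleTimeline(
        values=values, fs=fs, n_cycles=n_cycles, cycle_duration=code.cycle_duration
    )


def periodic_autocorrelation(code: StimulusCode) -> np.ndarray:
    """Periodic autocorrelation of the code in +/-1 coding, one value per lag.

    For an m-sequence this is two-valued: ``len(code)`` at lag 0 and ``-1`` at
    every other lag.
    """
    x = code.as_pm1()
    n = len(x)
    return np.array([np.dot(x, np.roll(x, lag)) for lag in range(n)])
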