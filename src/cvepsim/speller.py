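"""Three-step four-target copy-speller with an UNDO target.

The speller shows four boxes: three hold letter groups and the fourth is
UNDO.  A character is entered by three consecutive selections — group,
subgroup, letter — so error-free copy-spelling of a word of length L takes
``3 * L`` selections.  A wrong selection is recovered by selecting UNDO
(which reverts the interface one step), so each error costs two extra
selections: the error itself and its corrective UNDO.  An erroneous UNDO
likewise reverts one completed step, which then has to be redone.

Accuracy counts corrective UNDO selections in both numerator (when they hit
UNDO as intended) and denominator.  A run is abandoned — and flagged
non-functional — when the decoder times out repeatedly, when the selection
count explodes, or when the active-stimulation budget runs out; a run with
zero correct selections is non-functional as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cvepsim.cca import TrainedModel
from cvepsim.decoder import DecoderConfig, SelectionEvent, run_selection
from cvepsim.metrics import ItrInput, itr_bits_per_min
from cvepsim.synth import SubjectModel

__all__ = [
    "SpellerLayout",
    "RunPolicy",
    "RunResult",
    "default_layout",
    "plan_required_selections",
    "run_copy_spelling",
]

UNDO = 4


@dataclass(frozen=True)
class SpellerLayout:
    """Recursive 3-way partition of the alphabet over three selection steps.

    ``groups[a][b]`` is the string of symbols reached after selecting group
    ``a + 1`` then subgroup ``b + 1``; the third selection picks the symbol's
    position within it.  Target 4 is always UNDO.
    """

    alphabet: str
    groups: tuple[tuple[str, str, str], ...]
    undo_index: int = UNDO

    def path(self, symbol: str) -> tuple[int, int, int]:
        """The three 1-based targets selecting ``symbol``."""
        if symbol not in self.alphabet:
            raise ValueError(f"symbol {symbol!r} not in speller alphabet")
        for a, group in enumerate(self.groups):
            for b, sub in enumerate(group):
                if symbol in sub:
                    return (a + 1, b + 1, sub.index(symbol) + 1)
        raise ValueError(f"symbol {symbol!r} unreachable in layout")  # pragma: no cover


def default_layout(alphabet: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZ_") -> SpellerLayout:
    """27 symbols split 9/9/9, each group split 3/3/3, then singletons."""
    if len(alphabet) != 27 or len(set(alphabet)) != 27:
        raise ValueError("default layout needs 27 distinct symbols")
    groups = tuple(
        tuple(alphabet[a * 9 + b * 3 : a * 9 + (b + 1) * 3] for b in range(3))
        for a in range(3)
    )
    return SpellerLayout(alphabet=alphabet, groups=groups)


def plan_required_selections(word: str, layout: SpellerLayout) -> list[int]:
    """Target sequence for error-free spelling: three selections per symbol."""
    plan: list[int] = []
    for symbol in word:
        plan.extend(layout.path(symbol))
    return plan


@dataclass(frozen=True)
class RunPolicy:
    """When to give up on a copy-spelling run.

    ``max_consecutive_timeouts`` mirrors stopping a round early after several
    fruitless attempts; the selection and active-time budgets bound runs whose
    selections are effectively random.
    """

    max_consecutive_timeouts: int = 3
    selection_budget_factor: float = 6.0
    max_active_seconds: float = 600.0


@dataclass
class RunResult:
    """Outcome of one copy-spelling run (one word, one condition)."""

    word: str
    events: list[SelectionEvent]
    n_selections: int
    n_correct: int
    n_timeouts: int
    active_seconds: float
    wall_seconds: float
    completed: bool
    abandoned: bool
    accuracy: float | None
    itr: float | None
    functional: bool
    subject_id: int | None = None
    condition: str | None = None


def run_copy_spelling(
    subject: SubjectModel,
    word: str,
    model: TrainedModel,
    cfg: DecoderConfig,
    layout: SpellerLayout | None = None,
    rng: np.random.Generator | int | None = None,
    noise_scale: float = 1.0,
    policy: RunPolicy = RunPolicy(),
) -> RunResult:
    """Copy-spell ``word`` through the closed-loop decoder.

    Walks the error-free plan; every wrong selection queues one corrective
    UNDO before the plan resumes, and an erroneous UNDO reverts one completed
    plan step.  Accuracy and ITR follow the metrics module; the information
    clock counts active stimulation time only (selection and timeout
    latencies, no gaze-shift pauses).
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(rng)
    plan = plan_required_selections(word, layout)
    budget = int(np.ceil(policy.selection_budget_factor * max(len(plan), 1)))

    events: list[SelectionEvent] = []
    pos = 0
    pending_undo = 0
    n_correct = n_sel = n_timeouts = 0
    active = wall = 0.0
    consecutive_timeouts = 0
    abandoned = False

    while pos < len(plan) or pending_undo:
        true_target = layout.undo_index if pending_undo else plan[pos]
        ev = run_selection(subject, true_target, model, cfg, rng, noise_scale)
        events.append(ev)
        active += ev.latency
        wall += ev.latency
        if ev.timed_out:
            n_timeouts += 1
            consecutive_timeouts += 1
            if consecutive_timeouts >= policy.max_consecutive_timeouts:
                abandoned = True
                break
            continue
        consecutive_timeouts = 0
        wall += cfg.gaze_shift_seconds
        n_sel += 1
        if ev.predicted == true_target:
            n_correct += 1
            if pending_undo:
                pending_undo -= 1
            else:
                pos += 1
        elif ev.predicted == layout.undo_index:
            # erroneous UNDO: the interface reverts one completed step
            if pending_undo:
                pending_undo += 1
            elif pos > 0:
                pos -= 1
        else:
            pending_undo += 1
        if n_sel >= budget or active > policy.max_active_seconds:
            abandoned = True
            break

    completed = pos >= len(plan) and not pending_undo and not abandoned
    acc = 100.0 * n_correct / n_sel if n_sel else None
    itr = None
    if n_sel and active > 0 and acc is not None and n_correct > 0:
        itr = itr_bits_per_min(
            ItrInput(P=n_correct / n_sel, N=model.n_classes,
                     selections=n_sel, active_seconds=active)
        )
    functional = (not abandoned) and n_correct > 0
    return RunResult(
        word=word, events=events, n_selections=n_sel, n_correct=n_correct,
        n_timeouts=n_timeouts, active_seconds=active, wall_seconds=wall,
        completed=completed, abandoned=abandoned, accuracy=acc, itr=itr,
        functional=functional,
    )
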