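"""Online cVEP selection loop: buffering, correlation, certainty margin.

EEG arrives in 30-sample blocks (0.05 s at 600 Hz) and is appended to a
buffer ``Y``.  Once at least one full code cycle is buffered, every new block
triggers an evaluation: for each class ``i`` the spatially filtered buffer
``w_x_i' Y`` is correlated with the correspondingly filtered segment ``R_i``
of that class's periodic template, aligned to the buffer's code phase (minus
the calibration lag), giving correlations ``lambda_i``.  The certainty margin
is the gap between the largest and second-largest correlation, and a
selection is issued only when it strictly exceeds the threshold ``beta``.
After a selection the buffer is cleared and a gaze-shift pause follows; a
trial that never crosses the threshold times out.

When the buffer reaches its capacity (two code cycles) it slides: the oldest
block is dropped and the buffer's code phase advances accordingly, so
evaluation always uses the most recent data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from cvepsim.cca import TrainedModel
from cvepsim.codes import SampleTimeline
from cvepsim.synth import SubjectModel, simulate_epoch

__all__ = [
    "DecoderConfig",
    "DecoderState",
    "Evaluation",
    "SelectionEvent",
    "push_block",
    "evaluate",
    "maybe_select",
    "decode_stream",
    "run_selection",
    "stream_from_subject",
    "export_trace_csv",
]


@dataclass(frozen=True)
class DecoderConfig:
    """Online decoding parameters.

    ``beta`` is the certainty-margin threshold (0.15 by default, sensible
    between roughly 0.10 and 0.30); ``min_eval_samples`` defaults to one code
    cycle and gates the first evaluation; ``capacity`` is the buffer length
    (two code cycles), after which the buffer slides block-wise.
    """

    beta: float = 0.15
    block_size: int = 30
    fs: float = 600.0
    min_eval_samples: int = 630
    capacity: int = 1260
    max_trial_seconds: float = 10.0
    gaze_shift_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.capacity % self.block_size:
            raise ValueError("capacity must be a multiple of block_size")

    @property
    def block_seconds(self) -> float:
        return self.block_size / self.fs


@dataclass
class DecoderState:
    """Block-wise EEG buffer with its stimulus code phase."""

    buffer: np.ndarray
    n_y: int
    code_phase: int
    elapsed: float
    block_size: int
    cycle_len: int
    fs: float = 600.0

    @classmethod
    def empty(cls, n_channels: int, cfg: DecoderConfig, cycle_len: int) -> "DecoderState":
        return cls(
            buffer=np.zeros((n_channels, cfg.capacity)),
            n_y=0, code_phase=0, elapsed=0.0,
            block_size=cfg.block_size, cycle_len=cycle_len, fs=cfg.fs,
        )

    def reset(self) -> None:
        """Clear the buffer after a selection (code phase keeps running)."""
        self.n_y = 0

    @property
    def data(self) -> np.ndarray:
        return self.buffer[:, : self.n_y]


@dataclass
class Evaluation:
    """Per-class correlations, their argmax and the certainty margin."""

    lambdas: np.ndarray
    margin: float
    best: int


@dataclass
class SelectionEvent:
    """Outcome of one closed-loop selection attempt.

    ``latency`` is seconds of stimulation consumed (evaluation-gated, hence at
    least one code cycle for any non-timeout selection); gaze-shift and cue
    pauses are accounted separately by the caller.
    """

    predicted: int | None
    true_class: int | None
    latency: float
    timed_out: bool
    margin: float = 0.0
    lambdas: np.ndarray | None = None


def push_block(state: DecoderState, block: np.ndarray) -> DecoderState:
    """Append one 30-sample block; slide the buffer when at capacity."""
    block = np.asarray(block, dtype=float)
    if block.shape != (state.buffer.shape[0], state.block_size):
        raise ValueError(
            f"block must be {state.buffer.shape[0]} x {state.block_size}, "
            f"got {block.shape}"
        )
    cap = state.buffer.shape[1]
    bs = state.block_size
    if state.n_y + bs > cap:
        state.buffer[:, : cap - bs] = state.buffer[:, bs:]
        state.n_y = cap - bs
        state.code_phase = (state.code_phase + bs) % state.cycle_len
    state.buffer[:, state.n_y : state.n_y + bs] = block
    state.n_y += bs
    state.elapsed += bs / state.fs
    return state


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny_ = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny_ == 0:
        return 0.0
    return float(xc @ yc / (nx * ny_))


def evaluate(
    state: DecoderState,
    model: TrainedModel,
    min_eval_samples: int = 630,
) -> Evaluation:
    """Correlate the filtered buffer with every class's aligned template segment."""
    if state.n_y < min_eval_samples:
        raise ValueError(
            f"buffer holds {state.n_y} samples; "
            f"{min_eval_samples} required before evaluation"
        )
    if model.n_channels != state.buffer.shape[0]:
        raise ValueError("montage mismatch between filters and buffer")
    Y = state.data
    idx = (state.code_phase + np.arange(state.n_y) - model.lag) % model.cycle_len
    lambdas = np.empty(model.n_classes)
    for i, f in enumerate(model.filters):
        seg = model.code_cycles[i, idx].astype(float)
        x_proj = f.w_x @ Y
        y_proj = f.w_y.sum() * seg  # w_y' R_i with R_i's rows all equal to seg
        lambdas[i] = _pearson(x_proj, y_proj)
    order = np.sort(lambdas)[::-1]
    margin = float(order[0] - order[1]) if len(lambdas) > 1 else float(order[0])
    best = int(np.argmax(lambdas)) + 1  # ties -> lowest class index
    return Evaluation(lambdas=lambdas, margin=margin, best=best)


def maybe_select(ev: Evaluation, cfg: DecoderConfig) -> int | None:
    """The argmax class iff the certainty margin strictly exceeds ``beta``."""
    return ev.best if ev.margin > cfg.beta else None


def decode_stream(
    blocks: Iterable[np.ndarray],
    model: TrainedModel,
    cfg: DecoderConfig,
    true_class: int | None = None,
    trace: list | None = None,
) -> SelectionEvent:
    """Run the selection loop over a block stream until selection or stream end.

    ``trace``, if a list, collects one dict per evaluation (elapsed seconds,
    per-class correlations, margin, decision) for debugging or export.
    """
    state = DecoderState.empty(model.n_channels, cfg, model.cycle_len)
    last_ev: Evaluation | None = None
    for block in blocks:
        push_block(state, block)
        if state.n_y < cfg.min_eval_samples:
            continue
        ev = evaluate(state, model, cfg.min_eval_samples)
        last_ev = ev
        choice = maybe_select(ev, cfg)
        if trace is not None:
            trace.append(
                {
                    "elapsed": state.elapsed,
                    **{f"lambda_{i + 1}": float(v) for i, v in enumerate(ev.lambdas)},
                    "margin": ev.margin,
                    "decision": choice if choice is not None else "",
                }
            )
        if choice is not None:
            state.reset()
            return SelectionEvent(
                predicted=choice, true_class=true_class, latency=state.elapsed,
                timed_out=False, margin=ev.margin, lambdas=ev.lambdas.copy(),
            )
    return SelectionEvent(
        predicted=None, true_class=true_class, latency=state.elapsed,
        timed_out=True,
        margin=last_ev.margin if last_ev else 0.0,
        lambdas=last_ev.lambdas.copy() if last_ev else None,
    )


def stream_from_subject(
    subject: SubjectModel,
    target_class: int,
    model: TrainedModel,
    cfg: DecoderConfig,
    rng: np.random.Generator | int | None = None,
    noise_scale: float = 1.0,
) -> Iterator[np.ndarray]:
    """Simulated block stream of the subject attending ``target_class``."""
    cyc = model.code_cycles[target_class - 1]
    timeline = SampleTimeline(
        values=cyc, fs=model.fs, n_cycles=1, cycle_duration=len(cyc) / model.fs
    )
    epoch = simulate_epoch(
        subject, timeline, duration=cfg.max_trial_seconds, rng=rng,
        noise_scale=noise_scale,
    )
    n_blocks = epoch.n_samples // cfg.block_size
    for b in range(n_blocks):
        yield epoch.data[:, b * cfg.block_size : (b + 1) * cfg.block_size]


def run_selection(
    subject: SubjectModel,
    target_class: int,
    model: TrainedModel,
    cfg: DecoderConfig,
    rng: np.random.Generator | int | None = None,
    noise_scale: float = 1.0,
    trace: list | None = None,
) -> SelectionEvent:
    """Simulate one closed-loop selection attempt on a synthetic subject."""
    if subject.n_channels != model.n_channels:
        raise ValueError(
            f"montage mismatch: subject has {subject.n_channels} channels, "
            f"filters expect {model.n_channels}"
        )
    if not 1 <= target_class <= model.n_classes:
        raise ValueError(f"target_class {target_class} outside 1..{model.n_classes}")
    blocks = stream_from_subject(subject, target_class, model, cfg, rng, noise_scale)
    return decode_stream(blocks, model, cfg, true_class=target_class, trace=trace)


def export_trace_csv(trace: list[dict], path: str | Path) -> None:
    """Write a decode trace (per-evaluation correlations and decisions) to CSV."""
    if not trace:
        raise ValueError("empty trace")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(trace[0].keys()))
        writer.writeheader()
        writer.writerows(trace)
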