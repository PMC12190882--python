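"""CCA spatial-filter calibration for cVEP classification.

For each target class ``i`` the calibration phase averages the labeled
training trials into a class-average response ``X_bar_i`` (channels x
samples), builds the ideal binary stimulus template ``C_i`` (the class's 0/1
code timeline replicated across channels), and solves the canonical
correlation problem

    max_{w_x, w_y}  corr(w_x' X_bar_i, w_y' C_i)

for one spatial-filter pair per class.  The template's channel covariance is
rank one by construction (all rows identical), so a small ridge is added to
both auto-covariances before whitening; the ridge is scaled relative to the
mean auto-covariance diagonal, which keeps the solution invariant to the
overall scale of either signal.

Because the evoked response lags the stimulus by a neural latency the
stimulus presented, calibration also estimates a single integer-sample
template lag shared by all classes (the lag maximizing the mean squared
canonical correlation over a search grid).  The online decoder applies the
same lag when extracting template segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from cvepsim.codes import SampleTimeline
from cvepsim.montage import Montage
from cvepsim.synth import TrialSet, restrict_channels

__all__ = [
    "ClassTemplate",
    "AveragedResponse",
    "SpatialFilterPair",
    "TrainedModel",
    "average_trials",
    "build_template",
    "canonical_correlation",
    "train_classifier",
    "restrict_model",
    "save_model",
    "load_model",
]

DEFAULT_RIDGE = 1e-8


@dataclass
class ClassTemplate:
    """Ideal 0/1 stimulus template: the class code replicated across channels."""

    matrix: np.ndarray
    class_index: int


@dataclass
class AveragedResponse:
    """Element-wise mean of a class's training trials."""

    matrix: np.ndarray
    class_index: int
    nb_used: int


@dataclass
class SpatialFilterPair:
    """Unit-norm weight pair and training canonical correlation for one class."""

    w_x: np.ndarray
    w_y: np.ndarray
    rho: float
    class_index: int


@dataclass
class TrainedModel:
    """A full calibrated classifier: K filter pairs plus decoding metadata.

    ``code_cycles`` holds one 0/1 cycle of each class's sample-rate timeline;
    ``lag`` is the template alignment (in samples) estimated at calibration.
    """

    filters: list[SpatialFilterPair]
    code_cycles: np.ndarray
    fs: float
    lag: int = 0
    montage: Montage | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.filters)

    @property
    def n_channels(self) -> int:
        return len(self.filters[0].w_x)

    @property
    def cycle_len(self) -> int:
        return self.code_cycles.shape[1]


def average_trials(trials: TrialSet, class_index: int) -> AveragedResponse:
    """Element-wise mean across the trials labeled ``class_index``."""
    sel = trials.trials_for(class_index)
    if sel.shape[0] == 0:
        raise ValueError(f"no trials with label {class_index}")
    return AveragedResponse(
        matrix=sel.mean(axis=0), class_index=class_index, nb_used=sel.shape[0]
    )


def build_template(code_timeline: SampleTimeline | np.ndarray, m: int,
                   class_index: int = 1) -> ClassTemplate:
    """Stack ``m`` copies of a 0/1 timeline into a channels x samples template."""
    if m < 1:
        raise ValueError("m must be >= 1")
    values = (
        code_timeline.values
        if isinstance(code_timeline, SampleTimeline)
        else np.asarray(code_timeline)
    )
    return ClassTemplate(
        matrix=np.tile(values.astype(float), (m, 1)), class_index=class_index
    )


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=1, keepdims=True)


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = eigh(mat)
    vals = np.clip(vals, np.finfo(float).tiny, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def canonical_correlation(
    X: np.ndarray, Y: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> tuple[np.ndarray, np.ndarray, float]:
    """Leading canonical pair between two multichannel signals.

    Rows are channels, columns are (time) samples; both sides are row-centered
    before covariance computation since Pearson correlation is mean-invariant.
    ``ridge`` (relative to the mean auto-covariance diagonal) regularizes both
    auto-covariances, which is required when one side is rank-deficient — the
    stimulus template always is.

    Returns ``(w_x, w_y, rho)`` with both weight vectors unit-norm, ``rho >=
    0``, and the first nonzero entry of ``w_x`` positive.  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with the same number of samples")
    n = X.shape[1]
    if n <= max(X.shape[0], Y.shape[0]):
        raise ValueError("need more samples than channels on both sides")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    Xc, Yc = _center(X), _center(Y)
    Cxx = Xc @ Xc.T / (n - 1)
    Cyy = Yc @ Yc.T / (n - 1)
    Cxy = Xc @ Yc.T / (n - 1)
    for name, C in (("X", Cxx), ("Y", Cyy)):
        if np.trace(C) <= 0:
            raise ValueError(f"degenerate input on side {name}: zero variance "
                             "after centering")
    Cxx = Cxx + ridge * np.mean(np.diag(Cxx)) * np.eye(X.shape[0])
    Cyy = Cyy + ridge * np.mean(np.diag(Cyy)) * np.eye(Y.shape[0])
    Wx = _inv_sqrt(Cxx)
    Wy = _inv_sqrt(Cyy)
    U, s, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    w_x = Wx @ U[:, 0]
    w_y = Wy @ Vt[0]
    w_x /= np.linalg.norm(w_x)
    w_y /= np.linalg.norm(w_y)
    # sign convention: first nonzero w_x entry positive, rho realized >= 0
    nz = np.flatnonzero(np.abs(w_x) > 1e-12)
    if nz.size and w_x[nz[0]] < 0:
        w_x, w_y = -w_x, -w_y
    if float((w_x @ Xc) @ (w_y @ Yc)) < 0:
        w_y = -w_y
    return w_x, w_y, float(s[0])


def _ridge_rho2_scan(
    xbar: np.ndarray, cycle01: np.ndarray, lags: np.ndarray, ridge: float
) -> np.ndarray:
    """Squared max correlation of ``w' xbar`` with the lagged timeline, per lag.

    Fast path for the calibration lag search: the template side collapses to
    the 1-D timeline, so the maximal correlation over spatial weights is a
    ridge-regularized Rayleigh quotient solvable with one Cholesky factor.
    """
    m, n = xbar.shape
    Xc = _center(xbar)
    A = Xc @ Xc.T / (n - 1)
    A += ridge * np.mean(np.diag(A)) * np.eye(m)
    factor = cho_factor(A)
    idx = np.arange(n)
    out = np.empty(len(lags))
    for j, lag in enumerate(lags):
        y = cycle01[(idx - lag) % len(cycle01)].astype(float)
        yc = y - y.mean()
        b = Xc @ yc / (n - 1)
        var_y = yc @ yc / (n - 1)
        out[j] = float(b @ cho_solve(factor, b) / var_y)
    return out


def train_classifier(
    trials: TrialSet,
    codes: Sequence[SampleTimeline],
    ridge: float = DEFAULT_RIDGE,
    lag_search: tuple[int, int, int] | None = (0, 150, 2),
    montage: Montage | None = None,
) -> TrainedModel:
    """Calibrate one spatial-filter pair per class from labeled trials.

    ``codes`` supplies one timeline per class (class ``k`` at position
    ``k - 1``).  ``lag_search = (start, stop, step)`` controls the shared
    template-lag grid in samples (``None`` disables alignment, lag 0).
    """
    n_classes = len(codes)
    labels = set(int(v) for v in trials.labels)
    missing = sorted(set(range(1, n_classes + 1)) - labels)
    if missing:
        raise ValueError(f"missing training trials for classes {missing}")

    n = trials.data.shape[2]
    cycles = []
    for tl in codes:
        cyc = np.asarray(
            tl.values[: tl.samples_per_cycle]
            if isinstance(tl, SampleTimeline) else tl
        )
        cycles.append(cyc)
    cycles = np.stack(cycles)
    averages = [average_trials(trials, k) for k in range(1, n_classes + 1)]

    lag = 0
    if lag_search is not None:
        lags = np.arange(*lag_search)
        score = np.zeros(len(lags))
        for avg, cyc in zip(averages, cycles):
            score += _ridge_rho2_scan(avg.matrix, cyc, lags, ridge)
        lag = int(lags[np.argmax(score)])

    idx = np.arange(n)
    filters = []
    for avg, cyc in zip(averages, cycles):
        tmpl_vals = cyc[(idx - lag) % len(cyc)]
        template = build_template(tmpl_vals, trials.data.shape[1], avg.class_index)
        w_x, w_y, rho = canonical_correlation(avg.matrix, template.matrix, ridge)
        filters.append(SpatialFilterPair(w_x, w_y, rho, avg.class_index))
    return TrainedModel(
        filters=filters,
        code_cycles=cycles,
        fs=trials.fs,
        lag=lag,
        montage=montage if montage is not None else trials.montage,
        meta={"ridge": ridge, "nb": int(len(trials) // n_classes)},
    )


def restrict_model(model: TrainedModel, subset: Montage) -> TrainedModel:
    """Keep only the filter weights at a montage subset (no retraining).

    The training correlations ``rho`` are carried over unchanged; they
    describe the calibration run, not the restricted filters.
    """
    if model.montage is None:
        raise ValueError("model has no montage; cannot restrict")
    filters = [
        SpatialFilterPair(
            w_x=restrict_channels(f.w_x, subset, source=model.montage),
            w_y=restrict_channels(f.w_y, subset, source=model.montage),
            rho=f.rho,
            class_index=f.class_index,
        )
        for f in model.filters
    ]
    idx = model.montage.indices_of(subset)
    kept = Montage(tuple(np.array(model.montage.names)[idx]))
    return TrainedModel(
        filters=filters, code_cycles=model.code_cycles, fs=model.fs,
        lag=model.lag, montage=kept, meta=dict(model.meta, restricted=True),
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained filter set to JSON for reproducible decode runs."""
    payload = {
        "fs": model.fs,
        "lag": model.lag,
        "montage": list(model.montage.names) if model.montage else None,
        "code_cycles": model.code_cycles.astype(int).tolist(),
        "meta": model.meta,
        "filters": [
            {
                "class_index": f.class_index,
                "w_x": f.w_x.tolist(),
                "w_y": f.w_y.tolist(),
                "rho": f.rho,
            }
            for f in model.filters
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    filters = [
        SpatialFilterPair(
            w_x=np.array(f["w_x"]), w_y=np.array(f["w_y"]),
            rho=f["rho"], class_index=f["class_index"],
        )
        for f in payload["filters"]
    ]
    return TrainedModel(
        filters=filters,
        code_cycles=np.array(payload["code_cycles"]),
        fs=payload["fs"],
        lag=payload["lag"],
        montage=Montage(tuple(payload["montage"])) if payload["montage"] else None,
        meta=payload.get("meta", {}),
    )
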