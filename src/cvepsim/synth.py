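"""Synthetic multi-channel EEG with code-locked evoked structure.

The study this package models could not publish its raw EEG, so every
downstream stage (calibration, online decoding, the electrode-reduction
protocol) is driven by a generative stand-in for a participant:

* a **temporal response kernel** — the evoked response to a single stimulus
  bit transition, modelled as a sharp onset deflection followed by a damped
  oscillation (a VEP-like waveform), unit energy;
* a **spatial topography** — per-channel gains over the 16-electrode
  occipito-parietal montage, drawn from a spatially smooth Gaussian process
  and rescaled so that a chosen fraction (``focus``) of its squared-gain mass
  lies on the 6 electrodes that survive electrode reduction;
* a **response latency** and a **noise specification** (1/f "pink" background,
  a white component, and a narrowband alpha rhythm).

The forward model for an epoch is
``data = topography x (kernel * pm1(timeline), delayed) + noise`` where
``pm1`` maps the 0/1 flicker timeline to +/-1 so the evoked component is
zero-mean.  Noise has the same variance on every channel, calibrated per
subject so that the ratio of the **montage-average evoked variance** (the
evoked variance a channel of average squared gain carries) to the noise
variance equals ``snr_db``.  Tying the calibration to the montage average
rather than to a single electrode keeps ``snr_db`` (overall signal quality)
and ``focus`` (where on the scalp that signal sits) independent: moving
evoked energy off the retained electrodes lowers their signal but not the
noise floor.  Individual channels inherit the ratio implied by their
topography gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from cvepsim.codes import SampleTimeline
from cvepsim.montage import FULL16, REDUCED6, Montage

__all__ = [
    "NoiseSpec",
    "SubjectModel",
    "Epoch",
    "TrialSet",
    "vep_kernel",
    "sample_subject",
    "simulate_epoch",
    "simulate_training_session",
    "restrict_channels",
    "perturb_topography",
    "make_noise",
    "spatial_mixing",
    "subject_focus",
]

DEFAULT_FS = 600.0

#: Length scale (normalized scalp units) of the Gaussian process that makes
#: topographies spatially smooth.
_TOPO_LENGTH_SCALE = 0.35


@dataclass(frozen=True)
class NoiseSpec:
    """Additive background-noise mixture, variance fractions summing to <= 1.

    ``pink`` (1/f^alpha) noise takes the remaining fraction
    ``1 - white_fraction - alpha_fraction``.  The pink and alpha components
    are spatially correlated across channels (volume-conducted brain noise):
    ``spatial_corr`` is the fraction of their variance that is shared through
    a smooth scalp covariance, while the white component models uncorrelated
    sensor noise.
    """

    alpha_exponent: float = 1.0
    white_fraction: float = 0.15
    alpha_fraction: float = 0.2
    alpha_freq: float = 10.0
    alpha_bandwidth: float = 2.0
    spatial_corr: float = 0.75
    spatial_scale: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.white_fraction + self.alpha_fraction <= 1:
            raise ValueError("white_fraction + alpha_fraction must lie in [0, 1]")
        if not 0 <= self.spatial_corr <= 1:
            raise ValueError("spatial_corr must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectModel:
    """Generative parameters of one synthetic participant."""

    kernel: np.ndarray
    topography: np.ndarray
    latency: float
    noise_spec: NoiseSpec
    snr_db: float
    focus: float
    noise_sigma: float
    noise_mixing: np.ndarray | None = None
    fs: float = DEFAULT_FS
    montage: Montage = FULL16
    rng_seed: int | None = None

    @property
    def n_channels(self) -> int:
        return len(self.topography)


@dataclass
class Epoch:
    """A channels x samples recording segment.

    ``t0_code_phase`` is the sample offset into the stimulus code cycle at the
    first sample of the epoch (0 for calibration trials, which start on a code
    cycle boundary).
    """

    data: np.ndarray
    fs: float
    label: int | None = None
    t0_code_phase: int = 0
    montage: Montage = FULL16

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Labeled calibration trials: ``data`` is (n_trials, channels, samples)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    montage: Montage = FULL16

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def trials_for(self, class_index: int) -> np.ndarray:
        return self.data[self.labels == class_index]


def vep_kernel(
    fs: float = DEFAULT_FS,
    duration: float = 0.25,
    freq: float = 11.0,
    decay: float = 0.06,
    onset_sigma: float = 0.007,
    onset_weight: float = 0.75,
) -> np.ndarray:
    """VEP-like impulse response: sharp onset deflection plus damped sinusoid.

    The onset component is a narrow Gaussian bump (width ``onset_sigma``
    seconds) — the fast broadband deflection that makes flicker responses
    separable at the 63-bit code's 4-bit class shifts — and the oscillatory
    tail is a damped ``freq``-Hz sinusoid of time constant ``decay`` spanning
    ``duration`` seconds.  The result is normalized to unit energy.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    onset = np.exp(-0.5 * ((t - 2.5 * onset_sigma) / onset_sigma) ** 2)
    osc = np.sin(2 * np.pi * freq * t) * np.exp(-t / decay)
    onset /= np.linalg.norm(onset)
    osc /= np.linalg.norm(osc)
    k = onset_weight * onset + (1.0 - onset_weight) * osc
    return k / np.linalg.norm(k)


def _smooth_scalp_sample(montage: Montage, rng: np.random.Generator) -> np.ndarray:
    """Draw a spatially smooth zero-mean field over the montage."""
    xy = montage.coordinates()
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    cov = np.exp(-0.5 * d2 / _TOPO_LENGTH_SCALE**2) + 1e-9 * np.eye(len(montage))
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(montage))


def _apply_focus(topo: np.ndarray, focus: float, montage: Montage) -> np.ndarray:
    """Rescale so the squared-gain fraction on the retained subset equals ``focus``."""
    keep = montage.indices_of(REDUCED6)
    out = np.ones(len(topo), dtype=bool)
    out[keep] = False
    a, b = np.linalg.norm(topo[keep]), np.linalg.norm(topo[out])
    scaled = topo.astype(float).copy()
    scaled[keep] = 0.0 if a == 0 else topo[keep] * np.sqrt(focus) / a
    scaled[out] = 0.0 if b == 0 else topo[out] * np.sqrt(1.0 - focus) / b
    return scaled


def subject_focus(subject: SubjectModel) -> float:
    """Fraction of squared topography gain on the retained 6-electrode subset."""
    keep = subject.montage.indices_of(REDUCED6)
    total = float(np.sum(subject.topography**2))
    return float(np.sum(subject.topography[keep] ** 2) / total)


def _reference_evoked_std(kernel: np.ndarray, fs: float, latency: float) -> float:
    """Steady-state std of the kernel-filtered +/-1 code drive (unit topography).

    Computed on the package's default 63-bit m-sequence timeline so that noise
    calibration refers to the stimulation actually used.
    """
    from cvepsim.codes import code_to_timeline, generate_m_sequence

    tl = code_to_timeline(generate_m_sequence(), fs=fs, n_cycles=4)
    s = _evoked_waveform(tl.as_pm1(), kernel, int(round(latency * fs)))
    skip = len(kernel) + int(round(latency * fs))
    return float(np.std(s[skip:]))


def _evoked_waveform(drive: np.ndarray, kernel: np.ndarray, latency_samples: int) -> np.ndarray:
    s = fftconvolve(drive, kernel)[: len(drive)]
    if latency_samples > 0:
        s = np.concatenate([np.zeros(latency_samples), s[:-latency_samples]])
    return s


def sample_subject(
    seed: int | None,
    focus_target: float = 0.7,
    snr_db: float = -21.0,
    montage: Montage = FULL16,
    kernel: np.ndarray | None = None,
    noise_spec: NoiseSpec | None = None,
    latency_range: tuple[float, float] = (0.10, 0.15),
    fs: float = DEFAULT_FS,
) -> SubjectModel:
    """Draw a synthetic participant; deterministic for a fixed seed.

    ``focus_target`` in [0, 1] fixes the fraction of evoked (squared-gain)
    energy on the retained 6-electrode subset; ``snr_db`` sets the ratio of
    montage-average evoked variance to per-channel noise variance.
    """
    if not 0.0 <= focus_target <= 1.0:
        raise ValueError(f"focus_target={focus_target} outside [0, 1]")
    rng = np.random.default_rng(seed)
    if kernel is None:
        kernel = vep_kernel(fs)
    topo = _smooth_scalp_sample(montage, rng)
    topo = _apply_focus(topo, focus_target, montage)
    # sign convention: net occipital gain positive (sign is unidentifiable)
    if topo.sum() < 0:
        topo = -topo
    latency = float(rng.uniform(*latency_range))
    spec = noise_spec if noise_spec is not None else NoiseSpec()
    mixing = spatial_mixing(spec, montage)

    ref_gain2 = float(np.mean(topo**2))
    evoked_std = _reference_evoked_std(kernel, fs, latency)
    snr_lin = 10.0 ** (snr_db / 10.0)
    noise_sigma = float(np.sqrt(ref_gain2 * evoked_std**2 / snr_lin))

    return SubjectModel(
        kernel=kernel,
        topography=topo,
        latency=latency,
        noise_spec=spec,
        snr_db=snr_db,
        focus=focus_target,
        noise_sigma=noise_sigma,
        noise_mixing=mixing,
        fs=fs,
        montage=montage,
        rng_seed=seed,
    )


def spatial_mixing(spec: NoiseSpec, montage: Montage) -> np.ndarray:
    """Square-root of the cross-channel covariance of the brain-noise part.

    ``C = (1 - s) I + s K`` with ``K`` a smooth scalp kernel of length scale
    ``spatial_scale`` and ``s = spatial_corr``; unit diagonal, so mixing
    preserves per-channel variance in expectation.
    """
    xy = montage.coordinates()
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    K = np.exp(-0.5 * d2 / spec.spatial_scale**2)
    C = (1.0 - spec.spatial_corr) * np.eye(len(montage)) + spec.spatial_corr * K
    return np.linalg.cholesky(C + 1e-9 * np.eye(len(montage)))


def make_noise(
    n_samples: int,
    n_channels: int,
    spec: NoiseSpec,
    rng: np.random.Generator,
    fs: float = DEFAULT_FS,
    mixing: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-variance noise mixture per channel: pink + white + narrowband alpha.

    Components are synthesized in the frequency domain; the pink and alpha
    (brain) components are spatially mixed with ``mixing`` (rows = output
    channels) while the white (sensor) component stays independent.  Each
    channel is normalized to exactly unit variance per realization.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples of noise")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    pink_frac = 1.0 - spec.white_fraction - spec.alpha_fraction
    n_src = mixing.shape[1] if mixing is not None else n_channels

    pink_shape = np.zeros_like(freqs)
    pink_shape[1:] = freqs[1:] ** (-spec.alpha_exponent / 2.0)
    alpha_shape = np.exp(
        -0.5 * ((freqs - spec.alpha_freq) / (spec.alpha_bandwidth / 2.0)) ** 2
    )

    def _shaped(shape: np.ndarray, rows: int) -> np.ndarray:
        spectrum = shape * (
            rng.standard_normal((rows, len(freqs)))
            + 1j * rng.standard_normal((rows, len(freqs)))
        )
        x = np.fft.irfft(spectrum, n=n_samples, axis=1)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return x / sd

    brain = np.zeros((n_src, n_samples))
    if pink_frac > 0:
        brain += np.sqrt(pink_frac) * _shaped(pink_shape, n_src)
    if spec.alpha_fraction > 0:
        brain += np.sqrt(spec.alpha_fraction) * _shaped(alpha_shape, n_src)
    out = mixing @ brain if mixing is not None else brain
    if spec.white_fraction > 0:
        out = out + np.sqrt(spec.white_fraction) * _shaped(
            np.ones_like(freqs), n_channels
        )
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_epoch(
    subject: SubjectModel,
    timeline: SampleTimeline,
    duration: float | None = None,
    rng: np.random.Generator | int | None = None,
    noise_scale: float = 1.0,
    label: int | None = None,
    t0_code_phase: int = 0,
    return_parts: bool = False,
):
    """Simulate one multi-channel epoch driven by a stimulus timeline.

    The timeline is tiled periodically to cover ``duration`` seconds (default:
    the timeline's own length).  The per-call ``rng`` controls only the noise;
    the evoked component is a deterministic function of the subject.
    """
    if len(timeline) == 0:
        raise ValueError("empty stimulus timeline")
    if timeline.fs != subject.fs:
        raise ValueError("timeline and subject sampling rates differ")
    rng = np.random.default_rng(rng)
    n = len(timeline) if duration is None else int(round(duration * subject.fs))
    cycle = timeline.as_pm1()[: timeline.samples_per_cycle]
    if t0_code_phase:
        cycle = np.roll(cycle, -int(t0_code_phase))
    reps = int(np.ceil(n / len(cycle)))
    drive = np.tile(cycle, reps)[:n]

    s = _evoked_waveform(drive, subject.kernel, int(round(subject.latency * subject.fs)))
    evoked = np.outer(subject.topography, s)
    noise = subject.noise_sigma * make_noise(
        n, subject.n_channels, subject.noise_spec, rng, subject.fs,
        mixing=subject.noise_mixing,
    )
    data = evoked + noise_scale * noise
    epoch = Epoch(
        data=data, fs=subject.fs, label=label,
        t0_code_phase=int(t0_code_phase), montage=subject.montage,
    )
    if return_parts:
        return epoch, evoked, noise_scale * noise
    return epoch


def simulate_training_session(
    subject: SubjectModel,
    codes: Sequence[SampleTimeline],
    nb: int = 6,
    rng: np.random.Generator | int | None = None,
    noise_scale: float = 1.0,
    shuffle_within_block: bool = True,
) -> TrialSet:
    """Simulate a calibration session: ``nb`` blocks x one trial per class.

    Every trial spans the full timeline (two code cycles, 2.1 s at defaults)
    and starts on a code-cycle boundary (``t0_code_phase = 0``).  Defaults
    yield ``6 x 4 = 24`` labeled trials of 1260 samples each.
    """
    if nb < 1:
        raise ValueError("nb must be >= 1")
    if not codes:
        raise ValueError("need one timeline per class")
    rng = np.random.default_rng(rng)
    n_classes = len(codes)
    trials, labels = [], []
    for _ in range(nb):
        order = rng.permutation(n_classes) if shuffle_within_block else np.arange(n_classes)
        for k in order:
            ep = simulate_epoch(
                subject, codes[k], rng=rng, noise_scale=noise_scale, label=int(k) + 1
            )
            trials.append(ep.data)
            labels.append(int(k) + 1)
    return TrialSet(
        data=np.stack(trials), labels=np.array(labels), fs=subject.fs,
        montage=subject.montage,
    )


def perturb_topography(
    subject: SubjectModel,
    amount: float,
    rng: np.random.Generator | int | None = None,
) -> SubjectModel:
    """Session-to-session topography drift: a small smooth random rotation.

    ``amount`` is the relative norm of the smooth perturbation added before
    renormalizing (0.1 keeps the new topography at cosine similarity ~0.995
    with the old one).  Noise level is a property of the recording and is kept
    unchanged; the stored ``focus`` is recomputed from the drifted topography.
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    rng = np.random.default_rng(rng)
    bump = _smooth_scalp_sample(subject.montage, rng)
    bump *= amount * np.linalg.norm(subject.topography) / np.linalg.norm(bump)
    topo = subject.topography + bump
    topo *= np.linalg.norm(subject.topography) / np.linalg.norm(topo)
    drifted = replace(subject, topography=topo)
    return replace(drifted, focus=subject_focus(drifted))


def restrict_channels(x, subset: Montage, source: Montage | None = None):
    """Keep only the rows/entries of ``x`` at ``subset``'s electrode positions.

    ``x`` may be an :class:`Epoch`, a :class:`SubjectModel`, or a per-channel
    weight/gain vector (then ``source`` names its montage).  Original relative
    channel order is preserved.
    """
    if isinstance(x, Epoch):
        idx = x.montage.indices_of(subset)
        kept = Montage(tuple(np.array(x.montage.names)[idx]))
        return Epoch(
            data=x.data[idx], fs=x.fs, label=x.label,
            t0_code_phase=x.t0_code_phase, montage=kept,
        )
    if isinstance(x, SubjectModel):
        idx = x.montage.indices_of(subset)
        kept = Montage(tuple(np.array(x.montage.names)[idx]))
        mixing = x.noise_mixing[idx] if x.noise_mixing is not None else None
        return replace(x, topography=x.topography[idx], montage=kept,
                       noise_mixing=mixing)
    if isinstance(x, TrialSet):
        idx = x.montage.indices_of(subset)
        kept = Montage(tuple(np.array(x.montage.names)[idx]))
        return TrialSet(data=x.data[:, idx, :], labels=x.labels, fs=x.fs, montage=kept)
    arr = np.asarray(x)
    if source is None:
        raise ValueError("restricting a bare vector requires its source montage")
    idx = source.indices_of(subset)
    return arr[..., idx] if arr.ndim == 1 else arr[idx]
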