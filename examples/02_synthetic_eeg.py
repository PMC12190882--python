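"""Draw a synthetic participant and simulate code-locked EEG.

A subject is a response kernel, a smooth 16-channel topography whose
``focus`` fixes how much evoked energy sits on the 6 electrodes that survive
reduction, a response latency, and a noise model (pink + alpha + white, the
brain components spatially coherent).  The montage-average evoked-to-noise
variance ratio is calibrated to ``snr_db``.
"""

import numpy as np

import cvepsim as cv
from cvepsim.montage import FULL16, REDUCED6
from cvepsim.study import default_timelines
from cvepsim.synth import subject_focus

subject = cv.sample_subject(seed=42, focus_target=0.6, snr_db=-21.0)
print(f"subject: latency {subject.latency * 1000:.0f} ms, "
      f"snr {subject.snr_db:.1f} dB, focus {subject.focus:.2f}")
print("topography (squared gain, %):")
for name, g in zip(FULL16.names, subject.topography**2 * 100):
    tag = "*" if name in REDUCED6 else " "
    print(f"  {name:>4}{tag} {g:5.1f}")
print("(* = retained after electrode reduction; starred rows sum to "
      f"{subject_focus(subject) * 100:.0f}%)")

timelines = default_timelines()
epoch, evoked, noise = cv.simulate_epoch(subject, timelines[0], rng=0,
                                         return_parts=True)
snr_measured = 10 * np.log10(np.mean(evoked**2) / np.mean(noise**2))
print(f"\none 2.1 s epoch: {epoch.data.shape[0]} channels x "
      f"{epoch.data.shape[1]} samples")
print(f"measured montage-average evoked/noise ratio: {snr_measured:+.2f} dB "
      f"(target {subject.snr_db:+.1f} dB)")

session = cv.simulate_training_session(subject, timelines, rng=1)
per_class = {int(k): int(v) for k, v in
             zip(*np.unique(session.labels, return_counts=True))}
print(f"\ncalibration session: {len(session)} trials, {per_class} per class")
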