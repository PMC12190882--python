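# Methods

`cvepsim` models the closed loop of a four-target cVEP (code-modulated visual
evoked potential) speller and the statistics of an electrode-reduction study.
This note documents the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Stimulus codes

Targets flicker with circularly shifted copies of a 63-bit maximal-length
sequence (m-sequence) generated by a Fibonacci LFSR. Defaults: register
length 6 with feedback polynomial x⁶ + x⁵ + 1 and all-ones start state (any
primitive polynomial of degree 6 yields identical correlation properties;
taps and state are configurable), bit rate 60 bits/s — 63 bits per 1.05 s
cycle, i.e. 4 frames per bit on a 240 Hz display, 10 samples per bit at the
600 Hz sampling rate. Class *k* (of K = 4) uses the base code rotated by
(k − 1)·4 bits; a positive shift rotates toward later positions (element *i*
moves to *i* + shift mod 63). Whether the original system rotated forward or
backward in time is not recoverable and does not affect any property asserted
here; the convention is documented and applied consistently.

The m-sequence's periodic autocorrelation in ±1 coding is two-valued (63 at
lag 0, −1 elsewhere), so the four class codes are mutually near-orthogonal —
the basis of correlation decoding.

## Synthetic EEG forward model

No public raw EEG exists for this paradigm study design, so all calibration
and decoding runs on a generative subject model:

```
data = topography ⊗ (kernel ∗ pm1(timeline), delayed by latency) + noise
```

* **Kernel** — evoked response to one bit transition: a narrow Gaussian
  onset deflection (σ = 7 ms, weight 0.75) plus a damped 11 Hz sinusoid
  (decay 60 ms), 250 ms long, unit energy. The sharp component is what makes
  responses separable at the 66.7 ms class-shift spacing; the oscillatory
  tail overlaps the alpha band and makes decoding nontrivial. The whole
  waveform is configurable (the literature fixes no shape).
* **Topography** — a spatially smooth Gaussian-process sample over
  approximate 10-10 coordinates of the 16-electrode montage (P7, P3, Pz, P4,
  P8, PO7, PO3, POz, PO4, PO8, O1, Oz, O2, O9, Iz, O10; reference Cz, ground
  AFz), unit norm, rescaled so that the fraction `focus` ∈ [0, 1] of its
  squared-gain mass lies on the reduced subset (PO3, POz, PO4, O1, Oz, O2).
  `focus` is a modeling device for "how much of this subject's response
  survives electrode removal", not an estimate from data.
* **Latency** — uniform in 0.10–0.15 s per subject.
* **Noise** — per-channel unit-variance mixture: 65 % pink (1/f), 20 %
  narrowband alpha (10 ± 1 Hz), 15 % white. Pink and alpha are *brain* noise
  and spatially coherent (75 % of their variance shared through a smooth
  scalp covariance, length scale 0.5); white is independent sensor noise.
  Spatial coherence matters: it is what lets 16-channel CCA filters cancel
  noise across channels, and what breaks when those filters are truncated to
  6 channels. With spatially independent noise, restricted filters and
  retrained filters are near-equivalent and electrode reduction would cost
  almost nothing — contrary to what such studies observe.
* **SNR calibration** — `snr_db` fixes the ratio of the montage-average
  evoked variance (the evoked variance of a channel with average squared
  gain) to the per-channel noise variance. The calibration is deliberately
  *not* tied to a single electrode: referencing an electrode inside the
  retained subset would scale the noise floor with `focus` and cancel the
  very effect `focus` exists to control. Default −21 dB (single-trial,
  per-sample), in the range reported for raw VEP recordings; the 16-channel
  spatial filter adds roughly 12 dB.

Noise realizations are normalized to exact unit variance per channel, so the
calibration holds per epoch, not just in expectation.

`perturb_topography` models session-to-session nonstationarity as a smooth
random rotation of the topography; an `amount` of 0.5 leaves the new
topography at cosine ≈ 0.89 with the old one, consistent with between-run
VEP pattern variability after cap manipulation.

## Calibration (CCA)

Six blocks × four classes give 24 labeled 2.1 s trials (1260 samples, two
code cycles). Per class, trials are averaged and canonically correlated with
the binary code template (the class timeline replicated over channels):

* Both sides are row-centered (Pearson correlation is mean-invariant).
* A ridge of 1e−8 × mean auto-covariance diagonal regularizes both
  auto-covariances. The template's channel covariance is rank one by
  construction, so some regularization is mandatory; making the ridge
  relative keeps ρ exactly invariant to rescaling either signal.
* Only the leading canonical pair is kept; weights are unit-norm with the
  first nonzero entry of w_x positive and ρ ≥ 0 (filters are otherwise only
  defined up to sign/scale).
* A single integer-sample **template lag**, shared across classes, is
  estimated by grid search (0–150 samples, step 2) maximizing the mean
  squared canonical correlation. Without alignment, a physiological latency
  of ~100–150 ms aliases onto the 40-sample class-shift grid and the decoder
  systematically confuses neighboring classes; template alignment to the
  evoked response is therefore treated as part of the method. The grid scan
  uses a Cholesky fast path (the template side collapses to the 1-D
  timeline) and the reported filters/ρ come from the full CCA at the chosen
  lag.

No temporal filtering or detrending is applied before averaging (an explicit
modeling choice; the evoked model and noise are already band-limited by
construction).

## Online decoding

EEG arrives in 30-sample (0.05 s) blocks. Once one code cycle (630 samples)
is buffered, every new block triggers an evaluation: λᵢ = Pearson
correlation between the spatially filtered buffer and the correspondingly
filtered segment of class *i*'s periodic template, aligned to the buffer's
code phase minus the calibration lag. The certainty margin is
λ⁽¹⁾ − λ⁽²⁾ (ties give margin 0; argmax ties resolve to the lowest class
index for deterministic replay), and a selection is issued only when it
*strictly* exceeds β (default 0.15, sensible range 0.10–0.30). The buffer
holds at most two cycles (1260 samples) and then slides block-wise, the code
phase advancing with each dropped block. After a selection the buffer is
cleared and a 2 s gaze-shift pause follows (wall-clock only, not counted as
stimulation). A trial that never crosses β times out after 10 s.

Evaluating from one buffered cycle onward (rather than only at full
buffers) is a deliberate choice: per-selection stimulation times around
1.3–1.6 s are needed for the information-transfer rates such spellers
report, which is impossible if every selection must wait the full 2.1 s.

## Speller and study protocol

The three-step speller partitions 27 symbols (A–Z, underscore) 9/9/9, then
3/3/3, then singletons; each character costs three selections and target 4
is UNDO. The original study's letter grouping is unpublished, and its
printed per-target selection counts cannot be reconstructed from any
3-per-symbol scheme; the default layout makes no attempt to reproduce them
and any layout can be injected. A wrong selection queues one corrective
UNDO (which counts as a correct selection when it hits UNDO — accuracy
includes corrections in numerator and denominator); an erroneous UNDO
reverts one completed step. Either way one error costs two extra
selections. A run is abandoned (non-functional) after 3 consecutive
timeouts, a selection budget of 6× the error-free plan, or 600 s of active
stimulation; a run with zero correct selections is non-functional
regardless.

`run_three_condition_study` takes each subject through: 16-channel
calibration → baseline spelling of "HAVE_FUN" and "PROGRAM" → electrode
removal with filters truncated to the 6 retained channels (no retraining) →
fresh 6-channel calibration → retrained spelling. The topography drifts
(amount 0.5) between phases, so no-retrain decodes with increasingly stale
filters while retraining recalibrates after the drift — together with the
broken noise cancellation this reproduces the qualitative study pattern:
baseline functional for everyone, a substantial minority failing without
retraining, retraining recovering most (functionality and accuracy ordering
retrained ≥ no-retrain), and low-`focus` subjects driving the failures.

Cohort defaults (the simulated study conditions): 40 subjects, focus ~
U(0.2, 0.9), snr_db ~ N(−21, 1.5²), drift 0.5. Accuracy/ITR per condition
pool both words; the information clock counts active stimulation (selection
and timeout latencies), excluding gaze-shift and cue pauses — pause-inclusive
timing is incompatible with the upper range of printed ITRs.

## Metrics and statistics

Wolpaw bits per selection, B = log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1)),
with P·log₂P → 0 at P → 0; ITR = B × selections per minute of active time.
McNemar's χ² is uncorrected by default, (b−c)²/(b+c) — the variant
consistent with the study's printed functionality contrasts — with the
continuity-corrected form behind a flag. Cochran's Q uses the standard
column/row-sum formula and raises on the degenerate all-rows-constant case
(where Q is 0/0; note that exactly identical columns always produce it).
Paired Cohen's d is mean(diff)/SD(diff) with a seeded percentile bootstrap
(10 000 resamples) for its CI. Pearson and point-biserial correlations
delegate to scipy. Shapiro–Wilk tests and mixed-effects models are
deliberately not re-implemented; use scipy/statsmodels directly on the
study table if needed.

The packaged 38-subject results table drives the reproduction of the
study-level statistics; its per-condition means, functionality counts,
transitions, failure rates and McNemar statistics are recomputed from the
table, never stored. Two printed values are knowingly not reproducible from
the subject-level table and are not asserted: the published Cochran's Q
(40.00; the table's functionality pattern yields 29.55 by the standard
formula) and the (7, 2)-discordant McNemar (printed 2.27; the formula gives
2.78). The published no-retrain condition means also differ slightly from
the table's column means (consistent with run-level averaging over an
unpublished run structure) and are excluded from assertions.

## What the synthetic generator does and does not show

The generator reproduces code-locked evoked structure, spatially smooth
subject-specific topographies, colored and spatially coherent background
noise, response latency, and session nonstationarity. It does not model
volume-conduction leadfields, eye blinks or movement artifacts, fatigue,
attention lapses, or genuine inter-subject kernel variability. Passing the
cohort-level tests therefore shows that the *pipeline* behaves as the method
predicts under a plausible signal model — not that real EEG would yield the
same numbers. Simulated baseline ITRs (≈ 60–90 bits/min) sit above the real
cohort mean (≈ 49), i.e. the synthetic baseline condition is somewhat easier
than real recording conditions; all cohort-level claims asserted in tests
are orderings, not absolute levels.

## Problem sizes and runtime

The test suite simulates cohorts of 1–10 subjects for structural and
monotonicity checks and one 40-subject cohort (the study's sample size, with
both study words) for the phenomenology checks; the acceptance script runs
the same 40-subject protocol. A full 40-subject three-condition study takes
on the order of a minute on one CPU.
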