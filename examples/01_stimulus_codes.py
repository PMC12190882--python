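"""Generate the m-sequence stimulus codes and inspect their correlation
structure.

The four speller targets flicker with circularly shifted copies of one 63-bit
maximal-length sequence.  The two-valued periodic autocorrelation (63 at lag
zero, -1 everywhere else) is what makes the shifted copies separable by a
correlation decoder.
"""

import numpy as np

import cvepsim as cv
from cvepsim.codes import periodic_autocorrelation

base = cv.generate_m_sequence()
print(f"base code c1 ({len(base)} bits at {base.bit_rate:.0f} bits/s, "
      f"{base.cycle_duration:.2f} s per cycle):")
print(" ", base.to_text())
print(f"  balance: {base.as_array().sum()} ones / "
      f"{(base.as_array() == 0).sum()} zeros")

ac = periodic_autocorrelation(base)
print(f"periodic autocorrelation: {ac[0]:.0f} at lag 0, "
      f"{ac[1:].min():.0f}..{ac[1:].max():.0f} at all other lags")

print("\nclass codes are 4-bit circular shifts; +/-1 cross-correlations:")
codes = [cv.class_code(base, k) for k in range(1, 5)]
gram = np.array([[ci.as_pm1() @ cj.as_pm1() for cj in codes] for ci in codes])
print(gram)
print("-> 63 on the diagonal (identical codes), -1 off it: near-orthogonal.")

timeline = cv.code_to_timeline(base, fs=600, n_cycles=2)
print(f"\nexpanded at 600 Hz for one 2.1 s trial: {len(timeline)} samples "
      f"({timeline.samples_per_cycle} per cycle, 10 per bit)")
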