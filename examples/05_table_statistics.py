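"""Reproduce the study-table statistics from the packaged results table.

The package ships the 38-participant subject-level results (accuracy % and
ITR bits/min per condition; missing entries mark rounds where the closed
loop was non-functional).  Everything below is recomputed from that table.
"""

import json

import cvepsim as cv

table = cv.packaged_study_table()
report = cv.reproduce_report(table)

print(f"{report['n_subjects']} subjects; per-condition summaries "
      "(mean +/- SD over functional rounds):")
for cond in ("baseline", "noretrain", "retrained"):
    a = report["summary"][f"acc_{cond}"]
    i = report["summary"][f"itr_{cond}"]
    print(f"  {cond:<10} accuracy {a['mean']:6.2f} +/- {a['sd']:5.2f} %   "
          f"ITR {i['mean']:6.2f} +/- {i['sd']:5.2f} bits/min")

print(f"\nfunctional systems: {report['functional']}")
print(f"failure rates (%): "
      f"{ {k: round(v, 1) for k, v in report['failure_rate_pct'].items()} }")
print(f"after retraining: {report['regained']} regained, "
      f"{report['lost']} lost, {report['remained_failed']} remained failed")

print("\npaired functionality contrasts (McNemar chi-square, uncorrected):")
for name, m in report["mcnemar"].items():
    print(f"  {name:<24} b={m['b']:2d} c={m['c']:2d} chi2={m['chi2']:.2f}")
q = report["cochran_q"]
print(f"Cochran's Q over the three conditions: Q={q['Q']:.2f}, df={q['df']}")

print("\nthe full report serializes to JSON, e.g.:")
print(json.dumps(report)[:120] + " ...")
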