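"""Compare density ranking against the classical outlier rules.

On a bounded right-skewed metric, Z score and Tukey's fences place their
lower boundary below the natural limit of zero — a physically meaningless
bound, annotated as such — while density ranking simply reports that no
lower boundary exists and puts the upper one where the data thin out.
"""

import pdrank as pk

sample = pk.generate(pk.ShapeSpec("skewed_bounded", n=10_000, seed=3))
records = pk.compare_methods(sample, level=0.05)

print(f"{'method':14s} {'lower':>10s} {'upper':>10s} {'flagged':>9s}  notes")
for r in records:
    lo = "none" if r.lower is None else f"{r.lower:10.2f}"
    hi = "none" if r.upper is None else f"{r.upper:10.2f}"
    notes = []
    if r.lower_meaningless:
        notes.append("lower bound beyond natural limit")
    if r.upper_meaningless:
        notes.append("upper bound beyond natural limit")
    print(f"{r.method:14s} {lo:>10s} {hi:>10s} {r.flagged_fraction:8.2%}  "
          + "; ".join(notes))
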