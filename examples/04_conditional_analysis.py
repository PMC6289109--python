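"""Conditional (per-category) outlier analysis.

When one metric mixes two data-generation protocols with very different
scales — think conventional rotation crystallography versus serial
femtosecond experiments, whose data multiplicity runs orders of
magnitude higher — a single pooled analysis flags the whole minority
protocol as outlying.  Splitting on the protocol and ranking within each
subset restores meaningful, protocol-specific outlier boundaries.
"""

import numpy as np

import pdrank as pk

rng = np.random.default_rng(4)
routine = rng.lognormal(1.6, 0.5, 9_500)          # bulk protocol
extreme = rng.lognormal(5.5, 0.9, 500)            # high-multiplicity protocol
values = np.concatenate([routine, extreme])
protocol = np.array(["routine"] * routine.size + ["extreme"] * extreme.size)

sample = pk.Sample(values, lower_limit=1.0, label="multiplicity-like")
sample, _ = pk.apply_natural_limits(sample, lower=1.0)
keep = values >= 1.0

pooled = pk.flag_pdr_outliers(sample, 0.05)
print(f"pooled 5% upper boundary: {pooled.upper_boundary:.1f} "
      f"(flags {np.mean(pooled.flags[protocol[keep] == 'extreme']):.0%} "
      "of the extreme protocol)")

for cat, (sub, res) in pk.conditional_pdr(sample, protocol[keep], 0.05).items():
    print(f"{cat:8s} n={sub.n:5d}  5% upper boundary {res.upper_boundary:8.1f}  "
          f"flagged {res.flagged_fraction:.2%}")
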