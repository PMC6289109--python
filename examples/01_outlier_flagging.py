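"""Flag density-ranked outliers on a bounded, right-skewed metric.

Builds a clash-score-like sample (hard lower limit at 0, long right
tail), fits the kernel density model and flags the 5% and 1% least
probable observations.  Note the one-sided result: the data are dense
all the way down to the bound, so only an upper outlier boundary exists.
"""

import numpy as np

import pdrank as pk

sample = pk.generate(pk.ShapeSpec("skewed_bounded", n=10_000, seed=1))
model = pk.fit_density(sample)  # Gaussian kernel, h = 0.79*IQR*n^(-1/5)

print(f"n = {sample.n}, bandwidth h = {model.bandwidth.h:.3f}")
for level in (0.05, 0.01):
    res = pk.flag_pdr_outliers(sample, level, model)
    print(
        f"{level:.0%} PDR: threshold density {res.density_threshold:.5f}, "
        f"flagged {res.flagged_fraction:.2%}, "
        f"lower boundary {res.lower_boundary}, "
        f"upper boundary {res.upper_boundary:.2f}"
    )

# The flagged observations are exactly the ones whose estimated density
# ranks in the lowest `level` fraction: here the far right tail (and no
# lower tail, because the mode hugs the natural limit).
res = pk.flag_pdr_outliers(sample, 0.05, model)
print("largest unflagged value:", np.max(sample.values[~res.flags]).round(2))
print("smallest flagged value:", np.min(sample.values[res.flags]).round(2))
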