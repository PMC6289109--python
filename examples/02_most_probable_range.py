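"""Most Probable Range versus the interquartile range.

On a symmetric sample MPR(0.5) and the IQR coincide; on a skewed sample
the MPR is strictly more compact — the same 50% of observations, in a
shorter interval placed where the data actually concentrate.  On a
bimodal sample the multi-interval extension splits across the modes.
"""

import numpy as np

import pdrank as pk

for shape in ("normal", "skewed_bounded"):
    s = pk.generate(pk.ShapeSpec(shape, n=20_000, seed=2))
    iv = pk.most_probable_range(s, 0.5)
    (lo, hi), = iv.intervals
    q1, q3 = np.quantile(s.values, [0.25, 0.75])
    print(
        f"{shape:15s} MPR50 = [{lo:6.2f}, {hi:6.2f}] (length {iv.total_length:.2f})"
        f"   IQR = [{q1:6.2f}, {q3:6.2f}] (length {q3 - q1:.2f})"
    )

# multimodal: one interval per mode, total length below any single window
s = pk.generate(pk.ShapeSpec("multimodal", n=20_000, seed=2))
iv = pk.most_probable_intervals(s, 0.5)
pretty = ", ".join(f"[{lo:.2f}, {hi:.2f}]" for lo, hi in iv.intervals)
print(f"multimodal      MPR50 = {pretty} (total length {iv.total_length:.2f})")
print(f"covered fraction: {iv.covered_fraction:.3f} of n = {iv.n}")
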