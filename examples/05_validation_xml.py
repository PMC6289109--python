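"""Extract entry-level quality metrics from validation-report XML.

Writes a handful of small synthetic validation reports (the same
entry-level attribute layout as wwPDB validation XML), extracts the four
quality metrics and runs an outlier analysis on the clash scores.
"""

import tempfile
from pathlib import Path

import numpy as np

import pdrank as pk
from pdrank.data_io import metrics_to_frame

TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<wwPDB-validation-information>
  <Entry pdbid="{pdbid}" clashscore="{clash:.2f}" PDB-Rfree="{rfree:.3f}"
         percent-rama-outliers="{rama:.2f}" percent-RSRZ-outliers="{rsrz:.2f}"/>
</wwPDB-validation-information>
"""

rng = np.random.default_rng(5)
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    for i in range(200):
        (tmp / f"{i:04d}.xml").write_text(
            TEMPLATE.format(
                pdbid=f"{i:04d}",
                clash=rng.lognormal(1.8, 0.8),
                rfree=rng.normal(0.24, 0.03),
                rama=rng.exponential(0.3),
                rsrz=rng.exponential(2.0),
            )
        )
    records = pk.extract_validation_metrics(sorted(tmp.glob("*.xml")))

frame = metrics_to_frame(records)
print(frame.head().to_string(index=False))

clash = pk.Sample(frame["clashscore"].to_numpy(), lower_limit=0.0, label="clashscore")
res = pk.flag_pdr_outliers(clash, 0.05)
print(f"\nclashscore 5% PDR upper boundary: {res.upper_boundary:.1f}; "
      f"{int(res.flags.sum())} of {clash.n} entries flagged for review")
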