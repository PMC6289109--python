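"""Table readers/writers, natural-limit cleaning and validation-XML extraction.

Input tables are plain CSV/TSV with one header row, "." decimal separator
and UTF-8 text.  wwPDB validation reports are per-entry XML files whose
root ``Entry`` element carries entry-level summary attributes; the four
quality metrics used throughout (clash score, Rfree, percent Ramachandran
outliers, percent RSRZ outliers) are read from those attributes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd

from .errors import EmptySampleError, ParameterError
from .kde import Sample
from .pdr import OutlierResult

logger = logging.getLogger(__name__)

#: Entry-element attribute names in the wwPDB validation-report schema
#: (wwpdb_validation_v002), mapped to MetricRecord field names.
_ENTRY_ATTRS = {
    "clashscore": "clashscore",
    "PDB-Rfree": "rfree",
    "percent-rama-outliers": "percent_rama_outliers",
    "percent-RSRZ-outliers": "percent_rsrz_outliers",
}


@dataclass(frozen=True)
class CleaningReport:
    """Bookkeeping for rows dropped while building a Sample."""

    retained: int
    excluded_below: int = 0
    excluded_above: int = 0
    excluded_nonnumeric: int = 0

    @property
    def total(self) -> int:
        return (
            self.retained
            + self.excluded_below
            + self.excluded_above
            + self.excluded_nonnumeric
        )


@dataclass(frozen=True)
class MetricRecord:
    """Entry-level quality metrics extracted from one validation report."""

    entry_id: str
    clashscore: float | None = None
    rfree: float | None = None
    percent_rama_outliers: float | None = None
    percent_rsrz_outliers: float | None = None


def read_numeric_column(
    path: str | Path,
    column: str,
    delimiter: str = ",",
    label: str | None = None,
) -> tuple[Sample, CleaningReport]:
    """Read one numeric column into a Sample, dropping and counting
    non-numeric or missing cells."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    if column not in frame.columns:
        raise KeyError(f"column {column!r} not in {path} (has {list(frame.columns)})")
    raw = pd.to_numeric(frame[column], errors="coerce")
    good = raw.notna() & np.isfinite(raw.fillna(np.inf))
    values = raw[good].to_numpy(dtype=float)
    dropped = int((~good).sum())
    if values.size == 0:
        raise EmptySampleError(f"column {column!r} of {path} has no numeric values")
    sample = Sample(values, label=label if label is not None else column)
    return sample, CleaningReport(retained=values.size, excluded_nonnumeric=dropped)


def apply_natural_limits(
    sample: Sample,
    lower: float | None = None,
    upper: float | None = None,
) -> tuple[Sample, CleaningReport]:
    """Retain values within the natural limits (inclusive), counting the
    physically impossible values excluded on each side.

    Values exactly at a limit are legitimate data (for many metrics the
    bound is the mode) and are always retained.
    """
    if lower is not None and upper is not None and lower > upper:
        raise ParameterError("lower limit must not exceed upper limit")
    values = sample.values
    below = np.zeros(sample.n, dtype=bool) if lower is None else values < lower
    above = np.zeros(sample.n, dtype=bool) if upper is None else values > upper
    keep = ~(below | above)
    if not np.any(keep):
        raise EmptySampleError("all values fall outside the natural limits")
    cleaned = Sample(
        values[keep], lower_limit=lower, upper_limit=upper, label=sample.label
    )
    report = CleaningReport(
        retained=int(keep.sum()),
        excluded_below=int(below.sum()),
        excluded_above=int(above.sum()),
    )
    return cleaned, report


def extract_validation_metrics(xml_paths: list[str | Path]) -> list[MetricRecord]:
    """Extract entry-level metrics from wwPDB validation-report XML files.

    One record per well-formed file; malformed files are logged and
    skipped so a batch survives individual bad reports.  Attributes
    absent from an Entry element become missing (None) fields.
    """
    records: list[MetricRecord] = []
    for path in xml_paths:
        path = Path(path)
        try:
            root = ElementTree.parse(path).getroot()
        except (ElementTree.ParseError, OSError) as exc:
            logger.error("skipping %s: %s", path, exc)
            continue
        entry = root if root.tag == "Entry" else root.find(".//Entry")
        if entry is None:
            logger.error("skipping %s: no Entry element", path)
            continue
        fields: dict[str, float | None] = {}
        for attr, name in _ENTRY_ATTRS.items():
            raw = entry.get(attr)
            if raw is None:
                fields[name] = None
                continue
            try:
                val = float(raw)
                fields[name] = val if math.isfinite(val) else None
            except ValueError:
                fields[name] = None
        records.append(
            MetricRecord(entry_id=entry.get("pdbid", path.stem), **fields)
        )
    return records


def metrics_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Tabulate MetricRecords (one row per entry)."""
    return pd.DataFrame(
        {
            "entry_id": [r.entry_id for r in records],
            "clashscore": [r.clashscore for r in records],
            "rfree": [r.rfree for r in records],
            "percent_rama_outliers": [r.percent_rama_outliers for r in records],
            "percent_rsrz_outliers": [r.percent_rsrz_outliers for r in records],
        }
    )


def write_annotated(
    sample: Sample,
    result5: OutlierResult,
    result1: OutlierResult,
    path: str | Path,
    column: str = "value",
) -> int:
    """Write the sample with per-row 5% and 1% outlier flags.

    Row order is preserved; returns the number of data rows written.
    """
    if result5.flags.size != sample.n or result1.flags.size != sample.n:
        raise ParameterError("flag vectors must match the sample length")
    frame = pd.DataFrame(
        {
            column: sample.values,
            "pdr5": result5.flags,
            "pdr1": result1.flags,
        }
    )
    frame.to_csv(path, index=False)
    return sample.n
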