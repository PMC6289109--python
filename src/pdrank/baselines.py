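"""Conventional outlier boundaries: Z score, Tukey's fences, MAD, percent cut.

These are the location/scale and percentile rules that density ranking is
compared against.  All of them place symmetric (or percentile) boundaries
without looking at the local density, so on bounded or heavily skewed
data they can produce boundaries beyond a natural limit; such bounds are
reported as-is and annotated as meaningless rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, ParameterError
from .kde import DensityModel, Sample, fit_density
from .pdr import flag_pdr_outliers


@dataclass(frozen=True)
class MethodBounds:
    """Lower/upper outlier boundaries from one method on one sample."""

    method: str
    lower: float | None
    upper: float | None
    flagged_fraction: float
    lower_meaningless: bool = False
    upper_meaningless: bool = False
    error: str | None = None


def _flagged_fraction(sample: Sample, lower: float | None, upper: float | None) -> float:
    out = np.zeros(sample.n, dtype=bool)
    if lower is not None:
        out |= sample.values < lower
    if upper is not None:
        out |= sample.values > upper
    return float(np.mean(out))


def _annotate(sample: Sample, method: str, lower: float, upper: float) -> MethodBounds:
    lower_meaningless = sample.lower_limit is not None and lower < sample.lower_limit
    upper_meaningless = sample.upper_limit is not None and upper > sample.upper_limit
    return MethodBounds(
        method=method,
        lower=float(lower),
        upper=float(upper),
        flagged_fraction=_flagged_fraction(sample, lower, upper),
        lower_meaningless=bool(lower_meaningless),
        upper_meaningless=bool(upper_meaningless),
    )


def z_bounds(sample: Sample, level: float = 0.05) -> MethodBounds:
    """Mean +/- z(level) standard deviations; z(0.05)=1.96, z(0.01)=2.58."""
    if not (0.0 < level < 1.0):
        raise ParameterError(f"level must be in (0, 1), got {level}")
    sigma = sample.sigma
    if sigma <= 0.0:
        raise DegenerateSampleError("Z bounds undefined on a zero-spread sample")
    z = float(stats.norm.ppf(1.0 - level / 2.0))
    mu = float(np.mean(sample.values))
    return _annotate(sample, "z_score", mu - z * sigma, mu + z * sigma)


def tukey_fences(sample: Sample, k: float = 1.5) -> MethodBounds:
    """[Q1 - k*IQR, Q3 + k*IQR]; k=1.0 roughly matches 5% outliers on
    Normal data and k=1.5 roughly 1%."""
    if sample.n < 4:
        raise ParameterError("Tukey's fences need at least 4 observations")
    q1, q3 = np.quantile(sample.values, [0.25, 0.75])
    iqr = q3 - q1
    return _annotate(sample, "tukey_fences", q1 - k * iqr, q3 + k * iqr)


def mad_bounds(sample: Sample, n_mads: float = 3.0) -> MethodBounds:
    """median +/- n_mads * MAD, with the MAD left unscaled (a raw count of
    median absolute deviations, no normal-consistency factor)."""
    med = float(np.median(sample.values))
    mad = float(np.median(np.abs(sample.values - med)))
    if mad <= 0.0:
        raise DegenerateSampleError("MAD is zero: bounds undefined")
    return _annotate(sample, "mad", med - n_mads * mad, med + n_mads * mad)


def percent_cut(sample: Sample, level: float = 0.05) -> MethodBounds:
    """Symmetric percentile boundaries at level/2 and 1 - level/2.

    The level-0 limit is the full data range [min, max].
    """
    if not (0.0 <= level < 1.0):
        raise ParameterError(f"level must be in [0, 1), got {level}")
    lo, hi = np.quantile(sample.values, [level / 2.0, 1.0 - level / 2.0])
    return _annotate(sample, "percent_cut", float(lo), float(hi))


def compare_methods(
    sample: Sample, level: float = 0.05, model: DensityModel | None = None
) -> list[MethodBounds]:
    """One boundary record per method (PDR, Z, Tukey, MAD, percent cut).

    Per-method failures (degenerate spread, too few points) are reported
    in the record's ``error`` field, never fatal to the table.  Defaults
    tie every method to the same nominal ``level``: Tukey k is 1.0 at 5%
    and 1.5 at 1% and the MAD multiplier is z(level)/z(0.75), the count
    of raw MADs matching the Z rule on Normal data.
    """
    if model is None:
        model = fit_density(sample)
    records: list[MethodBounds] = []

    pdr_res = flag_pdr_outliers(sample, level, model)
    lower = pdr_res.lower_boundary
    upper = pdr_res.upper_boundary
    records.append(
        MethodBounds(
            method="pdr",
            lower=lower,
            upper=upper,
            flagged_fraction=pdr_res.flagged_fraction,
        )
    )

    tukey_k = 1.0 if level >= 0.05 else 1.5
    n_mads = float(stats.norm.ppf(1.0 - level / 2.0) / stats.norm.ppf(0.75)) if 0 < level < 1 else 3.0

    for name, call in (
        ("z_score", lambda: z_bounds(sample, level)),
        ("tukey_fences", lambda: tukey_fences(sample, tukey_k)),
        ("mad", lambda: mad_bounds(sample, n_mads)),
        ("percent_cut", lambda: percent_cut(sample, level)),
    ):
        try:
            records.append(call())
        except (DegenerateSampleError, ParameterError) as exc:
            records.append(
                MethodBounds(
                    method=name,
                    lower=None,
                    upper=None,
                    flagged_fraction=0.0,
                    error=str(exc),
                )
            )
    return records
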