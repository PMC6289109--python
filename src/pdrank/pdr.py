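"""Probability-Density-Ranking (PDR) outlier identification.

Each observation is ranked by its estimated probability density; the
observations in the lowest ``level`` fraction of density are flagged as
PDR outliers.  Unlike location/scale rules (Z score, Tukey's fences, MAD)
this works unchanged on bounded, skewed and multimodal distributions: a
low-density observation is an outlier wherever it sits, and a bound where
the density is high (e.g. a mode at a natural lower limit of zero) simply
produces no outlier boundary on that side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .kde import DensityModel, Sample, fit_density

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundaryCrossing:
    """One abscissa where the density curve crosses the outlier threshold."""

    x: float
    side: str          # "lower" or "upper", relative to the global mode
    rising: bool       # curve rises through the threshold left-to-right


@dataclass(frozen=True)
class OutlierResult:
    """PDR flags at one level, with threshold and outlier boundaries.

    ``lower_boundary`` is the abscissa below which data are outliers
    (absent when the density at the low end of the range never drops
    below the threshold, e.g. a mode sitting at a natural limit);
    ``upper_boundary`` likewise for the high end.  ``crossings`` holds
    every threshold crossing, which for multimodal curves can include
    inter-mode outlier pockets.
    """

    level: float
    density_threshold: float
    flags: np.ndarray
    lower_boundary: float | None
    upper_boundary: float | None
    crossings: tuple[BoundaryCrossing, ...]
    all_outlying: bool = False

    @property
    def flagged_fraction(self) -> float:
        return float(np.mean(self.flags))


def flag_pdr_outliers(
    sample: Sample, level: float, model: DensityModel | None = None
) -> OutlierResult:
    """Flag the observations whose density ranks in the lowest ``level``.

    The density threshold is the ``level`` quantile (linear interpolation)
    of the n per-observation densities; observations strictly below it are
    flagged, so ties at the threshold stay unflagged and the flagged
    fraction never exceeds ``level`` beyond quantile rounding.
    """
    if not (0.0 <= level < 1.0):
        raise ParameterError(f"level must be in [0, 1), got {level}")
    if model is None:
        model = fit_density(sample)
    dens = model.point_densities
    if level == 0.0:
        threshold = 0.0
        flags = np.zeros(sample.n, dtype=bool)
    else:
        threshold = float(np.quantile(dens, level))
        flags = dens < threshold

    crossings, all_outlying = outlier_boundaries(model, threshold)
    lower = None
    upper = None
    if not all_outlying and crossings:
        # no lower boundary when the curve already starts above threshold
        # (mass piled on a natural limit); symmetrically for the upper end
        if model.grid_densities[0] < threshold:
            lower = min(c.x for c in crossings)
        if model.grid_densities[-1] < threshold:
            upper = max(c.x for c in crossings)
    return OutlierResult(
        level=level,
        density_threshold=threshold,
        flags=flags,
        lower_boundary=lower,
        upper_boundary=upper,
        crossings=tuple(crossings),
        all_outlying=all_outlying,
    )


def outlier_boundaries(
    model: DensityModel, density_threshold: float
) -> tuple[list[BoundaryCrossing], bool]:
    """Find where the density curve crosses a threshold.

    Grid intervals that bracket the threshold are refined by bisection on
    the exact density evaluator to 1e-6 of the grid range.  Each crossing
    is classified lower/upper relative to the global mode.  Returns
    ``(crossings, all_outlying)``; ``all_outlying`` is set when the
    threshold exceeds the curve's maximum.
    """
    if density_threshold < 0:
        raise ParameterError("density threshold must be nonnegative")
    grid = model.grid
    dens = model.grid_densities
    if density_threshold > dens.max():
        logger.warning("threshold %g above maximum density %g: all data outlying",
                       density_threshold, dens.max())
        return [], True
    if density_threshold <= 0.0:
        return [], False

    above = dens >= density_threshold
    change = np.nonzero(above[:-1] != above[1:])[0]
    tol = 1e-6 * (grid[-1] - grid[0])
    mode_x = model.mode_abscissa
    crossings: list[BoundaryCrossing] = []
    for i in change:
        lo, hi = float(grid[i]), float(grid[i + 1])
        f_lo = float(dens[i]) - density_threshold
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            f_mid = float(model.evaluate(np.array([mid]))[0]) - density_threshold
            if (f_mid < 0) == (f_lo < 0):
                lo, f_lo = mid, f_mid
            else:
                hi = mid
        x = 0.5 * (lo + hi)
        crossings.append(
            BoundaryCrossing(
                x=x,
                side="lower" if x < mode_x else "upper",
                rising=bool(above[i + 1]),
            )
        )
    return crossings, False


def conditional_pdr(
    sample: Sample,
    categories: np.ndarray,
    level: float,
    min_size: int = 10,
    **fit_kwargs,
) -> dict[str, tuple[Sample, OutlierResult]]:
    """Run the full PDR procedure independently within each category.

    Categories with fewer than ``min_size`` observations are skipped with
    a warning (a kernel density estimate on a handful of points is not a
    meaningful ranking basis).  Returns, per category, the sub-sample and
    its :class:`OutlierResult` — identical to manually splitting the data
    and analysing each subset alone.
    """
    categories = np.asarray(categories)
    if categories.size != sample.n:
        raise ParameterError("need exactly one category label per observation")
    out: dict[str, tuple[Sample, OutlierResult]] = {}
    for cat in np.unique(categories):
        mask = categories == cat
        if int(mask.sum()) < min_size:
            logger.warning(
                "category %r has %d < %d observations; skipped",
                cat, int(mask.sum()), min_size,
            )
            continue
        sub = Sample(
            sample.values[mask],
            lower_limit=sample.lower_limit,
            upper_limit=sample.upper_limit,
            label=f"{sample.label}[{cat}]" if sample.label else str(cat),
        )
        model = fit_density(sub, **fit_kwargs)
        out[str(cat)] = (sub, flag_pdr_outliers(sub, level, model))
    return out
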