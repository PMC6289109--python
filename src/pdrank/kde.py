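"""Kernel density estimation engines and bandwidth rules.

Everything downstream (outlier ranking, most-probable-range statistics,
method comparisons) is built on the estimators in this module.  The working
estimate is the classic fixed-bandwidth kernel density estimate

    f_hat(x) = (1 / (n h)) * sum_i K((x - X_i) / h)

with a Gaussian kernel and the robust rule-of-thumb bandwidth
h = 0.79 * IQR * n**(-1/5) (the IQR variant of the normal-reference rule
h = 1.06 * sigma * n**(-1/5)).  Two adaptive estimators are provided for
cross-checking: a k-nearest-neighbour kernel whose local bandwidth is the
distance d_k(x) to the k-th nearest observation, and the two-step
(Abramson-type) variable kernel with per-observation bandwidths
h_i = h * (f_pilot(X_i) / g)**(-1/2), g the geometric mean pilot density.

Evaluation is exact (no binning or grid interpolation): the Gaussian kernel
is summed over every observation within |u| <= 12 bandwidths, beyond which
a double-precision sum cannot change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateSampleError, ParameterError

logger = logging.getLogger(__name__)

#: |u| beyond which a Gaussian kernel term cannot affect a float64 sum.
_GAUSS_CUTOFF = 12.0

#: Maximum number of kernel terms evaluated per vectorised block.
_BLOCK_BUDGET = 4_000_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """An ordered collection of finite numeric observations.

    Parameters
    ----------
    values
        The observations, in metric units.  Must be finite.
    lower_limit, upper_limit
        Optional natural (physical) limits of the metric, e.g. 0 for a
        clash score or 1 for diffraction data multiplicity.  Limits are
        metadata used by boundary and range logic; values are expected to
        respect them (use :func:`pdrank.data_io.apply_natural_limits` to
        clean raw data).
    label
        Free-text name used in reports and plots.
    """

    values: np.ndarray
    lower_limit: float | None = None
    upper_limit: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size < 1:
            raise ParameterError("a Sample needs at least one observation")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("sample values must all be finite")
        if (
            self.lower_limit is not None
            and self.upper_limit is not None
            and self.lower_limit > self.upper_limit
        ):
            raise ParameterError("lower_limit must not exceed upper_limit")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sigma(self) -> float:
        """Sample standard deviation (n-1 denominator)."""
        if self.n < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))

    @property
    def iqr(self) -> float:
        """Interquartile range, linear-interpolation quantiles."""
        q1, q3 = np.quantile(self.values, [0.25, 0.75])
        return float(q3 - q1)


@dataclass(frozen=True)
class KernelSpec:
    """A kernel function together with its roughness constant.

    ``roughness`` is the integral of K(t)^2 over the real line; it enters
    the asymptotic variance of the density estimate.  ``second_moment`` is
    the integral of t^2 K(t).
    """

    kernel_id: Literal["gaussian", "uniform"]
    roughness: float
    second_moment: float

    @staticmethod
    def from_id(kernel_id: str) -> "KernelSpec":
        if kernel_id == "gaussian":
            return KernelSpec("gaussian", 1.0 / (2.0 * math.sqrt(math.pi)), 1.0)
        if kernel_id == "uniform":
            # K(u) = 1/2 on [-1, 1]; int K^2 = 1/2, int t^2 K = 1/3
            return KernelSpec("uniform", 0.5, 1.0 / 3.0)
        raise ConfigurationError(f"unknown kernel_id: {kernel_id!r}")


GAUSSIAN = KernelSpec.from_id("gaussian")
UNIFORM = KernelSpec.from_id("uniform")


@dataclass(frozen=True)
class BandwidthSpec:
    """How smoothing is parameterised for one density model.

    For fixed-bandwidth methods ``h`` is the bandwidth; for the kNN kernel
    ``k`` is the neighbour count and ``h`` is unused.  ``sigma`` and
    ``iqr`` record the sample statistics the rule was computed from.
    """

    method: Literal["iqr_rule", "normal_reference", "knn", "two_step"]
    h: float | None = None
    k: int | None = None
    sigma: float = 0.0
    iqr: float = 0.0

    def __post_init__(self) -> None:
        if self.method in ("iqr_rule", "normal_reference"):
            if self.h is None or self.h <= 0:
                raise ParameterError("fixed-bandwidth method needs h > 0")
        if self.method == "knn" and (self.k is None or self.k < 1):
            raise ParameterError("knn method needs k >= 1")


@dataclass(frozen=True)
class DensityModel:
    """A fitted density estimate: per-observation densities plus a curve.

    ``point_densities`` are exact evaluations of the estimator at each
    observation (never grid-interpolated); the grid curve supports
    boundary extraction and modality checks.  ``evaluate`` re-evaluates
    the same estimator exactly at arbitrary points.
    """

    sample: Sample
    kernel: KernelSpec
    bandwidth: BandwidthSpec
    point_densities: np.ndarray
    grid: np.ndarray
    grid_densities: np.ndarray
    evaluate: Callable[[np.ndarray], np.ndarray] = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    @property
    def mode_abscissa(self) -> float:
        """Abscissa of the global maximum of the grid density curve."""
        return float(self.grid[int(np.argmax(self.grid_densities))])


@dataclass(frozen=True)
class DensityVariance:
    """A density estimate at a point with its approximate variance."""

    fhat: float
    var: float
    n: int
    h: float


# ---------------------------------------------------------------------------
# bandwidth rules
# ---------------------------------------------------------------------------

def bandwidth_normal_reference(sample: Sample) -> BandwidthSpec:
    """Normal-reference rule h = 1.06 * sigma * n**(-1/5).

    Raises
    ------
    DegenerateSampleError
        If the sample standard deviation is zero.
    """
    sigma = sample.sigma
    if sigma <= 0.0:
        raise DegenerateSampleError(
            "normal-reference bandwidth undefined: sample has zero spread"
        )
    h = 1.06 * sigma * sample.n ** (-1.0 / 5.0)
    return BandwidthSpec("normal_reference", h=h, sigma=sigma, iqr=sample.iqr)


def bandwidth_iqr(sample: Sample) -> BandwidthSpec:
    """Robust rule-of-thumb h = 0.79 * IQR * n**(-1/5).

    Quartiles use linear interpolation between order statistics.  When the
    IQR is zero (heavily tied data) the normal-reference rule is used as a
    fallback; if the standard deviation is also zero the sample is
    degenerate and an error is raised.
    """
    iqr = sample.iqr
    if iqr <= 0.0:
        logger.warning(
            "IQR is zero for %r; falling back to normal-reference bandwidth",
            sample.label or "sample",
        )
        fallback = bandwidth_normal_reference(sample)
        return BandwidthSpec(
            "iqr_rule", h=fallback.h, sigma=fallback.sigma, iqr=iqr
        )
    h = 0.79 * iqr * sample.n ** (-1.0 / 5.0)
    return BandwidthSpec("iqr_rule", h=h, sigma=sample.sigma, iqr=iqr)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def kernel_eval(kernel: KernelSpec, u: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the kernel function K(u)."""
    u = np.asarray(u, dtype=float)
    if kernel.kernel_id == "gaussian":
        out = np.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
    elif kernel.kernel_id == "uniform":
        out = np.where(np.abs(u) <= 1.0, 0.5, 0.0)
    else:  # pragma: no cover - KernelSpec.from_id guards this
        raise ConfigurationError(f"unknown kernel_id: {kernel.kernel_id!r}")
    return float(out) if out.ndim == 0 else out


def _kernel_support(kernel: KernelSpec) -> float:
    """Half-width (in u units) beyond which kernel terms are dropped."""
    return _GAUSS_CUTOFF if kernel.kernel_id == "gaussian" else 1.0


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _windowed_fixed_sum(
    sorted_values: np.ndarray,
    points: np.ndarray,
    h: float,
    kernel: KernelSpec,
) -> np.ndarray:
    """Sum K((x - X_i)/h) over i, exactly, using sorted-window blocks.

    Observations outside the kernel's numerical support contribute terms
    below double-precision resolution (Gaussian) or exactly zero (uniform)
    and are skipped.  Points are processed in blocks sized so that the
    temporary (block x window) matrix stays small.
    """
    n = sorted_values.size
    out = np.empty(points.size, dtype=float)
    order = np.argsort(points, kind="stable")
    sp = points[order]
    reach = _kernel_support(kernel) * h

    start = 0
    while start < sp.size:
        # grow the block while the shared window stays within budget
        lo_idx = np.searchsorted(sorted_values, sp[start] - reach, side="left")
        end = start + 1
        hi_idx = np.searchsorted(sorted_values, sp[start] + reach, side="right")
        while end < sp.size:
            cand_hi = np.searchsorted(sorted_values, sp[end] + reach, side="right")
            if (end - start + 1) * max(cand_hi - lo_idx, 1) > _BLOCK_BUDGET:
                break
            hi_idx = cand_hi
            end += 1
        window = sorted_values[lo_idx:hi_idx]
        if window.size == 0:
            out[order[start:end]] = 0.0
        else:
            u = (sp[start:end, None] - window[None, :]) / h
            out[order[start:end]] = kernel_eval(kernel, u).sum(axis=1)
        start = end
    return out


def density_at(
    sample: Sample,
    points: Sequence[float] | np.ndarray,
    kernel: KernelSpec = GAUSSIAN,
    bw: BandwidthSpec | float | None = None,
) -> np.ndarray:
    """Fixed-bandwidth kernel density estimate at ``points``.

    Implements f_hat(x) = (1/(n h)) * sum_i K((x - X_i)/h); when a point
    coincides with an observation the observation's own kernel term is
    included.  ``bw`` may be a :class:`BandwidthSpec`, a plain bandwidth,
    or ``None`` for the IQR rule.
    """
    points = np.asarray(points, dtype=float).ravel()
    if points.size == 0:
        return np.empty(0)
    if bw is None:
        bw = bandwidth_iqr(sample)
    h = float(bw.h) if isinstance(bw, BandwidthSpec) else float(bw)
    if h <= 0:
        raise ParameterError("bandwidth h must be positive")
    sorted_values = np.sort(sample.values)
    sums = _windowed_fixed_sum(sorted_values, points, h, kernel)
    return sums / (sample.n * h)


def _knn_distances(sorted_values: np.ndarray, points: np.ndarray, k: int) -> np.ndarray:
    """Distance to the k-th nearest observation for each point."""
    n = sorted_values.size
    d = np.empty(points.size)
    for j, x in enumerate(points):
        pos = np.searchsorted(sorted_values, x)
        lo = max(0, pos - k)
        hi = min(n, pos + k)
        dist = np.abs(sorted_values[lo:hi] - x)
        if dist.size > k:
            d[j] = np.partition(dist, k - 1)[k - 1]
        else:
            d[j] = np.max(dist)
    return d


def density_knn(
    sample: Sample,
    points: Sequence[float] | np.ndarray,
    k: int,
    kernel: KernelSpec = GAUSSIAN,
) -> np.ndarray:
    """Adaptive kNN kernel estimate with local bandwidth d_k(x).

    f_hat(x) = (1/(n d_k(x))) * sum_i K((x - X_i)/d_k(x)), where d_k(x)
    is the distance from x to its k-th nearest observation.  Where d_k(x)
    is zero (at least k duplicate observations at x) the smallest positive
    inter-point distance is substituted and a warning logged; a fully
    degenerate sample raises an error.
    """
    points = np.asarray(points, dtype=float).ravel()
    if not (1 <= k <= sample.n):
        raise ParameterError(f"k must be in [1, n={sample.n}], got {k}")
    if points.size == 0:
        return np.empty(0)
    sorted_values = np.sort(sample.values)
    gaps = np.diff(sorted_values)
    positive_gaps = gaps[gaps > 0]
    if positive_gaps.size == 0:
        raise DegenerateSampleError("all observations identical: d_k is zero everywhere")
    min_gap = float(positive_gaps.min())

    d = _knn_distances(sorted_values, points, k)
    zero = d <= 0.0
    if np.any(zero):
        logger.warning(
            "d_k(x) = 0 at %d evaluation point(s) (>= k duplicates); "
            "substituting smallest positive inter-point distance %g",
            int(zero.sum()),
            min_gap,
        )
        d = np.where(zero, min_gap, d)

    out = np.empty(points.size)
    for j, (x, dk) in enumerate(zip(points, d)):
        u = (x - sample.values) / dk
        out[j] = kernel_eval(kernel, u).sum() / (sample.n * dk)
    return out


def density_two_step(
    sample: Sample,
    points: Sequence[float] | np.ndarray,
    kernel: KernelSpec = GAUSSIAN,
    pilot_bw: BandwidthSpec | None = None,
) -> np.ndarray:
    """Two-step (Abramson) variable-kernel estimate.

    A fixed-bandwidth pilot estimate (IQR rule) is evaluated at the
    observations; each observation then receives a local bandwidth
    h_i = h * (f_pilot(X_i)/g)**(-1/2) with g the geometric mean of the
    pilot densities, and the final estimate averages kernels with those
    per-observation bandwidths.  Zero pilot densities are floored to the
    smallest positive pilot value (logged) so the geometric mean exists.
    """
    points = np.asarray(points, dtype=float).ravel()
    if sample.n < 2:
        raise ParameterError("two-step estimator needs n >= 2")
    if points.size == 0:
        return np.empty(0)
    if pilot_bw is None:
        pilot_bw = bandwidth_iqr(sample)
    pilot = density_at(sample, sample.values, kernel, pilot_bw)
    if np.any(pilot <= 0.0):
        floor = pilot[pilot > 0.0].min() if np.any(pilot > 0.0) else np.finfo(float).tiny
        logger.warning(
            "two-step pilot density zero at %d observation(s); flooring to %g",
            int((pilot <= 0.0).sum()),
            floor,
        )
        pilot = np.maximum(pilot, floor)
    g = float(np.exp(np.mean(np.log(pilot))))
    local_h = pilot_bw.h * np.sqrt(g / pilot)

    out = np.empty(points.size)
    for j, x in enumerate(points):
        u = (x - sample.values) / local_h
        out[j] = np.sum(kernel_eval(kernel, u) / local_h) / sample.n
    return out


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_density(
    sample: Sample,
    kernel: KernelSpec | str = GAUSSIAN,
    bandwidth: str | BandwidthSpec = "iqr",
    k: int | None = None,
    grid_size: int = 1024,
    clip_to_limits: bool = True,
) -> DensityModel:
    """Fit a density model: exact point densities plus a grid curve.

    ``bandwidth`` is one of ``"iqr"``, ``"normal"``, ``"knn"`` (with ``k``,
    default 2% of n), ``"twostep"``, or a ready :class:`BandwidthSpec`.
    The grid spans [min - 3h, max + 3h] (h from the IQR rule), clipped to
    the sample's natural limits unless ``clip_to_limits`` is false.
    """
    if isinstance(kernel, str):
        kernel = KernelSpec.from_id(kernel)

    pad_bw = bandwidth_iqr(sample)

    if isinstance(bandwidth, BandwidthSpec):
        bw = bandwidth
        method = bw.method
    elif bandwidth in ("iqr", "iqr_rule"):
        bw = pad_bw
        method = "iqr_rule"
    elif bandwidth in ("normal", "normal_reference"):
        bw = bandwidth_normal_reference(sample)
        method = "normal_reference"
    elif bandwidth == "knn":
        kk = k if k is not None else max(1, round(0.02 * sample.n))
        bw = BandwidthSpec("knn", k=kk, sigma=sample.sigma, iqr=sample.iqr)
        method = "knn"
    elif bandwidth in ("twostep", "two_step"):
        bw = BandwidthSpec(
            "two_step", h=pad_bw.h, sigma=sample.sigma, iqr=sample.iqr
        )
        method = "two_step"
    else:
        raise ConfigurationError(f"unknown bandwidth method: {bandwidth!r}")

    if method in ("iqr_rule", "normal_reference"):
        def evaluate(pts: np.ndarray, _bw=bw, _kern=kernel) -> np.ndarray:
            return density_at(sample, pts, _kern, _bw)
    elif method == "knn":
        def evaluate(pts: np.ndarray, _k=bw.k, _kern=kernel) -> np.ndarray:
            return density_knn(sample, pts, _k, _kern)
    else:
        def evaluate(pts: np.ndarray, _kern=kernel, _pilot=pad_bw) -> np.ndarray:
            return density_two_step(sample, pts, _kern, _pilot)

    lo = float(sample.values.min()) - 3.0 * pad_bw.h
    hi = float(sample.values.max()) + 3.0 * pad_bw.h
    if clip_to_limits:
        if sample.lower_limit is not None:
            lo = max(lo, sample.lower_limit)
        if sample.upper_limit is not None:
            hi = min(hi, sample.upper_limit)
    grid = np.linspace(lo, hi, grid_size)

    point_densities = evaluate(sample.values)
    grid_densities = evaluate(grid)
    return DensityModel(
        sample=sample,
        kernel=kernel,
        bandwidth=bw,
        point_densities=point_densities,
        grid=grid,
        grid_densities=grid_densities,
        evaluate=evaluate,
    )


def integrate_model(model: DensityModel) -> float:
    """Trapezoid integral of the fitted curve on an unclipped wide grid.

    Natural-limit clipping removes kernel mass that spills past a bound
    (no boundary correction is applied by design), so normalisation is
    checked on the unclipped span [min - 3h, max + 3h].
    """
    s = model.sample
    h = bandwidth_iqr(s).h
    grid = np.linspace(s.values.min() - 3.0 * h, s.values.max() + 3.0 * h, model.grid.size)
    dens = model.evaluate(grid)
    return float(np.trapezoid(dens, grid))


# ---------------------------------------------------------------------------
# density variance and the two-point difference test
# ---------------------------------------------------------------------------

def density_variance(
    fhat: float,
    n: int,
    h: float,
    kernel: KernelSpec = GAUSSIAN,
    constant: Literal["roughness", "second_moment"] = "roughness",
) -> DensityVariance:
    """Approximate variance of a kernel density estimate at a point.

    var(f_hat(x)) ~= f_hat(x) * c_K / (n h), with c_K the kernel roughness
    integral K(t)^2 dt (Gaussian: 1/(2 sqrt(pi))).  ``constant`` selects
    the kernel second moment integral t^2 K(t) dt instead (Gaussian: 1),
    an alternative normalising constant seen in some treatments.
    """
    if h <= 0:
        raise ParameterError("bandwidth h must be positive")
    if fhat < 0 or n < 1:
        raise ParameterError("need fhat >= 0 and n >= 1")
    c = kernel.roughness if constant == "roughness" else kernel.second_moment
    return DensityVariance(fhat=float(fhat), var=float(fhat) * c / (n * h), n=n, h=h)


def density_difference_test(
    a: DensityVariance, b: DensityVariance, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-sided z-test for a difference between two density estimates.

    Returns ``(significant, z)`` with z = (f_a - f_b)/sqrt(var_a + var_b).
    Equal estimates with zero variance give z = 0 by convention; unequal
    estimates with zero total variance are degenerate.
    """
    se2 = a.var + b.var
    if se2 <= 0.0:
        if a.fhat == b.fhat:
            return False, 0.0
        raise DegenerateSampleError(
            "zero variance with unequal density estimates: test undefined"
        )
    z = (a.fhat - b.fhat) / math.sqrt(se2)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return bool(abs(z) > crit), float(z)
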