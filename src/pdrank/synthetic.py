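"""Seeded generators for the distribution shapes typical of archive metrics.

Structural-biology archive metrics are rarely textbook-Normal: they are
bounded, skewed and sometimes multimodal, with long one-sided tails.
Five canonical shapes cover the cases the analysis methods must handle:

``normal``
    A plain Gaussian — the reference case where density ranking must
    agree with the classical Z-score / Tukey / percentile rules.
``skewed_bounded``
    A lognormal-like metric with a hard lower limit at 0 and a long
    right tail (clash-score-like).
``zero_inflated``
    A point mass sitting exactly on the natural lower limit 0 plus an
    exponential-like tail within [0, 1] (fraction-of-violations-like);
    the mode is the bound itself.
``multimodal``
    A two-component Gaussian mixture above a lower limit of 1
    (multiplicity-like), where single-interval spread measures mislead.
``clustered_tail``
    A lognormal bulk plus a small, distant high-value cluster
    (molecular-weight-like), producing structure inside the outlier tail.

Every generator is deterministic given its seed, and generated values
respect the declared natural limits exactly (rejection sampling, never
silent clipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, ParameterError
from .kde import Sample

SHAPES = ("normal", "skewed_bounded", "zero_inflated", "multimodal", "clustered_tail")

#: Canonical parameters for each shape; fixtures, not fitted archive values.
_DEFAULTS: dict[str, dict[str, float]] = {
    "normal": {"loc": 0.0, "scale": 1.0},
    "skewed_bounded": {"mu_log": 1.5, "sigma_log": 0.8},
    "zero_inflated": {"p0": 0.4, "tail_scale": 0.02},
    "multimodal": {
        "weight1": 0.6, "loc1": 4.0, "scale1": 0.7,
        "loc2": 7.0, "scale2": 0.5,
    },
    "clustered_tail": {
        "bulk_fraction": 0.95, "mu_log": 2.0, "sigma_log": 0.6,
        "cluster_loc": 60.0, "cluster_scale": 1.5,
    },
}


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters for one synthetic sample."""

    shape_id: str
    n: int
    seed: int
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape_id not in SHAPES:
            raise ConfigurationError(f"unknown shape_id: {self.shape_id!r}")
        if self.n < 1:
            raise ParameterError("n must be at least 1")
        merged = dict(_DEFAULTS[self.shape_id])
        merged.update(self.params)
        if self.shape_id == "zero_inflated" and not (0.0 <= merged["p0"] < 1.0):
            raise ParameterError("p0 must be in [0, 1)")
        if self.shape_id == "multimodal" and not (0.0 < merged["weight1"] < 1.0):
            raise ParameterError("weight1 must be in (0, 1)")
        object.__setattr__(self, "params", merged)


def _truncated(draw, rng: np.random.Generator, n: int, lower: float) -> np.ndarray:
    """Draw n values >= lower by rejection."""
    out = np.empty(0)
    while out.size < n:
        chunk = draw(rng, n - out.size)
        out = np.concatenate([out, chunk[chunk >= lower]])
    return out[:n]


def generate(spec: ShapeSpec) -> Sample:
    """Generate one seeded sample of the requested shape."""
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    sid = spec.shape_id

    if sid == "normal":
        values = rng.normal(p["loc"], p["scale"], spec.n)
        lower, upper = None, None
    elif sid == "skewed_bounded":
        values = rng.lognormal(p["mu_log"], p["sigma_log"], spec.n)
        lower, upper = 0.0, None
    elif sid == "zero_inflated":
        at_bound = rng.random(spec.n) < p["p0"]
        tail = rng.exponential(p["tail_scale"], spec.n)
        # tail values must stay within the metric's [0, 1] range
        while np.any(tail >= 1.0):
            redraw = tail >= 1.0
            tail[redraw] = rng.exponential(p["tail_scale"], int(redraw.sum()))
        values = np.where(at_bound, 0.0, tail)
        lower, upper = 0.0, 1.0
    elif sid == "multimodal":
        comp1 = rng.random(spec.n) < p["weight1"]
        lower = 1.0

        def draw1(r, m):
            return r.normal(p["loc1"], p["scale1"], m)

        def draw2(r, m):
            return r.normal(p["loc2"], p["scale2"], m)

        v1 = _truncated(draw1, rng, int(comp1.sum()), lower)
        v2 = _truncated(draw2, rng, spec.n - int(comp1.sum()), lower)
        values = np.empty(spec.n)
        values[comp1] = v1
        values[~comp1] = v2
        upper = None
    elif sid == "clustered_tail":
        in_bulk = rng.random(spec.n) < p["bulk_fraction"]
        bulk = rng.lognormal(p["mu_log"], p["sigma_log"], spec.n)
        lower = 0.0

        def draw_cluster(r, m):
            return r.normal(p["cluster_loc"], p["cluster_scale"], m)

        cluster = _truncated(draw_cluster, rng, spec.n - int(in_bulk.sum()), lower)
        values = np.empty(spec.n)
        values[in_bulk] = bulk[in_bulk]
        values[~in_bulk] = cluster
        upper = None
    else:  # pragma: no cover - ShapeSpec guards this
        raise ConfigurationError(f"unknown shape_id: {sid!r}")

    return Sample(values, lower_limit=lower, upper_limit=upper, label=sid)


def fixture_suite(seed: int, n: int = 10_000) -> dict[str, Sample]:
    """One canonical sample per shape, deterministic in ``seed``.

    Per-shape substreams are derived from the global seed so that the
    shapes stay independent of each other and of the shape ordering.
    """
    root = np.random.SeedSequence(seed)
    out: dict[str, Sample] = {}
    for shape, child in zip(SHAPES, root.spawn(len(SHAPES))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out[shape] = generate(ShapeSpec(shape_id=shape, n=n, seed=sub_seed))
    return out
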