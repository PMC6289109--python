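"""Independent brute-force oracles: literal double-loop formula evaluations.

These deliberately avoid every vectorised or windowed code path in the
package so they can serve as an independent reference for the estimators.
"""

import math

import numpy as np


def kernel(u: float, kernel_id: str = "gaussian") -> float:
    if kernel_id == "gaussian":
        return math.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
    return 0.5 if abs(u) <= 1.0 else 0.0


def fixed_kde(values, points, h, kernel_id="gaussian"):
    """f(x) = (1/(n h)) sum_i K((x - X_i)/h), one term at a time."""
    n = len(values)
    out = []
    for x in points:
        total = 0.0
        for xi in values:
            total += kernel((x - xi) / h, kernel_id)
        out.append(total / (n * h))
    return np.array(out)


def knn_kde(values, points, k, kernel_id="gaussian"):
    """Adaptive estimate with bandwidth = distance to k-th nearest point."""
    n = len(values)
    out = []
    for x in points:
        d = sorted(abs(x - xi) for xi in values)[k - 1]
        total = 0.0
        for xi in values:
            total += kernel((x - xi) / d, kernel_id)
        out.append(total / (n * d))
    return np.array(out)


def two_step_kde(values, points, h, kernel_id="gaussian"):
    """Abramson variable kernel with geometric-mean pilot normalisation."""
    n = len(values)
    pilot = fixed_kde(values, values, h, kernel_id)
    g = math.exp(sum(math.log(p) for p in pilot) / n)
    local = [h * math.sqrt(g / p) for p in pilot]
    out = []
    for x in points:
        total = 0.0
        for xi, hi in zip(values, local):
            total += kernel((x - xi) / hi, kernel_id) / hi
        out.append(total / n)
    return np.array(out)
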