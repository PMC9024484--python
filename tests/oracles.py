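"""Independent brute-force reference implementations used only by the
test suite.

These deliberately use plain Python loops, dict counting and explicit
enumeration — no shared code with the package — so agreement with the
vectorised implementations is a meaningful check.
"""

from __future__ import annotations

import math
from itertools import combinations


def _symbol(d: float, delta: float, gamma: float) -> int:
    if abs(d) <= delta:
        return 0
    if d > gamma:
        return 2
    if d > delta:
        return 1
    if d < -gamma:
        return -2
    return -1


def naive_slope_entropy(x, m: int, gamma: float, delta: float = 0.001) -> float:
    """Pattern-enumeration Slope Entropy."""
    x = list(map(float, x))
    counts: dict[tuple, int] = {}
    for i in range(len(x) - m + 1):
        sub = x[i : i + m]
        pat = tuple(_symbol(sub[k] - sub[k + 1], delta, gamma) for k in range(m - 1))
        counts[pat] = counts.get(pat, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def _cheb(x, i: int, j: int, m: int) -> float:
    return max(abs(x[i + k] - x[j + k]) for k in range(m))


def naive_apen(x, m: int, r: float) -> float:
    """Double-loop Approximate Entropy, self-matches included."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        t = n - mm + 1
        total = 0.0
        for i in range(t):
            cnt = sum(1 for j in range(t) if _cheb(x, i, j, mm) <= r)
            total += math.log(cnt / t)
        return total / t

    return phi(m) - phi(m + 1)


def naive_sampen(x, m: int, r: float):
    """Double-loop Sample Entropy; returns None when undefined."""
    x = list(map(float, x))
    n = len(x)
    t = n - m
    b = sum(
        1
        for i in range(t)
        for j in range(t)
        if i != j and _cheb(x, i, j, m) <= r
    )
    a = sum(
        1
        for i in range(t)
        for j in range(t)
        if i != j and _cheb(x, i, j, m + 1) <= r
    )
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def naive_apen_diagnostics(x, m: int, r: float) -> tuple[float, float]:
    """Brute-force weak/strong match-criterion percentages."""
    x = list(map(float, x))
    t = len(x) - m + 1
    counts = [
        sum(1 for j in range(t) if _cheb(x, i, j, m) <= r) for i in range(t)
    ]
    weak = 100.0 * sum(c >= 10 for c in counts) / t
    strong = 100.0 * sum(c >= 100 for c in counts) / t
    return weak, strong


def _u_stat(a, b) -> float:
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


def enumerate_mwu_p(a, b) -> float:
    """Exact two-sided Mann–Whitney p by full enumeration of all
    C(n_a + n_b, n_a) group assignments (tie-free inputs assumed)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    u_obs = _u_stat(a, b)
    dev = abs(u_obs - mu) - 1e-12
    extreme = 0
    total = 0
    idx = set(range(len(pooled)))
    for comb in combinations(range(len(pooled)), n_a):
        aa = [pooled[i] for i in comb]
        bb = [pooled[i] for i in idx - set(comb)]
        if abs(_u_stat(aa, bb) - mu) >= dev:
            extreme += 1
        total += 1
    return extreme / total


def fit_sinusoid_amplitude(values, period: float) -> float:
    """Least-squares amplitude of a sinusoid of known period (plus an
    intercept), via the closed-form normal equations."""
    import numpy as np

    t = np.arange(len(values), dtype=float)
    design = np.column_stack(
        [np.sin(2 * np.pi * t / period), np.cos(2 * np.pi * t / period), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, np.asarray(values, dtype=float), rcond=None)
    return float(math.hypot(coef[0], coef[1]))
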