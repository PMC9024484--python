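"""Entropy estimators for minute-resolution physiological time series.

Implements three regularity / complexity statistics used as scalar
classification features:

* **Slope Entropy (SlpEn)** — symbolic entropy of consecutive-sample
  differences quantised to a 5-symbol alphabet ``{+2, +1, 0, -1, -2}``
  by two thresholds: ``delta`` (near-zero band) and ``gamma`` (steep
  band).  The Shannon entropy (natural log) of the relative frequencies
  of the resulting ``(m-1)``-symbol patterns is returned.
* **Approximate Entropy (ApEn)** — ``phi^m(r) - phi^{m+1}(r)`` with
  Chebyshev-distance template matching and self-matches included.
* **Sample Entropy (SampEn)** — ``-ln(A/B)``, the log-ratio of
  ``(m+1)``- to ``m``-length cross-template match counts, self-matches
  excluded; :data:`UNDEFINED` when no matches exist.

All estimators operate on a gap-free 1-D array.  Tolerances ``r`` and
``gamma`` are interpreted in units of the series' standard deviation,
so inputs are expected to be z-normalised upstream; no internal
rescaling is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SlpEnParams",
    "MatchParams",
    "MatchCounts",
    "UNDEFINED",
    "is_defined",
    "symbolize_slopes",
    "slope_entropy",
    "slope_entropy_grid",
    "approximate_entropy",
    "sample_entropy",
    "matching_entropy_grid",
    "apen_match_diagnostics",
    "recommended_min_length",
]

#: Alphabet used by the slope symbolisation, for reference.
SLOPE_ALPHABET = (-2, -1, 0, 1, 2)


class _UndefinedEntropy:
    """Sentinel for an undefined SampEn (no template matches).

    Falsy and unequal to every number; callers treat it as a missing
    value rather than an error.
    """

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _UndefinedEntropy()


def is_defined(value: object) -> bool:
    """True unless *value* is the :data:`UNDEFINED` sentinel."""
    return value is not UNDEFINED


@dataclass(frozen=True)
class SlpEnParams:
    """Slope Entropy parameters: embedding dimension and the two slope
    thresholds.  Requires ``m >= 2`` and ``0 < delta < gamma``."""

    m: int
    gamma: float
    delta: float = 0.001

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be >= 2, got {self.m}")
        if not (0.0 < self.delta < self.gamma):
            raise ValueError(
                f"thresholds must satisfy 0 < delta < gamma, got "
                f"delta={self.delta}, gamma={self.gamma}"
            )


@dataclass(frozen=True)
class MatchParams:
    """Template-matching parameters for ApEn/SampEn: embedding dimension
    ``m`` and Chebyshev tolerance ``r`` (in SD units)."""

    m: int
    r: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"tolerance r must be > 0, got {self.r}")


@dataclass(frozen=True)
class MatchCounts:
    """Per-template match counters underlying ApEn.

    ``b_i`` counts matches (self included) at dimension ``m`` over the
    ``N-m+1`` templates; ``a_i`` at dimension ``m+1`` over ``N-m``.
    ``phi_m`` / ``phi_m1`` are the averaged log relative frequencies.
    """

    b_i: np.ndarray
    a_i: np.ndarray
    phi_m: float
    phi_m1: float


def _as_series(x: object) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("input series is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input series contains NaN/inf; repair gaps upstream")
    return arr


def _slope_symbols(diffs: np.ndarray, delta: float, gamma: float) -> np.ndarray:
    """Map differences to the 5-symbol alphabet.

    The zero band is closed (``|d| <= delta``); the ±1 bands are
    half-open (``delta < d <= gamma``); ±2 beyond.  Ties are
    measure-zero for continuous data.
    """
    sym = np.zeros(diffs.shape, dtype=np.int8)
    sym[diffs > delta] = 1
    sym[diffs > gamma] = 2
    sym[diffs < -delta] = -1
    sym[diffs < -gamma] = -2
    return sym


def symbolize_slopes(x: np.ndarray, p: SlpEnParams) -> np.ndarray:
    """Symbolise the slopes of all length-``m`` subsequences of *x*.

    Differences follow the earlier-minus-later convention
    ``y_i = x_i - x_{i+1}``; the entropy is invariant to the opposite
    convention because negation permutes the alphabet bijectively.

    Returns an ``(N - m + 1, m - 1)`` int8 array, one symbol pattern per
    subsequence.
    """
    arr = _as_series(x)
    n = arr.size
    if n < p.m:
        raise ValueError(f"series of length {n} too short for m={p.m}")
    diffs = arr[:-1] - arr[1:]
    sym = _slope_symbols(diffs, p.delta, p.gamma)
    return sliding_window_view(sym, p.m - 1).copy()


def _pattern_entropy(codes: np.ndarray, normalize: bool, max_patterns: int) -> float:
    _, counts = np.unique(codes, return_counts=True)
    # sort so the value depends only on the count multiset: makes
    # symmetries (e.g. under negation) hold to the last bit
    freqs = np.sort(counts) / codes.size
    h = float(-np.sum(freqs * np.log(freqs))) + 0.0  # avoid -0.0
    if normalize:
        denom = math.log(min(max_patterns, codes.size))
        h = h / denom if denom > 0 else 0.0
    return h


def _encode_patterns(sym: np.ndarray, m: int) -> np.ndarray:
    # base-5 integer code per (m-1)-symbol pattern
    windows = sliding_window_view(sym.astype(np.int64) + 2, m - 1)
    weights = 5 ** np.arange(m - 1, dtype=np.int64)
    return windows @ weights


def slope_entropy(x: np.ndarray, p: SlpEnParams, *, normalize: bool = False) -> float:
    """Slope Entropy of *x*: Shannon entropy (nats) of the relative
    frequencies of the observed slope patterns.

    Non-negative; zero iff a single distinct pattern occurs.  With
    ``normalize=True`` the value is divided by the log of the maximum
    attainable pattern count ``min(5^(m-1), N-m+1)`` for cross-tool
    comparison; the raw value is the default.
    """
    arr = _as_series(x)
    n = arr.size
    if n < p.m:
        raise ValueError(f"series of length {n} too short for m={p.m}")
    diffs = arr[:-1] - arr[1:]
    sym = _slope_symbols(diffs, p.delta, p.gamma)
    codes = _encode_patterns(sym, p.m)
    return _pattern_entropy(codes, normalize, 5 ** (p.m - 1))


def slope_entropy_grid(
    x: np.ndarray,
    m_values: "np.ndarray | list[int]",
    gamma_values: "np.ndarray | list[float]",
    delta: float = 0.001,
    *,
    normalize: bool = False,
) -> np.ndarray:
    """Slope Entropy over a full ``(m, gamma)`` grid in one pass.

    Symbolises the difference sequence once per gamma and reuses it for
    every embedding dimension, which is what makes whole-grid searches
    over cohorts affordable.  Returns an array of shape
    ``(len(m_values), len(gamma_values))``.
    """
    arr = _as_series(x)
    m_values = list(m_values)
    diffs = arr[:-1] - arr[1:]
    out = np.empty((len(m_values), len(gamma_values)))
    for j, gamma in enumerate(gamma_values):
        if not (0.0 < delta < gamma):
            raise ValueError(f"need 0 < delta < gamma, got delta={delta}, gamma={gamma}")
        sym = _slope_symbols(diffs, delta, gamma)
        for i, m in enumerate(m_values):
            if arr.size < m:
                raise ValueError(f"series of length {arr.size} too short for m={m}")
            codes = _encode_patterns(sym, m)
            out[i, j] = _pattern_entropy(codes, normalize, 5 ** (m - 1))
    return out


def _chebyshev_template_distances(x: np.ndarray, m: int) -> np.ndarray:
    """(N-m+1) x (N-m+1) matrix of Chebyshev distances between all
    length-m templates, built incrementally from the scalar distances."""
    n = x.size
    t = n - m + 1
    d0 = np.abs(x[:, None] - x[None, :])
    dist = d0[:t, :t].copy()
    for k in range(1, m):
        np.maximum(dist, d0[k : k + t, k : k + t], out=dist)
    return dist


def _self_match_counts(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """Per-template match counts at dimension m, self-match included
    (matches are d <= r), over all N-m+1 templates."""
    dist = _chebyshev_template_distances(x, m)
    return (dist <= r).sum(axis=1)


def apen_match_counts(x: np.ndarray, p: MatchParams) -> MatchCounts:
    """The raw ApEn counters ``B_i``, ``A_i`` and averaged log
    frequencies ``phi^m``, ``phi^{m+1}`` (self-matches included)."""
    arr = _as_series(x)
    n = arr.size
    if n < p.m + 2:
        raise ValueError(f"series of length {n} too short for ApEn at m={p.m}")
    b_i = _self_match_counts(arr, p.m, p.r)
    a_i = _self_match_counts(arr, p.m + 1, p.r)
    phi_m = float(np.mean(np.log(b_i / (n - p.m + 1))))
    phi_m1 = float(np.mean(np.log(a_i / (n - p.m))))
    return MatchCounts(b_i=b_i, a_i=a_i, phi_m=phi_m, phi_m1=phi_m1)


def approximate_entropy(x: np.ndarray, p: MatchParams) -> float:
    """Approximate Entropy ``phi^m(r) - phi^{m+1}(r)``.

    Template counts follow the standard convention: ``N-m+1`` templates
    at dimension ``m`` and ``N-m`` at ``m+1``.  Self-matches are
    included, so the result is always finite.
    """
    counts = apen_match_counts(x, p)
    return counts.phi_m - counts.phi_m1


def sample_entropy(x: np.ndarray, p: MatchParams) -> "float | _UndefinedEntropy":
    """Sample Entropy ``-ln(A/B)`` over cross-template matches only.

    Both dimensions use the first ``N-m`` templates so every length-m
    template has a length-(m+1) continuation.  Returns
    :data:`UNDEFINED` (never raises) when either match count is zero.
    """
    arr = _as_series(x)
    n = arr.size
    if n < p.m + 2:
        raise ValueError(f"series of length {n} too short for SampEn at m={p.m}")
    t = n - p.m
    dist_m = _chebyshev_template_distances(arr, p.m)[:t, :t]
    b = int((dist_m <= p.r).sum()) - t
    dist_m1 = _chebyshev_template_distances(arr, p.m + 1)
    a = int((dist_m1 <= p.r).sum()) - t
    if a == 0 or b == 0:
        return UNDEFINED
    return float(-math.log(a / b))


def apen_match_diagnostics(x: np.ndarray, p: MatchParams) -> tuple[float, float]:
    """Reliability diagnostics for ApEn at a given length.

    Returns the percentage of dimension-m templates (self-match
    included) with at least 10 matches (weak criterion) and at least
    100 matches (strong criterion).  Low percentages flag probability
    estimates resting on too few matches.
    """
    arr = _as_series(x)
    if arr.size < p.m + 2:
        raise ValueError(f"series of length {arr.size} too short for m={p.m}")
    b_i = _self_match_counts(arr, p.m, p.r)
    weak = 100.0 * float(np.mean(b_i >= 10))
    strong = 100.0 * float(np.mean(b_i >= 100))
    return weak, strong


def recommended_min_length(m: int) -> int:
    """Common rule-of-thumb minimum series length for a reliable ApEn
    estimate at embedding dimension ``m``: ``10**m`` samples."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 10**m


def matching_entropy_grid(
    x: np.ndarray,
    m_values: "np.ndarray | list[int]",
    r_values: "np.ndarray | list[float]",
) -> tuple[np.ndarray, np.ndarray]:
    """ApEn and SampEn over a full ``(m, r)`` grid sharing one distance
    computation per dimension.

    Returns ``(apen, sampen)`` arrays of shape
    ``(len(m_values), len(r_values))``; undefined SampEn cells are NaN.
    """
    arr = _as_series(x)
    n = arr.size
    m_values = list(m_values)
    r_values = np.asarray(list(r_values), dtype=float)
    max_m = max(m_values)
    if n < max_m + 2:
        raise ValueError(f"series of length {n} too short for m={max_m}")

    dims = sorted({d for m in m_values for d in (m, m + 1)})
    # counts[d][i, k]: matches of template i at dimension d for tolerance r_k,
    # self-match included, over all N-d+1 templates; subtotals[d][k]: total
    # matches over the leading (N-d) x (N-d) submatrix (the SampEn B-count
    # restriction, where both template indices run over the first N-d only)
    counts: dict[int, np.ndarray] = {}
    subtotals: dict[int, np.ndarray] = {}
    d0 = np.abs(arr[:, None] - arr[None, :])
    dist = d0.copy()
    for d in range(1, max(dims) + 1):
        if d > 1:
            t = n - d + 1
            dist = np.maximum(dist[:t, :t], d0[d - 1 :, d - 1 :])
        if d in dims:
            per_r, per_r_sub = [], []
            for r in r_values:
                mask = dist <= r
                per_r.append(mask.sum(axis=1))
                per_r_sub.append(int(mask[: n - d, : n - d].sum()))
            counts[d] = np.stack(per_r, axis=1)
            subtotals[d] = np.asarray(per_r_sub)

    apen = np.empty((len(m_values), r_values.size))
    sampen = np.full((len(m_values), r_values.size), np.nan)
    for i, m in enumerate(m_values):
        b_full, a_full = counts[m], counts[m + 1]
        t_m, t_m1 = n - m + 1, n - m
        apen[i] = np.log(b_full / t_m).mean(axis=0) - np.log(a_full / t_m1).mean(axis=0)
        b_cross = subtotals[m] - (n - m)
        a_cross = a_full.sum(axis=0) - (n - m)
        ok = (b_cross > 0) & (a_cross > 0)
        sampen[i, ok] = -np.log(a_cross[ok] / b_cross[ok])
    return apen, sampen
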