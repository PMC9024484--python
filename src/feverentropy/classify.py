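"""Two-sample evaluation of entropy features and the parameter grid search.

Each grid cell — one entropy method at one ``(m, gamma-or-r)`` setting
and one analysis length ``N`` — yields a single scalar feature per
subject.  The cell is evaluated with:

* a two-sided Wilcoxon–Mann–Whitney test at ``alpha = 0.05`` (exact
  null distribution for small tie-free samples, normal approximation
  with tie and continuity corrections otherwise);
* a ROC curve over the subject features, with orientation (whether low
  or high entropy predicts bacterial infection) selected automatically
  as the direction with AUC >= 0.5;
* sensitivity and specificity at the ROC point closest to the perfect
  corner (0, 1).

The positive class is bacterial infection: sensitivity is the fraction
of bacterial-infection subjects correctly flagged.  p-values are
reported raw (no multiple-testing correction across the grid, which is
how such grid searches are conventionally reported here); an optional
Benjamini–Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .entropy import matching_entropy_grid, slope_entropy_grid
from .preprocess import CleanSeries

__all__ = [
    "ALPHA",
    "DEFAULT_M_VALUES",
    "DEFAULT_TUNE_VALUES",
    "METHODS",
    "RocCurve",
    "OperatingPoint",
    "GridResult",
    "mann_whitney_two_sided",
    "roc_points",
    "closest_to_01_threshold",
    "compute_features",
    "grid_search",
    "results_frame",
    "benjamini_hochberg",
]

ALPHA = 0.05
POSITIVE_LABEL = "bacterial"
METHODS = ("SlpEn", "ApEn", "SampEn")

#: Embedding dimensions searched: m in [3, 9].
DEFAULT_M_VALUES = tuple(range(3, 10))
#: Tolerance / slope-threshold grid: 0.10 to 0.90 in steps of 0.05.
DEFAULT_TUNE_VALUES = tuple(np.round(np.linspace(0.10, 0.90, 17), 2))
#: Near-zero slope band, held constant throughout the search.
DEFAULT_DELTA = 0.001

_EXACT_MAX_TOTAL = 25


def mann_whitney_two_sided(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Uses the exact null distribution when ``len(a) + len(b) <= 25`` and
    there are no ties across the pooled sample; otherwise the normal
    approximation with tie correction and continuity correction.
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _EXACT_MAX_TOTAL and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve of a scalar feature for the bacterial-positive task.

    ``thresholds`` are on the raw feature scale.  With orientation
    ``"low"`` a subject is called positive when feature <= threshold;
    with ``"high"`` when feature >= threshold.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    orientation: str
    auc: float


def roc_points(features, labels, positive: str = POSITIVE_LABEL) -> RocCurve:
    """ROC curve over all distinct feature values plus the degenerate
    endpoints.

    The orientation is chosen automatically as the direction with
    AUC >= 0.5; a tie (AUC exactly 0.5 both ways) resolves to "low",
    the direction expected when disease lowers signal complexity.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray([1 if lab == positive else 0 for lab in labels])
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("ROC requires both classes present")
    auc_high = roc_auc_score(y, features)
    orientation = "high" if auc_high > 0.5 else "low"
    score = features if orientation == "high" else -features
    fpr, tpr, thr = _sk_roc_curve(y, score, drop_intermediate=False)
    thresholds = thr if orientation == "high" else -thr
    auc = auc_high if orientation == "high" else 1.0 - auc_high
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, orientation=orientation, auc=float(auc))


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    se: float
    sp: float
    distance: float


def closest_to_01_threshold(roc: RocCurve) -> OperatingPoint:
    """Operating point minimising the Euclidean distance
    ``sqrt((1 - Se)^2 + (1 - Sp)^2)`` to the perfect corner (0, 1).

    Ties (within 1e-12) break towards higher sensitivity, then higher
    specificity, then lower threshold, so the output is deterministic.
    """
    d2 = roc.fpr**2 + (1.0 - roc.tpr) ** 2
    best = None
    for i in range(d2.size):
        key = (round(float(d2[i]), 12), -roc.tpr[i], roc.fpr[i], roc.thresholds[i])
        if best is None or key < best[0]:
            best = (key, i)
    i = best[1]
    return OperatingPoint(
        threshold=float(roc.thresholds[i]),
        se=float(roc.tpr[i]),
        sp=float(1.0 - roc.fpr[i]),
        distance=float(math.sqrt(d2[i])),
    )


@dataclass(frozen=True)
class GridResult:
    """One cell of the parameter grid: the row type of the headline
    result tables (method, N, parameter pair, p, Se, Sp)."""

    method: str
    n: int
    m: int
    tune: float
    p_value: float
    u_stat: float
    threshold: float
    se: float
    sp: float
    orientation: str
    auc: float
    n_bacterial: int
    n_other: int
    n_excluded: int
    evaluable: bool

    @property
    def significant(self) -> bool:
        return self.evaluable and self.p_value < ALPHA


def compute_features(
    cohort: "list[CleanSeries]",
    methods,
    m_values=DEFAULT_M_VALUES,
    tune_values=DEFAULT_TUNE_VALUES,
    delta: float = DEFAULT_DELTA,
) -> dict[str, np.ndarray]:
    """Per-subject entropy features over the whole grid.

    Returns ``{method: array(n_subjects, len(m_values), len(tune_values))}``.
    ApEn and SampEn share one template-distance computation per subject.
    Undefined SampEn cells are NaN.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    out = {
        meth: np.empty((len(cohort), len(m_values), len(tune_values)))
        for meth in methods
    }
    need_match = bool({"ApEn", "SampEn"} & set(methods))
    for k, series in enumerate(cohort):
        if "SlpEn" in methods:
            out["SlpEn"][k] = slope_entropy_grid(series.values, m_values, tune_values, delta)
        if need_match:
            apen, sampen = matching_entropy_grid(series.values, m_values, tune_values)
            if "ApEn" in methods:
                out["ApEn"][k] = apen
            if "SampEn" in methods:
                out["SampEn"][k] = sampen
    return out


def _evaluate_cell(
    features: np.ndarray, labels: "list[str]", method: str, n: int, m: int, tune: float
) -> GridResult:
    defined = np.isfinite(features)
    feats = features[defined]
    labs = [lab for lab, keep in zip(labels, defined) if keep]
    n_excl = int((~defined).sum())
    n_bact = labs.count("bacterial")
    n_other = labs.count("other")
    if n_bact == 0 or n_other == 0:
        return GridResult(
            method=method, n=n, m=m, tune=tune, p_value=float("nan"),
            u_stat=float("nan"), threshold=float("nan"), se=float("nan"),
            sp=float("nan"), orientation="", auc=float("nan"),
            n_bacterial=n_bact, n_other=n_other, n_excluded=n_excl, evaluable=False,
        )
    a = feats[[lab == "bacterial" for lab in labs]]
    b = feats[[lab == "other" for lab in labs]]
    u, p = mann_whitney_two_sided(a, b)
    roc = roc_points(feats, labs)
    op = closest_to_01_threshold(roc)
    return GridResult(
        method=method, n=n, m=m, tune=tune, p_value=p, u_stat=u,
        threshold=op.threshold, se=op.se, sp=op.sp,
        orientation=roc.orientation, auc=roc.auc,
        n_bacterial=n_bact, n_other=n_other, n_excluded=n_excl, evaluable=True,
    )


def grid_search(
    cohort: "list[CleanSeries]",
    method: str,
    n: "int | None" = None,
    m_values=DEFAULT_M_VALUES,
    tune_values=DEFAULT_TUNE_VALUES,
    delta: float = DEFAULT_DELTA,
    features: "np.ndarray | None" = None,
) -> list[GridResult]:
    """Evaluate one entropy method over the full ``(m, tune)`` grid.

    ``cohort`` must already be length-filtered, trimmed and normalised
    at a single N.  Subjects with an undefined feature (SampEn without
    matches) are dropped from the affected cell only; a cell that loses
    an entire class is marked not evaluable.  Precomputed ``features``
    (from :func:`compute_features`) may be passed to avoid recomputation.
    """
    if not cohort:
        raise ValueError("empty cohort")
    lengths = {s.n for s in cohort}
    if len(lengths) != 1:
        raise ValueError(f"cohort mixes lengths {sorted(lengths)}; filter/trim first")
    n = n if n is not None else lengths.pop()
    labels = [s.label for s in cohort]
    if not ({"bacterial", "other"} <= set(labels)):
        raise ValueError("cohort must contain both classes")
    if features is None:
        features = compute_features(cohort, [method], m_values, tune_values, delta)[method]
    results = []
    for i, m in enumerate(m_values):
        for j, tune in enumerate(tune_values):
            results.append(
                _evaluate_cell(features[:, i, j], labels, method, n, int(m), float(tune))
            )
    return results


def results_frame(results: "list[GridResult]") -> pd.DataFrame:
    """Tidy table of grid results, one row per cell."""
    rows = [
        {
            "method": r.method, "N": r.n, "m": r.m, "tune": r.tune,
            "p": r.p_value, "U": r.u_stat, "threshold": r.threshold,
            "Se": r.se, "Sp": r.sp, "orientation": r.orientation, "auc": r.auc,
            "n_bacterial": r.n_bacterial, "n_other": r.n_other,
            "n_excluded": r.n_excluded, "evaluable": r.evaluable,
            "significant": r.significant,
        }
        for r in results
    ]
    columns = [
        "method", "N", "m", "tune", "p", "U", "threshold", "Se", "Sp",
        "orientation", "auc", "n_bacterial", "n_other", "n_excluded",
        "evaluable", "significant",
    ]
    return pd.DataFrame(rows, columns=columns)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; the headline
    tables report raw p-values)."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if finite.any():
        from statsmodels.stats.multitest import multipletests

        adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return adj
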