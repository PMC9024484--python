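"""Conditioning of raw minute-sampled body-temperature recordings.

The chain applied before any entropy estimation, in this fixed order:

1. :func:`repair_gaps` — linear interpolation of short probe
   disconnections (at most ``max_gap`` consecutive missing samples);
2. :func:`resolve_long_gaps` — keep the longest contiguous clean
   interval when longer disconnections remain, rejecting recordings
   whose clean interval falls below the smallest analysis length;
3. :func:`filter_by_length` — discard recordings shorter than the
   target analysis length ``N``;
4. :func:`trim_central` — keep the central ``N`` samples, the segment
   most likely recorded at thermal equilibrium with the probe in place;
5. :func:`znormalize` — rescale the trimmed window to zero mean and
   unit (population) SD, so entropy tolerances are in SD units.

Normalisation statistics are computed on the trimmed window only, which
guarantees each analysed window is exactly zero-mean/unit-SD.
Missing samples are carried as NaN inside :class:`TemperatureSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LABELS",
    "MIN_ANALYSIS_LENGTH",
    "ANALYSIS_LENGTHS",
    "TemperatureSeries",
    "CleanSeries",
    "SeriesRejected",
    "StationarityProfile",
    "repair_gaps",
    "resolve_long_gaps",
    "trim_central",
    "znormalize",
    "stationarity_profile",
    "filter_by_length",
    "prepare_series",
    "prepare_cohort",
]

LABELS = ("bacterial", "other")

#: Smallest fixed analysis length; shorter clean intervals are rejected.
MIN_ANALYSIS_LENGTH = 500

#: The ladder of fixed lengths used to equalise series across subjects.
ANALYSIS_LENGTHS = (500, 600, 700, 800, 900, 1000, 1100)


class SeriesRejected(Exception):
    """A recording that cannot enter the analysis (typed rejection).

    Carries the subject id and a machine-readable ``reason`` code so
    experiment drivers can log the exclusion and continue.
    """

    def __init__(self, subject_id: str, reason: str, detail: str = ""):
        self.subject_id = subject_id
        self.reason = reason
        self.detail = detail
        super().__init__(f"{subject_id}: {reason}" + (f" ({detail})" if detail else ""))


@dataclass
class TemperatureSeries:
    """One subject's minute-sampled temperature recording (degC).

    ``values`` holds NaN at missing samples (probe disconnections);
    ``label`` is the diagnostic class, ``"bacterial"`` or ``"other"``.
    """

    subject_id: str
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class CleanSeries:
    """A gap-free, fixed-length analysis window with provenance."""

    subject_id: str
    label: str
    values: np.ndarray
    trim_start: int = 0
    trim_stop: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.isnan(self.values).any():
            raise ValueError("CleanSeries cannot contain missing samples")
        if self.trim_stop == 0:
            self.trim_stop = self.trim_start + self.values.size

    @property
    def n(self) -> int:
        return int(self.values.size)


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive True values."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def repair_gaps(s: TemperatureSeries, max_gap: int = 5) -> TemperatureSeries:
    """Fill interior missing runs of length <= ``max_gap`` by linear
    interpolation between the flanking present samples.

    Longer runs, and runs touching the series edges (no flanking value
    on one side), are left missing for :func:`resolve_long_gaps`.
    Present samples are never altered and the length is unchanged.
    """
    mask = s.missing_mask
    if not mask.any():
        return s
    values = s.values.copy()
    for start, stop in _nan_runs(mask):
        run = stop - start
        if run > max_gap or start == 0 or stop == len(values):
            continue  # unrepairable here; handled downstream
        left, right = values[start - 1], values[stop]
        frac = np.arange(1, run + 1) / (run + 1)
        values[start:stop] = left + frac * (right - left)
    return replace(s, values=values)


def resolve_long_gaps(
    s: TemperatureSeries, min_length: int = MIN_ANALYSIS_LENGTH
) -> TemperatureSeries:
    """Reduce a recording with remaining gaps to its longest contiguous
    clean interval.

    Edge gaps are trimmed as a side effect.  Raises
    :class:`SeriesRejected` when the longest clean interval is shorter
    than ``min_length`` (the smallest analysis length), mirroring the
    manual practice of discarding recordings without a usable clean
    segment.  Clean input is returned unchanged.
    """
    mask = s.missing_mask
    if not mask.any():
        return s
    best_start, best_stop = 0, 0
    for start, stop in _nan_runs(~mask):
        if stop - start > best_stop - best_start:
            best_start, best_stop = start, stop
    if best_stop - best_start < min_length:
        raise SeriesRejected(
            s.subject_id,
            "no-clean-interval",
            f"longest clean run {best_stop - best_start} < {min_length}",
        )
    return replace(s, values=s.values[best_start:best_stop].copy())


def trim_central(s: TemperatureSeries, n: int) -> CleanSeries:
    """Keep the central ``n`` consecutive samples, starting at index
    ``floor((L - n) / 2)``.  The output is a verbatim slice (no
    resampling); the trim offsets are recorded for provenance."""
    if s.has_missing:
        raise ValueError("trim_central requires a gap-free series; repair gaps first")
    length = s.n
    if length < n:
        raise ValueError(f"series of length {length} shorter than requested N={n}")
    start = (length - n) // 2
    return CleanSeries(
        subject_id=s.subject_id,
        label=s.label,
        values=s.values[start : start + n].copy(),
        trim_start=start,
        trim_stop=start + n,
    )


def znormalize(c: CleanSeries) -> CleanSeries:
    """Rescale to zero mean and unit population SD (divide by N).

    Raises ``ValueError`` for a constant window (SD = 0).  Idempotent
    up to floating-point round-off.
    """
    sd = float(np.std(c.values))
    if sd == 0.0:
        raise ValueError(f"{c.subject_id}: constant window cannot be z-normalized")
    values = (c.values - float(np.mean(c.values))) / sd
    return replace(c, values=values, normalized=True)


@dataclass
class StationarityProfile:
    """Advisory stationarity summary: SD of each consecutive
    non-overlapping window plus the coefficient of variation of those
    SDs.  Never used to reject a series."""

    window: int
    window_sds: np.ndarray = field(repr=False)

    @property
    def cv(self) -> float:
        mean = float(np.mean(self.window_sds))
        if mean == 0.0:
            return 0.0
        return float(np.std(self.window_sds) / mean)


def stationarity_profile(values: np.ndarray, window: int = 50) -> StationarityProfile:
    """Population SD of each consecutive non-overlapping ``window``-sample
    block (``floor(N / window)`` values); roughly constant SDs indicate
    a stationary variance profile."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < window:
        raise ValueError(f"series of length {arr.size} shorter than window {window}")
    k = arr.size // window
    sds = arr[: k * window].reshape(k, window).std(axis=1)
    return StationarityProfile(window=window, window_sds=sds)


def filter_by_length(
    cohort: "list[TemperatureSeries]", n: int
) -> tuple[list[TemperatureSeries], dict[str, int]]:
    """Retain the series with current length >= ``n``.

    Returns the retained subset and per-class retained counts.  An
    empty result is legal (the caller decides whether the experiment at
    this length is feasible).
    """
    kept = [s for s in cohort if s.n >= n]
    counts = {label: sum(1 for s in kept if s.label == label) for label in LABELS}
    return kept, counts


def prepare_series(s: TemperatureSeries, n: int, max_gap: int = 5) -> CleanSeries:
    """Full conditioning chain for one recording at analysis length ``n``:
    repair short gaps, resolve long ones, check length, trim centrally,
    z-normalize.  Raises :class:`SeriesRejected` when the recording
    cannot supply a clean central window of length ``n``."""
    repaired = repair_gaps(s, max_gap=max_gap)
    resolved = resolve_long_gaps(repaired)
    if resolved.n < n:
        raise SeriesRejected(
            s.subject_id, "too-short", f"clean length {resolved.n} < N={n}"
        )
    return znormalize(trim_central(resolved, n))


def prepare_cohort(
    cohort: "list[TemperatureSeries]", n: int, max_gap: int = 5
) -> tuple[list[CleanSeries], list[SeriesRejected]]:
    """Apply :func:`prepare_series` across a cohort, collecting typed
    exclusions instead of aborting."""
    clean: list[CleanSeries] = []
    excluded: list[SeriesRejected] = []
    for s in cohort:
        try:
            clean.append(prepare_series(s, n, max_gap=max_gap))
        except SeriesRejected as exc:
            excluded.append(exc)
    return clean, excluded
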