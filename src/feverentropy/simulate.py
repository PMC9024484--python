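"""Synthetic two-class body-temperature cohorts.

The clinical recordings this analysis targets are not publicly
available, so this module generates labelled cohorts with the
statistical structure the pipeline assumes:

* a 37 degC baseline with a circadian sinusoid (24 h period);
* sporadic fever episodes — linear rise to a random peak, exponential
  decay — at a Poisson rate per 24 h;
* a stochastic AR(1) component whose lag-1 coefficient ``rho`` differs
  by class: the bacterial-infection class is generated *smoother*
  (higher ``rho``, hence lower entropy) than the other-fever class,
  realising the direction of the clinical effect (disease reduces
  signal complexity).  Both classes share the same stationary SD, so
  z-normalisation cannot separate them by variance, and the same mean
  and fever-amplitude model, so absolute temperature carries no class
  information;
* white measurement noise and probe-disconnection dropouts with
  geometric run lengths.

Per-subject raw lengths default to the published cohort's recording
lengths (10 bacterial + 13 other, 537–1468 minutes).  Every output is
a pure function of the configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import TemperatureSeries

__all__ = [
    "TABLE1_BACTERIAL_LENGTHS",
    "TABLE1_OTHER_LENGTHS",
    "SyntheticCohortConfig",
    "generate_series",
    "generate_cohort",
    "inject_dropouts",
    "table1_cohort_lengths",
]

#: Raw recording lengths (minutes) of the reference cohort, per class.
TABLE1_BACTERIAL_LENGTHS = (936, 1231, 1154, 1279, 1443, 1134, 680, 710, 586, 1117)
TABLE1_OTHER_LENGTHS = (
    1284, 1468, 1427, 1444, 1295, 913, 1105, 1017, 830, 537, 1121, 859, 934,
)

BASELINE_C = 37.0
CLIP_RANGE_C = (34.0, 42.0)
MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters for a labelled temperature cohort.

    Class contrast lives solely in the AR(1) coefficients
    ``rho_bacterial`` / ``rho_other``; all other parameters are shared.
    ``lengths_bacterial`` / ``lengths_other`` default to the reference
    cohort's recording lengths (recycled if more subjects are requested).
    """

    n_bacterial: int = 10
    n_other: int = 13
    lengths_bacterial: tuple = TABLE1_BACTERIAL_LENGTHS
    lengths_other: tuple = TABLE1_OTHER_LENGTHS
    circadian_amplitude_c: float = 0.3
    circadian_period_min: float = float(MINUTES_PER_DAY)
    fever_rate_per_day: float = 1.5
    fever_amplitude_range_c: tuple = (1.0, 3.0)
    fever_rise_min: float = 30.0
    fever_decay_min: float = 120.0
    rho_bacterial: float = 0.98
    rho_other: float = 0.85
    ar_sd_c: float = 0.15
    noise_sd_c: float = 0.05
    dropout_rate: float = 0.01
    dropout_mean_run: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_bacterial", "rho_other"):
            rho = getattr(self, name)
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {rho}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.fever_rise_min <= 0 or self.fever_decay_min <= 0:
            raise ValueError("fever time constants must be > 0")

    def rho_for(self, label: str) -> float:
        return self.rho_bacterial if label == "bacterial" else self.rho_other


def _fever_pulse(t: np.ndarray, onset: float, amplitude: float, rise: float, decay: float) -> np.ndarray:
    """One fever episode: linear rise over ``rise`` minutes to
    ``amplitude`` degC, then exponential decay with time constant
    ``decay`` minutes."""
    dt = t - onset
    pulse = np.zeros_like(t, dtype=float)
    rising = (dt >= 0) & (dt < rise)
    pulse[rising] = amplitude * dt[rising] / rise
    decaying = dt >= rise
    pulse[decaying] = amplitude * np.exp(-(dt[decaying] - rise) / decay)
    return pulse


def _ar1(length: int, rho: float, stationary_sd: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) sample path scaled to a fixed stationary SD, started from
    the stationary distribution."""
    if stationary_sd == 0.0:
        return np.zeros(length)
    innov_sd = stationary_sd * np.sqrt(1.0 - rho**2)
    x = np.empty(length)
    x[0] = rng.normal(0.0, stationary_sd)
    eps = rng.normal(0.0, innov_sd, size=length - 1)
    for t in range(1, length):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def generate_series(
    cfg: SyntheticCohortConfig, label: str, length: int, rng: np.random.Generator
) -> TemperatureSeries:
    """One subject's recording: baseline + circadian sinusoid + fever
    pulses + AR(1) component + white noise, clipped to the physiological
    range 34–42 degC."""
    t = np.arange(length, dtype=float)
    phase = rng.uniform(0.0, cfg.circadian_period_min)
    values = BASELINE_C + cfg.circadian_amplitude_c * np.sin(
        2.0 * np.pi * (t + phase) / cfg.circadian_period_min
    )
    n_episodes = rng.poisson(cfg.fever_rate_per_day * length / MINUTES_PER_DAY)
    for _ in range(n_episodes):
        onset = rng.uniform(-cfg.fever_decay_min, length)
        amplitude = rng.uniform(*cfg.fever_amplitude_range_c)
        values += _fever_pulse(t, onset, amplitude, cfg.fever_rise_min, cfg.fever_decay_min)
    values += _ar1(length, cfg.rho_for(label), cfg.ar_sd_c, rng)
    if cfg.noise_sd_c > 0:
        values += rng.normal(0.0, cfg.noise_sd_c, size=length)
    values = np.clip(values, *CLIP_RANGE_C)
    return TemperatureSeries(subject_id="", label=label, values=values)


def inject_dropouts(
    s: TemperatureSeries, rate: float, mean_run: float, rng: np.random.Generator
) -> TemperatureSeries:
    """Mark probe-disconnection dropouts as missing samples.

    Runs start at uniform positions with geometric lengths of mean
    ``mean_run``; the number of runs is Poisson with mean
    ``rate * N / mean_run``, so the expected missing fraction is about
    ``rate`` (slightly less where runs overlap or hit the end).
    Present samples are never altered.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return s
    n = s.n
    values = s.values.copy()
    n_runs = rng.poisson(rate * n / mean_run)
    for _ in range(n_runs):
        start = int(rng.integers(0, n))
        run = int(rng.geometric(1.0 / mean_run))
        values[start : start + run] = np.nan
    return replace(s, values=values)


def _subject_lengths(cfg: SyntheticCohortConfig, label: str) -> list[int]:
    base = cfg.lengths_bacterial if label == "bacterial" else cfg.lengths_other
    count = cfg.n_bacterial if label == "bacterial" else cfg.n_other
    if not base:
        raise ValueError(f"no length model for class {label!r}")
    return [int(base[i % len(base)]) for i in range(count)]


def generate_cohort(cfg: SyntheticCohortConfig) -> "list[TemperatureSeries]":
    """A full labelled cohort, reproducible from ``cfg.seed``.

    Each subject draws from an independent child random stream, so a
    subject's series depends only on the seed and its index.  With the
    default length model, raw lengths equal the reference cohort's
    recorded values exactly.
    """
    specs = [("bacterial", i, length) for i, length in enumerate(_subject_lengths(cfg, "bacterial"))]
    specs += [("other", i, length) for i, length in enumerate(_subject_lengths(cfg, "other"))]
    streams = np.random.SeedSequence(cfg.seed).spawn(len(specs))
    cohort = []
    for (label, idx, length), stream in zip(specs, streams):
        rng = np.random.default_rng(stream)
        s = generate_series(cfg, label, length, rng)
        s = replace(s, subject_id=f"{'B' if label == 'bacterial' else 'O'}{idx + 1:02d}")
        if cfg.dropout_rate > 0:
            s = inject_dropouts(s, cfg.dropout_rate, cfg.dropout_mean_run, rng)
        cohort.append(s)
    return cohort


def table1_cohort_lengths() -> "list[tuple[str, str, int]]":
    """(subject_id, label, raw length) triples of the reference cohort's
    length table — the fixture used for length-filter checks."""
    rows = [
        (f"B{i + 1:02d}", "bacterial", length)
        for i, length in enumerate(TABLE1_BACTERIAL_LENGTHS)
    ]
    rows += [
        (f"O{i + 1:02d}", "other", length)
        for i, length in enumerate(TABLE1_OTHER_LENGTHS)
    ]
    return rows
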