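import numpy as np
import pytest

from feverentropy import CleanSeries, TemperatureSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(values, label="other", subject_id="S01"):
    return TemperatureSeries(subject_id=subject_id, label=label, values=np.asarray(values, dtype=float))


def make_clean_cohort(rng, n_bacterial=4, n_other=5, length=60, shift=0.0):
    """Small normalized cohort of white-noise windows for grid tests.

    ``shift`` adds a pre-normalization smoothing contrast to the
    bacterial class (0 = identical distributions).
    """
    cohort = []
    for i in range(n_bacterial + n_other):
        label = "bacterial" if i < n_bacterial else "other"
        x = rng.normal(size=length)
        if label == "bacterial" and shift > 0:
            # moving-average smoothing lowers entropy for the bacterial class
            k = int(1 + shift)
            x = np.convolve(x, np.ones(k) / k, mode="same")
        x = (x - x.mean()) / x.std()
        cohort.append(
            CleanSeries(subject_id=f"S{i:02d}", label=label, values=x, normalized=True)
        )
    return cohort
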