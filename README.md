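# feverentropy

Entropy analysis of minute-resolution body-temperature time series for
discriminating fever caused by bacterial infection from fever with
other causes.

Continuous thermometry (e.g. a probe in the external auditory canal
logging one sample per minute) turns body temperature from a handful of
ward measurements into a dynamical signal. Disease tends to *lower* the
complexity of physiological signals, so a regularity statistic computed
on a patient's temperature curve is a candidate single-number feature
for flagging bacterial infection early. This package implements that
analysis end to end for researchers working with such recordings:

- **Entropy estimators** (`feverentropy.entropy`)
  - *Slope Entropy* — each length-`m` window is reduced to `m−1`
    consecutive differences `y_i = x_i − x_{i+1}`, quantised to the
    alphabet `{+2, +1, 0, −1, −2}` by a near-zero threshold `δ` and a
    steep-slope threshold `γ`; the feature is the Shannon entropy (nats)
    of the observed pattern frequencies.
  - *Approximate Entropy* — `ApEn(m, r, N) = ϕ^m(r) − ϕ^{m+1}(r)` with
    Chebyshev-distance template matching within tolerance `r`,
    self-matches included.
  - *Sample Entropy* — `SampEn(m, r, N) = −ln(A^m(r) / B^m(r))` over
    cross-template matches only, with a typed `UNDEFINED` sentinel when
    no matches exist, plus the weak/strong (≥10 / ≥100 matches) ApEn
    reliability diagnostics.
- **Preprocessing** (`feverentropy.preprocess`) — linear interpolation
  of probe disconnections of at most 5 samples, longest-clean-interval
  resolution of longer dropouts, central trimming to the fixed analysis
  lengths 500–1100, and z-normalisation of the analysed window (so `r`
  and `γ` are in SD units).
- **Evaluation** (`feverentropy.classify`) — two-sided
  Wilcoxon–Mann–Whitney test (α = 0.05), ROC curve with automatic
  orientation, sensitivity/specificity at the closest point to (0, 1),
  and the full grid search `m ∈ [3, 9]`, `γ, r ∈ [0.10, 0.90]` in 0.05
  steps (δ fixed at 0.001).
- **Synthetic cohorts** (`feverentropy.simulate`) — the clinical
  recordings such studies use are not public, so a generator produces
  labelled cohorts (default 10 bacterial + 13 other, recording lengths
  537–1468 min) with circadian baseline, fever episodes, probe-dropout
  gaps and a class-dependent AR(1) regularity contrast.
- **Driver + CLI** (`feverentropy.pipeline`, `feverentropy` command) —
  cohort CSV I/O, YAML-configured experiment runs, headline tables of
  significant grid cells.

## Worked example

```python
import numpy as np
from feverentropy import (
    SlpEnParams, SyntheticCohortConfig, closest_to_01_threshold,
    generate_cohort, mann_whitney_two_sided, prepare_cohort,
    roc_points, slope_entropy,
)

cohort = generate_cohort(SyntheticCohortConfig(seed=6))   # 10 + 13 subjects
clean, excluded = prepare_cohort(cohort, 1000)            # repair, trim, z-normalise
feats = np.array([slope_entropy(s.values, SlpEnParams(3, 0.20)) for s in clean])
labels = np.array([s.label for s in clean])

u, p = mann_whitney_two_sided(feats[labels == "bacterial"], feats[labels == "other"])
roc = roc_points(feats, labels)
op = closest_to_01_threshold(roc)
print(f"p={p:.4f} AUC={roc.auc:.3f} orientation={roc.orientation}")
print(f"threshold={op.threshold:.4f} Se={op.se:.2f} Sp={op.sp:.2f}")
```

prints

```
p=0.0303 AUC=0.886 orientation=low
threshold=2.6777 Se=1.00 Sp=0.71
```

Twelve of the 23 recordings supply a clean central 1000-minute window
at this seed. The bacterial class scores *lower* Slope Entropy
(orientation `low`): classifying a subject as bacterial when the
feature falls at or below 2.6777 recovers all five bacterial subjects
(Se = 1.00) while correctly passing 5 of 7 others (Sp = 0.71), and the
class difference is significant at α = 0.05 (exact Mann–Whitney,
p = 0.0303).

The same experiment over every method, length and grid cell:

```sh
feverentropy simulate --seed 6 --out cohort/
feverentropy run --config experiment.yaml --out results/
```

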