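# gaitbattery

Digital gait characteristics from a single lower-back accelerometer, and
PLS-DA classification of Parkinson's disease (PD) versus controls (CL).

Gait changes early in PD, often before overt motor signs, and a single
tri-axial accelerometer worn at L5 can quantify it objectively. Beyond
the familiar spatiotemporal parameters (step time, step length,
velocity, cadence, variability, asymmetry), the raw signal carries
frequency, regularity, magnitude and complexity information that turns
out to discriminate disease at least as well. This package implements
that full analysis as a reusable, tested pipeline:

* a **synthetic cohort generator** producing lumbar gait accelerometry
  (100 Hz, VT/ML/AP axes) with ground-truth heel-strike/toe-off events,
  instrumented-mat pass annotations and demographics, with configurable
  PD-vs-CL group effects (including a null cohort at effect 0);
* **segmentation** of recordings into passes, strides and steps from the
  events, with tilt correction, gravity removal and 20 Hz low-pass
  filtering;
* a **210-characteristic battery** in five domains — spatiotemporal
  (25), frequency (56), regularity (20), magnitude (84), complexity
  (25) — including harmonic ratio, index of harmonicity,
  autocorrelation step/stride regularity, the gait symmetry index,
  inverted-pendulum step length, phase-plot orbit geometry and
  Rosenstein largest Lyapunov exponents;
* **PLS-DA from scratch** (NIPALS), with stratified cross-validated
  component selection via Q²/R²X/R²Y, VIP variable ranking, a six-model
  subset battery (spatiotemporal / signal-based / all gait, each ±
  demographics), ROC/AUC, and Welch-t / z-score group statistics.

Key relations: step length from vertical excursion `h` and sensor
height `l` as `L = 2√(2lh − h²)`; harmonic ratio as Σ even / Σ odd
stride-harmonic amplitudes (inverted for ML); step/stride regularity as
peaks of the unbiased autocorrelation `A(m) = Σ xᵢxᵢ₊ₘ/(N−m)`;
`VIP_j = √(p·Σ_b SSYᵦ w_jᵦ² / Σ_b SSYᵦ)` with mean squared VIP ≡ 1.
See `docs/methods.md` for the full model description.

## Worked example

```python
from gaitbattery.synthetic import CohortConfig, generate_cohort
from gaitbattery.pipeline import extract_features, demographics_design
from gaitbattery.evaluation import run_battery

cohort = generate_cohort(CohortConfig(n_pd=13, n_cl=13, seed=7,
                                      duration=60.0))
features = extract_features(cohort)          # 26 rows x 210 characteristics
dem = demographics_design(cohort.demographics_frame)
reports = run_battery(features, dem, features["group"].to_numpy(),
                      subsets=["spatiotemporal", "signal_based"],
                      k_folds=5, a_max=4)
for name, r in reports.items():
    print(f"{name:16s} acc={r.accuracy:.1f}%  auc={r.auc:.1f}%  A*={r.n_components}")
```

prints

```
spatiotemporal   acc=69.2%  auc=77.5%  A*=1
signal_based     acc=88.5%  auc=95.9%  A*=2
```

i.e. on this small synthetic cohort with planted group effects, the
pooled out-of-fold accuracy of the model using only signal-based
characteristics (frequency + regularity + magnitude + complexity, 185
columns) clearly exceeds the model restricted to the 25 classical
spatiotemporal characteristics — the central qualitative behaviour the
battery is designed to expose. `A*` is the number of PLS components
selected by the Q² plateau rule.

A command-line interface wraps the same pipeline:

```bash
gaitbattery run-all --out runs/demo --seed 1
gaitbattery report --out runs/demo
```

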