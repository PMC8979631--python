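# Methods

`gaitbattery` implements a complete digital gait analysis for lower-back
(L5) tri-axial accelerometry: a synthetic cohort generator with ground
truth, event-driven segmentation, a 210-characteristic feature battery in
five domains, and from-scratch PLS-DA classification with VIP variable
ranking. This note documents the models, the numerical choices, and what
the synthetic study can and cannot show.

## The synthetic walking protocol

Each subject walks continuously for two minutes (default) around a 25 m
oval circuit whose straight section contains a 5.5 m instrumented-mat
segment. Stepping is continuous; heel-strike and toe-off events and pass
intervals are annotated only on the mat, as a pressure walkway would
record them. With control parameters this yields roughly 6 passes and 45
mat steps per two-minute bout, and slower, shorter-stepping subjects
produce roughly 5 passes with slightly more steps per pass — the regime
reported for instrumented-walkway protocols in early Parkinson's disease
(PD) cohorts.

The acceleration signal is a jittered harmonic series on the stride
cycle, not a biomechanical simulation. Per axis:

* VT and AP carry even stride harmonics (2, 4, 6, 8 — i.e. the step
  frequency and multiples), ML carries odd stride harmonics (1, 3, 5, 7),
  matching the empirically observed harmonic structure of lumbar gait
  signals.
* The stride phase is piecewise linear between heel-strike times whose
  increments are `step_time + N(0, step_time_jitter_sd)`.
* A per-step multiplicative envelope combines amplitude jitter
  (`amplitude_jitter_cv`) and left/right scaling (`1 ∓ asymmetry_factor/2`).
* White measurement noise (`noise_sd`, m/s²) is added per axis, and
  +9.81 m/s² gravity on VT. Sample rate 100 Hz, ±8 g range enforced.

VT amplitudes are calibrated so that the double-integrated vertical
displacement has a per-step peak-to-peak excursion `h` consistent with
the subject's step length `L` under the inverted pendulum,
`h = l − sqrt(l² − L²/4)` with `l` the sensor height (0.53 × body
height). This makes spatial parameters recoverable downstream and ties
"lower signal magnitude" to "shorter steps" the way real gait does.

Group distributions (controls): stride frequency 1.00 ± 0.06 Hz, step
length 0.68 ± 0.06 m, step-time jitter 10 ± 3 ms, amplitude jitter CV
0.05 ± 0.015, noise 0.12 ± 0.03 m/s², asymmetry 0.03 ± 0.02, ML
fundamental 0.95 ± 0.12 m/s². PD means are shifted by −0.3 to +0.8
control SDs (shorter/slower steps, more temporal and amplitude
variability, more asymmetry, lower ML/AP amplitudes), magnitudes on the
order of the ~1 SD group separations typical of early-disease cohorts;
`effect_scale` multiplies all shifts and 0 yields a null cohort.
Demographics are truncated normals (PD slightly shorter, lighter, lower
MoCA, similar age), also scaled by `effect_scale`.

What the generator does **not** emulate: freezing episodes, turning
dynamics as analysable signal (off-mat walking continues the same
harmonic model), sensor drift or miscalibration, and any physiologic
coupling beyond the pendulum constraint. Passing tests therefore
demonstrate that the pipeline measures what it claims on signals with
known structure — not that the same accuracies would hold on clinical
data.

## Segmentation and preprocessing

Preprocessing: (i) tilt correction rotating the bout-mean acceleration
vector onto VT (skipped when the mean vector is < 1 m/s², i.e. the
signal is already gravity-free); (ii) removal of the VT mean (gravity);
(iii) 4th-order zero-phase Butterworth low-pass at 20 Hz. Events are
inputs, never detected from the signal. Indexing is 0-based with
half-open `[start, end)` intervals, event times mapped to the nearest
sample; a step runs heel strike → next (contralateral) heel strike, a
stride heel strike → next ipsilateral heel strike; passes with fewer
than 4 heel strikes are dropped (the weakest rule that guarantees one
stride per foot).

## The 210-characteristic battery

Domain sizes: spatiotemporal 25, frequency 56, regularity 20, magnitude
84, complexity 25. `features/registry.py` is the single source of truth
for names, domains and units; matrix columns and VIP tables are generated
from it.

**Spatiotemporal (25)** — means and SDs of step time, stance time, swing
time, step length, step velocity; |left − right| asymmetries of four of
these; cadence; stride time/length/velocity means and two stride SDs;
five coefficients of variation (100·SD/mean). Step length uses the
uncorrected Zijlstra inverted pendulum (the 1.25 empirical correction is
available via `corrected=True`). Double integration uses the 0.1 Hz
4th-order zero-phase high-pass on windows ≥ 30 s; per-pass windows
(~4–5 s) are shorter than the filter's ~10 s impulse response, so they
instead get mean removal before integration plus linear detrending of
the displacement. Variability SDs pool both feet.

**Frequency (56)** — dominant-peak frequency/amplitude/width/slope/range
from a Welch PSD (Hann, 3 s segments, 50 % overlap) in 0.3–5 Hz, with
parabolic interpolation of the peak, on 4 channels (VT/ML/AP/resultant)
× 2 levels (whole bout, pass average); harmonic ratio (Σ even / Σ odd
stride-harmonic amplitudes, inverted for ML, harmonics 1–20, capped at
1e6) and index of harmonicity (power at the fundamental / cumulative
power of harmonics 1–6; fundamental = stride frequency for ML, step
frequency for VT/AP) per axis at pass and per-stride level; total Welch
power per channel.

**Regularity (20)** — unbiased autocorrelation
`A(m) = Σ x_i x_{i+m} / (N−m)` normalised by `A(0)`, restricted to lags
≤ N/2 to bound variance inflation; step/stride regularity Ad1/Ad2 are
the peaks in ±20 % windows around the mean step/stride lags (the window
tolerates jitter without locking onto neighbouring harmonics), per
channel at bout and pass level; the Ad1/Ad2 symmetry ratio for VT and
ML; the gait symmetry index GSI = max over the step-lag window of the
Euclidean norm of the three per-axis biased autocorrelations, divided by
√3. GSI needs ≥ 5 strides at bout level; a single mat pass holds only
~4 strides, so the pass-level GSI relaxes the requirement to 2 strides.

**Magnitude (84)** — RMS, SD, max, min, range, jerk RMS and jerk ratio
on 4 channels × 3 segmentation levels (step, stride, pass), averaged
across segments. Samples are mean-removed per segment (otherwise the
gravity/posture bias dominates); the resultant is the norm of the
mean-removed vector signal, whose RMS is taken without further mean
removal so the Pythagorean identity RMS_res² = Σ RMS_axis² holds
exactly. Jerk is the central difference of acceleration; jerk ratio =
jerk RMS × duration / RMS is the dimensionless smoothness form (the
common alternative, an ML/AP jerk-RMS ratio, was considered and
rejected as redundant with the per-axis jerk cells).

**Complexity (25)** — phase-plot orbits (acceleration vs its central-
difference derivative, both z-normalised over the bout) per stride:
mean and SD of shoelace orbit area, half-orbit area asymmetries about
the first and second principal axes (computed by polygon/half-plane
intersection, hence rotation- and scale-invariant), and centroid drift
(RMS distance of per-stride orbit centroids from their mean). The
largest Lyapunov exponent uses Rosenstein's algorithm: delay embedding
(dimension 5 per scalar channel, 2 per channel for the 3-axis joint
space; delay = first minimum of average mutual information, fallback 10
samples), nearest neighbours outside a one-stride Theiler window, and a
least-squares slope on the mean log-divergence curve. The slope is
fitted on a half-stride window *starting after the embedding memory
(m−1)·τ has expired*: the nearest-neighbour distance at offset 0 is a
selection-biased minimum whose bias decays in steps at multiples of τ,
and fitting inside that region reports spurious positive exponents even
for a noisy sinusoid. Reference points are subsampled to ≤ 2500 to
bound the neighbour-search cost; neighbours are still searched among
all embedded points.

## PLS-DA, component selection, VIP

Predictors are median-imputed (training set only) and autoscaled; the
response is a column-centred one-hot matrix for (PD, CL). NIPALS runs
per component to a 1e-10 relative tolerance on the scores (max 500
iterations), deflating X and Y; weights are unit-norm and scores come
out mutually orthogonal. Prediction uses B = W(PᵀW)⁻¹Qᵀ; class = argmax
of the two continuous outputs, ties to PD (a missed case costs more
than a false alarm).

Q²(a) = 1 − PRESS(a)/SS(Y) with PRESS pooled over stratified k-folds
(k = 7, shuffle seed 20200214 by default) and scaling refitted in every
training fold; R²X/R²Y are cumulative explained sums of squares of the
full-data fit. The component count A* is the smallest `a` whose Q² gain
over the next component is ≤ 0.01, capped at 10 — a plateau rule chosen
because "pick components by cross-validation" admits many readings and
this one is deterministic and conservative.

VIP_j(a) = sqrt(p · Σ_{b≤a} SSY_b w_jb² / Σ_{b≤a} SSY_b), so mean
squared VIP is exactly 1 at every a; the ranking criterion is the mean
of the cumulative-at-a VIPs over a = 1..A* (averaging the per-component
increments instead is available by computing `vip_scores` per a).

Six subset models form the battery: spatiotemporal (25), spatiotemporal
+ demographics (31), signal-based (185), signal-based + demographics
(191), all gait (210), all gait + demographics (216); demographics are
age, sex (0/1), height, weight, BMI, MoCA. Metrics (accuracy,
sensitivity and specificity with PD positive, trapezoidal AUC with ties
counted half) are computed on pooled out-of-fold predictions, refitting
per fold at A*; a stratified hold-out mode exists for comparison. Group
statistics use Welch's t-test (no equal-variance assumption), z-scores
(mean_PD − mean_CL)/SD_CL, and Pearson correlations among influential
(VIP > 1) characteristics; p-values are reported raw, with an optional
Benjamini–Hochberg correction.

## Simulation sizes

The default study is 81 PD + 61 CL subjects with 120 s recordings — the
configuration `scripts/acceptance.py` runs end-to-end (together with an
equally sized null cohort). The replicate-based checks in the test suite
use deliberately scaled-down versions chosen to keep the whole suite
fast while leaving the tested contrasts far from marginal: 20 replicate
cohorts of 13 + 13 subjects with 60 s walks for planted-effect recovery
and the signal-vs-spatiotemporal comparison, 20 null cohorts of 10 + 10,
and 20-seed pairs of group-mean subjects for the direction checks.

## Known limitations

* The pendulum step length inherits the usual amplitude-dependent bias
  (~5–10 % here); recovery tests bound the error at 15 % and the
  correction factor is off by default.
* Whole-bout features include off-mat walking; in the generator that
  signal is statistically identical to on-mat gait, which flatters
  bout-level features relative to real oval-circuit data with turns.
* The Lyapunov exponent is a slope estimate on a finite noisy curve;
  its absolute scale depends on the fit window convention documented
  above, and only relative comparisons across subjects are meaningful.
* Null-cohort classification sits at chance only because demographics
  effects are also scaled by `effect_scale`; with real demographics a
  +DEM model can classify above chance in the absence of any gait
  effect.
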