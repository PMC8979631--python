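"""Autocorrelation-based gait regularity and symmetry (20 named scalars).

Step regularity (Ad1) and stride regularity (Ad2) are the peaks of the
unbiased, normalised autocorrelation of the trunk acceleration at the
mean step and stride lags; their ratio indexes step-to-step symmetry.
The gait symmetry index (GSI) combines the three axes' autocorrelations
at the step lag into a single [0, 1] measure.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from ..types import AXES, AXES_RES, GaitError, GaitEvents, RawRecording, resultant
from ..segmentation import _pass_events

logger = logging.getLogger(__name__)

LAG_WINDOW = 0.20  # search +/-20 % around the nominal step/stride lag

FEATURE_NAMES = tuple(
    f"rg_{kind}_regularity_{ax}_{lvl}"
    for kind in ("step", "stride") for ax in AXES_RES
    for lvl in ("bout", "pass")
) + ("rg_symmetry_vt_bout", "rg_symmetry_ml_bout",
     "rg_gsi_bout", "rg_gsi_pass")


def unbiased_autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """A(m) = [1/(N-m)] sum_i x_i x_{i+m} on the mean-removed signal,
    normalised by A(0); restricted to lags m <= N/2 to bound the variance
    inflation of the unbiased estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag > n // 2:
        raise GaitError("max_lag must be <= N/2")
    x = x - x.mean()
    a0 = float(x @ x) / n
    if a0 <= 0:
        raise GaitError("constant signal has no autocorrelation")
    full = sps.correlate(x, x, mode="full", method="fft")
    raw = full[n - 1:n + max_lag]  # lags 0..max_lag
    counts = n - np.arange(max_lag + 1)
    a = (raw / counts) / a0
    a[0] = 1.0
    return a


def _biased_normalised_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    denom = float(x @ x)
    if denom <= 0:
        raise GaitError("constant signal has no autocorrelation")
    full = sps.correlate(x, x, mode="full", method="fft")
    return full[n - 1:n + max_lag] / denom


def _lag_window(nominal_lag: float, n: int) -> tuple[int, int]:
    lo = int(np.floor(nominal_lag * (1 - LAG_WINDOW)))
    hi = int(np.ceil(nominal_lag * (1 + LAG_WINDOW)))
    return max(lo, 1), min(hi, n // 2)


def step_stride_regularity(x: np.ndarray, mean_step_time: float,
                           mean_stride_time: float, fs: float
                           ) -> tuple[float, float, float]:
    """(Ad1, Ad2, Ad1/Ad2): autocorrelation peaks in +/-20 % windows
    around the mean step and stride lags.  Missing (NaN) when a window
    falls outside the admissible lag range."""
    n = len(x)
    step_lag = mean_step_time * fs
    stride_lag = mean_stride_time * fs
    max_lag = n // 2
    a = unbiased_autocorrelation(x, max_lag)

    def peak(nominal: float) -> float:
        lo, hi = _lag_window(nominal, n)
        if hi < lo:
            logger.debug("empty lag search window at lag %.1f", nominal)
            return np.nan
        return float(a[lo:hi + 1].max())

    ad1, ad2 = peak(step_lag), peak(stride_lag)
    sym = ad1 / ad2 if np.isfinite(ad1) and np.isfinite(ad2) and ad2 != 0 \
        else np.nan
    return ad1, ad2, sym


def gait_symmetry_index(samples: np.ndarray, mean_step_time: float,
                        mean_stride_time: float, fs: float,
                        min_strides: int = 5) -> float:
    """GSI = max_m C(m)/sqrt(3) over the step-lag window, with C(m) the
    Euclidean norm of the three per-axis biased normalised
    autocorrelations; 1 = perfectly symmetric gait."""
    n = samples.shape[0]
    n_strides = (n / fs) / mean_stride_time
    if n_strides < min_strides:
        raise GaitError(
            f"gait symmetry index requires >= {min_strides} strides")
    max_lag = n // 2
    acs = [_biased_normalised_autocorr(samples[:, k], max_lag)
           for k in range(3)]
    c = np.sqrt(np.sum(np.square(acs), axis=0))
    lo, hi = _lag_window(mean_step_time * fs, n)
    if hi < lo:
        return np.nan
    return float(c[lo:hi + 1].max() / np.sqrt(3.0))


def _mean_times(idx: list[int], fs: float) -> tuple[float, float]:
    t = np.asarray(idx) / fs
    steps = np.diff(t)
    strides = t[2:] - t[:-2]
    return float(steps.mean()), float(strides.mean())


def regularity_vector(rec: RawRecording, ev: GaitEvents) -> dict[str, float]:
    """All 20 regularity characteristics for one preprocessed recording."""
    out = dict.fromkeys(FEATURE_NAMES, np.nan)
    res = resultant(rec.samples)
    channels = {"vt": rec.vt, "ml": rec.ml, "ap": rec.ap, "res": res}

    passes = _pass_events(rec, ev)
    if not passes:
        logger.warning("%s: no usable passes for regularity",
                       rec.subject_id)
        return out
    all_idx = [i for _, _, _, idx, _ in passes for i in idx]
    step_t, stride_t = _mean_times_pooled(passes, rec.fs)

    for ax, x in channels.items():
        ad1, ad2, sym = step_stride_regularity(x, step_t, stride_t, rec.fs)
        out[f"rg_step_regularity_{ax}_bout"] = ad1
        out[f"rg_stride_regularity_{ax}_bout"] = ad2
        if ax == "vt":
            out["rg_symmetry_vt_bout"] = sym
        elif ax == "ml":
            out["rg_symmetry_ml_bout"] = sym

    try:
        out["rg_gsi_bout"] = gait_symmetry_index(
            rec.samples, step_t, stride_t, rec.fs, min_strides=5)
    except GaitError as exc:
        logger.warning("%s: %s", rec.subject_id, exc)

    pass_vals = {f"{kind}_{ax}": [] for kind in ("step", "stride")
                 for ax in AXES_RES}
    gsi_vals = []
    for p_idx, start, end, idx, feet in passes:
        i0 = max(int(round(start * rec.fs)), 0)
        i1 = min(max(int(round(end * rec.fs)), 1), rec.n_samples)
        st, sd = _mean_times(idx, rec.fs)
        for ax in AXES_RES:
            seg = channels[ax][i0:i1]
            try:
                ad1, ad2, _ = step_stride_regularity(seg, st, sd, rec.fs)
            except GaitError:
                continue
            if np.isfinite(ad1):
                pass_vals[f"step_{ax}"].append(ad1)
            if np.isfinite(ad2):
                pass_vals[f"stride_{ax}"].append(ad2)
        try:
            gsi_vals.append(gait_symmetry_index(
                rec.samples[i0:i1], st, sd, rec.fs, min_strides=2))
        except GaitError:
            pass
    for kind in ("step", "stride"):
        for ax in AXES_RES:
            vals = pass_vals[f"{kind}_{ax}"]
            if vals:
                out[f"rg_{kind}_regularity_{ax}_pass"] = float(np.mean(vals))
    if gsi_vals:
        out["rg_gsi_pass"] = float(np.mean(gsi_vals))
    return out


def _mean_times_pooled(passes, fs: float) -> tuple[float, float]:
    steps, strides = [], []
    for _, _, _, idx, _ in passes:
        t = np.asarray(idx) / fs
        steps.extend(np.diff(t))
        strides.extend(t[2:] - t[:-2])
    return float(np.mean(steps)), float(np.mean(strides))
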