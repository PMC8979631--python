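"""Spatiotemporal gait characteristics (25 named scalars).

Temporal parameters come straight from walkway events; spatial parameters
(step length, and velocities derived from it) use the inverted-pendulum
model on the double-integrated vertical acceleration: with l the sensor
height above ground (~L5) and h the per-step vertical excursion of the
trunk, step length L = 2*sqrt(2*l*h - h^2)  (Zijlstra's estimator, used
here without the empirical 1.25 correction; enable `corrected` to apply
it).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import integrate, signal as sps

from ..types import GaitError, GaitEvents, RawRecording

logger = logging.getLogger(__name__)

HIGHPASS_HZ = 0.1  # drift removal after each integration
PENDULUM_CORRECTION = 1.25

FEATURE_NAMES = (
    # means (5)
    "st_step_time_mean", "st_stance_time_mean", "st_swing_time_mean",
    "st_step_length_mean", "st_step_velocity_mean",
    # within-subject SDs / variability (5)
    "st_step_time_sd", "st_stance_time_sd", "st_swing_time_sd",
    "st_step_length_sd", "st_step_velocity_sd",
    # asymmetries |L - R| (4)
    "st_step_time_asym", "st_stance_time_asym", "st_swing_time_asym",
    "st_step_length_asym",
    # cadence (1)
    "st_cadence",
    # stride means (3)
    "st_stride_time_mean", "st_stride_length_mean", "st_stride_velocity_mean",
    # stride SDs (2)
    "st_stride_time_sd", "st_stride_length_sd",
    # coefficients of variation, % (5)
    "st_step_time_cv", "st_step_length_cv", "st_step_velocity_cv",
    "st_stride_time_cv", "st_stride_length_cv",
)


def temporal_params(ev: GaitEvents) -> pd.DataFrame:
    """Per-event table of step/stride/stance/swing times (seconds).

    Rows are indexed by the heel strike opening each step; intervals that
    would cross a pass boundary are excluded.  Stance requires the
    ipsilateral toe-off inside the pass; otherwise stance/swing are NaN.
    """
    if len(ev.heel_strikes) < 2:
        raise GaitError("at least two heel strikes are required")
    rows = []
    for start, end in ev.passes:
        hs = ev.heel_strikes_in(start, end)
        to = ev.toe_offs_in(start, end)
        for i in range(len(hs) - 1):
            t0, f0 = hs[i]
            t1, f1 = hs[i + 1]
            row = {
                "pass_start": start, "t": t0, "foot": f0,
                "step_time": t1 - t0, "step_foot": f1,
                "stride_time": np.nan, "stance_time": np.nan,
                "swing_time": np.nan,
            }
            if i + 2 < len(hs):
                t2, f2 = hs[i + 2]
                row["stride_time"] = t2 - t0
                to_match = [tt for tt, ff in to if ff == f0 and t0 < tt < t2]
                if to_match:
                    row["stance_time"] = to_match[0] - t0
                    row["swing_time"] = row["stride_time"] - row["stance_time"]
                else:
                    logger.debug("missing toe-off for HS at t=%.3f", t0)
            rows.append(row)
    if not rows:
        raise GaitError("no within-pass step intervals found")
    return pd.DataFrame(rows)


def pendulum_step_length(h: float, sensor_height: float,
                         corrected: bool = False) -> float:
    """Closed-form inverted-pendulum step length from excursion h (m)."""
    l = sensor_height
    if h >= l:
        raise GaitError("excursion h must be smaller than sensor height")
    L = 2.0 * math.sqrt(2.0 * l * h - h * h)
    return PENDULUM_CORRECTION * L if corrected else L


def vertical_displacement(vt: np.ndarray, fs: float) -> np.ndarray:
    """Double-integrate VT acceleration into drift-free displacement (m).

    Long segments use a 0.1 Hz 4th-order zero-phase high-pass after each
    integration; the filter's impulse response spans ~10 s, so shorter
    windows (single passes/steps) would be dominated by edge transients
    and instead get mean removal before integration plus a linear
    detrend of the displacement — the stable equivalent at that length.
    """
    x = np.asarray(vt, dtype=float)
    if len(x) == 0:
        raise GaitError("empty segment")
    dx = 1.0 / fs
    if len(x) / fs >= 3.0 / HIGHPASS_HZ:
        sos = sps.butter(4, HIGHPASS_HZ, btype="high", fs=fs, output="sos")
        vel = sps.sosfiltfilt(sos,
                              integrate.cumulative_trapezoid(x, dx=dx,
                                                             initial=0.0))
        return sps.sosfiltfilt(sos,
                               integrate.cumulative_trapezoid(vel, dx=dx,
                                                              initial=0.0))
    vel = integrate.cumulative_trapezoid(x - x.mean(), dx=dx, initial=0.0)
    disp = integrate.cumulative_trapezoid(vel, dx=dx, initial=0.0)
    return sps.detrend(disp, type="linear")


def step_length_pendulum(vt_segment: np.ndarray, sensor_height: float,
                         fs: float, corrected: bool = False) -> float:
    """Inverted-pendulum step length for one step of preprocessed VT
    acceleration; NaN (logged) when the excursion exceeds sensor height."""
    if sensor_height <= 0:
        raise GaitError("sensor_height must be positive")
    disp = vertical_displacement(vt_segment, fs)
    h = float(disp.max() - disp.min())
    if h >= sensor_height:
        logger.warning("vertical excursion %.3f m >= sensor height; "
                       "step length set to missing", h)
        return np.nan
    return pendulum_step_length(h, sensor_height, corrected=corrected)


def _step_lengths_by_pass(rec: RawRecording, ev: GaitEvents,
                          sensor_height: float,
                          corrected: bool = False) -> pd.DataFrame:
    """Per-step pendulum lengths, integrating VT once per pass."""
    rows = []
    for start, end in ev.passes:
        hs = ev.heel_strikes_in(start, end)
        if len(hs) < 4:
            continue
        i0 = int(round(start * rec.fs))
        i1 = min(int(round(end * rec.fs)), rec.n_samples)
        disp = vertical_displacement(rec.vt[i0:i1], rec.fs)
        for i in range(len(hs) - 1):
            t0, f0 = hs[i]
            t1, f1 = hs[i + 1]
            j0 = max(int(round(t0 * rec.fs)) - i0, 0)
            j1 = min(int(round(t1 * rec.fs)) - i0, len(disp))
            if j1 - j0 < 3:
                continue
            h = float(disp[j0:j1].max() - disp[j0:j1].min())
            if h >= sensor_height:
                logger.warning("step excursion >= sensor height; skipped")
                length = np.nan
            else:
                length = pendulum_step_length(h, sensor_height, corrected)
            rows.append({"t": t0, "foot": f0, "step_foot": f1,
                         "step_length": length})
    return pd.DataFrame(rows)


def _cv(values: np.ndarray) -> float:
    m = np.nanmean(values)
    return 100.0 * np.nanstd(values, ddof=1) / m if m != 0 else np.nan


def spatiotemporal_vector(rec: RawRecording, ev: GaitEvents,
                          sensor_height: float,
                          corrected: bool = False) -> dict[str, float]:
    """The full 25-characteristic spatiotemporal block for one subject.

    Velocities are computed per step (length/time) then averaged;
    asymmetry is |mean_left - mean_right| of the per-foot means; SDs pool
    both feet.  Returns an all-NaN vector when fewer than two strides per
    foot are available.
    """
    try:
        tp = temporal_params(ev)
    except GaitError:
        logger.warning("%s: unusable events; all-missing vector",
                       rec.subject_id)
        return {name: np.nan for name in FEATURE_NAMES}
    strides_per_foot = tp.dropna(subset=["stride_time"]).groupby("foot").size()
    if len(strides_per_foot) < 2 or strides_per_foot.min() < 2:
        logger.warning("%s: fewer than 2 valid strides per foot; "
                       "all-missing vector", rec.subject_id)
        return {name: np.nan for name in FEATURE_NAMES}

    sl = _step_lengths_by_pass(rec, ev, sensor_height, corrected)
    if sl.empty:
        sl = pd.DataFrame(columns=["t", "foot", "step_foot", "step_length"])
    merged = tp.merge(sl, on=["t", "foot", "step_foot"], how="left")
    merged["step_velocity"] = merged["step_length"] / merged["step_time"]
    # stride length = sum of the two component step lengths
    merged["next_step_length"] = merged["step_length"].shift(-1)
    same_pass = merged["pass_start"] == merged["pass_start"].shift(-1)
    merged["stride_length"] = np.where(
        same_pass & merged["stride_time"].notna(),
        merged["step_length"] + merged["next_step_length"], np.nan)
    merged["stride_velocity"] = merged["stride_length"] / merged["stride_time"]

    def asym(col: str, by: str = "step_foot") -> float:
        means = merged.groupby(by)[col].mean()
        if len(means) < 2:
            return np.nan
        return float(abs(means.get("L", np.nan) - means.get("R", np.nan)))

    out = {
        "st_step_time_mean": merged["step_time"].mean(),
        "st_stance_time_mean": merged["stance_time"].mean(),
        "st_swing_time_mean": merged["swing_time"].mean(),
        "st_step_length_mean": merged["step_length"].mean(),
        "st_step_velocity_mean": merged["step_velocity"].mean(),
        "st_step_time_sd": merged["step_time"].std(),
        "st_stance_time_sd": merged["stance_time"].std(),
        "st_swing_time_sd": merged["swing_time"].std(),
        "st_step_length_sd": merged["step_length"].std(),
        "st_step_velocity_sd": merged["step_velocity"].std(),
        "st_step_time_asym": asym("step_time"),
        "st_stance_time_asym": asym("stance_time", by="foot"),
        "st_swing_time_asym": asym("swing_time", by="foot"),
        "st_step_length_asym": asym("step_length"),
        "st_cadence": 60.0 / merged["step_time"].mean(),
        "st_stride_time_mean": merged["stride_time"].mean(),
        "st_stride_length_mean": merged["stride_length"].mean(),
        "st_stride_velocity_mean": merged["stride_velocity"].mean(),
        "st_stride_time_sd": merged["stride_time"].std(),
        "st_stride_length_sd": merged["stride_length"].std(),
        "st_step_time_cv": _cv(merged["step_time"].to_numpy()),
        "st_step_length_cv": _cv(merged["step_length"].to_numpy()),
        "st_step_velocity_cv": _cv(merged["step_velocity"].to_numpy()),
        "st_stride_time_cv": _cv(merged["stride_time"].to_numpy()),
        "st_stride_length_cv": _cv(merged["stride_length"].to_numpy()),
    }
    assert set(out) == set(FEATURE_NAMES)
    return {name: float(out[name]) for name in FEATURE_NAMES}
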