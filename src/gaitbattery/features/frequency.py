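"""Power-spectral-density domain characteristics (56 named scalars).

Dominant-peak descriptors come from a Welch periodogram (Hann window, 3 s
segments, 50 % overlap); harmonic ratio and index of harmonicity are
computed from finite Fourier amplitudes at integer harmonics of the
stride (or step) frequency of each analysed segment.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from ..types import AXES, AXES_RES, GaitError, GaitEvents, RawRecording, resultant
from ..segmentation import _pass_events

logger = logging.getLogger(__name__)

PEAK_BAND = (0.3, 5.0)  # Hz, search band for the dominant peak
WELCH_SEG_S = 3.0
HR_MAX_HARMONIC = 20  # 10 even + 10 odd stride harmonics
IH_N_HARMONICS = 6
HR_CAP = 1e6

PEAK_MEASURES = ("freq", "amp", "width", "slope", "range")
FEATURE_NAMES = tuple(
    f"fr_peak_{m}_{ax}_{lvl}"
    for m in PEAK_MEASURES for ax in AXES_RES for lvl in ("bout", "pass")
) + tuple(
    f"fr_hr_{ax}_{lvl}" for ax in AXES for lvl in ("pass", "stride")
) + tuple(
    f"fr_ih_{ax}_{lvl}" for ax in AXES for lvl in ("pass", "stride")
) + tuple(f"fr_total_power_{ax}" for ax in AXES_RES)


def welch_psd(x: np.ndarray, fs: float):
    nperseg = min(int(WELCH_SEG_S * fs), len(x))
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")


def psd_peak_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Dominant-peak frequency/amplitude/width/slope/range in 0.3-5 Hz."""
    if len(x) < 3 * fs:
        raise GaitError("psd_peak_features requires >= 3 s of signal")
    missing = dict.fromkeys(PEAK_MEASURES, np.nan)
    if np.allclose(x, 0.0):
        logger.warning("all-zero signal; PSD peak features missing")
        return missing
    f, pxx = welch_psd(x, fs)
    band = (f >= PEAK_BAND[0]) & (f <= PEAK_BAND[1])
    if not band.any() or pxx[band].max() <= 0:
        return missing
    fb, pb = f[band], pxx[band]
    i_pk = int(np.argmax(pb))
    peak_freq, peak_amp = float(fb[i_pk]), float(pb[i_pk])
    # parabolic interpolation refines the peak beyond the Welch grid
    if 0 < i_pk < len(pb) - 1:
        y0, y1, y2 = pb[i_pk - 1], pb[i_pk], pb[i_pk + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                peak_freq = float(fb[i_pk] + shift * (fb[1] - fb[0]))
                peak_amp = float(y1 - 0.25 * (y0 - y2) * shift)
    half = peak_amp / 2.0

    def crossing(direction: int) -> float:
        i = i_pk
        while 0 <= i + direction < len(pb) and pb[i + direction] >= half:
            i += direction
        j = i + direction
        if not (0 <= j < len(pb)):  # never dropped below half inside band
            return float(fb[i])
        # linear interpolation of the half-power crossing
        f1, f2, p1, p2 = fb[i], fb[j], pb[i], pb[j]
        return float(f1 + (half - p1) / (p2 - p1) * (f2 - f1))

    left, right = crossing(-1), crossing(+1)
    width = right - left
    slope = ((peak_amp - np.interp(left, fb, pb)) / (peak_freq - left)
             if peak_freq > left else np.nan)
    near = (fb >= peak_freq - 0.5) & (fb <= peak_freq + 0.5)
    rng = peak_amp - float(pb[near].min())
    return {"freq": peak_freq, "amp": peak_amp, "width": float(width),
            "slope": float(slope), "range": rng}


def total_power(x: np.ndarray, fs: float) -> float:
    """Integrated Welch PSD; approximately the time-domain variance."""
    f, pxx = welch_psd(x, fs)
    return float(np.trapezoid(pxx, f))


def fourier_amplitudes(x: np.ndarray, fs: float, base_freq: float,
                       n_harmonics: int) -> np.ndarray:
    """|finite Fourier coefficient| at harmonics 1..n of base_freq."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    t = np.arange(len(x)) / fs
    h = np.arange(1, n_harmonics + 1)
    basis = np.exp(-2j * np.pi * base_freq * np.outer(h, t))
    return np.abs(basis @ x) * 2.0 / len(x)


def _resolvable_harmonics(base_freq: float, fs: float, want: int) -> int:
    n = min(want, int(np.floor((fs / 2) / base_freq)))
    if n < want:
        logger.debug("only %d of %d harmonics resolvable below Nyquist",
                     n, want)
    return n


def harmonic_ratio(segment: np.ndarray, axis: str, stride_frequency: float,
                   fs: float) -> float:
    """Even/odd stride-harmonic amplitude ratio (odd/even for ML).

    The segment must span an integer number of strides.  VT and AP gait
    energy concentrates on even stride harmonics, ML on odd ones, so in a
    smooth gait the ratio is large on every axis.
    """
    if axis not in AXES:
        raise GaitError(f"axis must be one of {AXES}")
    n_h = _resolvable_harmonics(stride_frequency, fs, HR_MAX_HARMONIC)
    n_h -= n_h % 2  # keep even/odd pairs balanced
    if n_h < 2:
        return np.nan
    amps = fourier_amplitudes(segment, fs, stride_frequency, n_h)
    even = amps[1::2].sum()  # harmonics 2, 4, ...
    odd = amps[0::2].sum()  # harmonics 1, 3, ...
    num, den = (odd, even) if axis == "ml" else (even, odd)
    if den <= 0:
        return HR_CAP if num > 0 else np.nan
    return float(min(num / den, HR_CAP))


def index_of_harmonicity(segment: np.ndarray, axis: str,
                         stride_frequency: float, fs: float) -> float:
    """Power at the fundamental over cumulative power at harmonics 1-6.

    The fundamental is the stride frequency for ML and the step frequency
    (2 x stride) for VT/AP; 1 = perfectly harmonic signal.
    """
    if axis not in AXES:
        raise GaitError(f"axis must be one of {AXES}")
    f0 = stride_frequency if axis == "ml" else 2.0 * stride_frequency
    n_h = _resolvable_harmonics(f0, fs, IH_N_HARMONICS)
    if n_h < 1:
        return np.nan
    power = fourier_amplitudes(segment, fs, f0, n_h) ** 2
    total = power.sum()
    if total <= 0:
        logger.warning("zero cumulative harmonic power; IH missing")
        return np.nan
    return float(power[0] / total)


def _integer_stride_span(idx: list[int], feet: list[str]):
    """(start_idx, end_idx, n_strides) covering whole strides in a pass."""
    last = len(idx) - 1
    while last > 0 and feet[last] != feet[0]:
        last -= 1
    n_strides = last // 2
    if n_strides < 1:
        return None
    return idx[0], idx[last], n_strides


def spectral_vector(rec: RawRecording, ev: GaitEvents) -> dict[str, float]:
    """All 56 frequency-domain characteristics for one preprocessed
    recording; bout level uses the whole recording, pass level averages
    per-pass values."""
    out = dict.fromkeys(FEATURE_NAMES, np.nan)
    res = resultant(rec.samples)
    channels = {"vt": rec.vt, "ml": rec.ml, "ap": rec.ap, "res": res}

    for ax, x in channels.items():
        try:
            for m, v in psd_peak_features(x, rec.fs).items():
                out[f"fr_peak_{m}_{ax}_bout"] = v
        except GaitError:
            pass
        out[f"fr_total_power_{ax}"] = total_power(x, rec.fs)

    passes = _pass_events(rec, ev)
    pass_peaks = {ax: {m: [] for m in PEAK_MEASURES} for ax in AXES_RES}
    hr_pass = {ax: [] for ax in AXES}
    ih_pass = {ax: [] for ax in AXES}
    hr_stride = {ax: [] for ax in AXES}
    ih_stride = {ax: [] for ax in AXES}

    for p_idx, start, end, idx, feet in passes:
        i0 = max(int(round(start * rec.fs)), 0)
        i1 = min(max(int(round(end * rec.fs)), 1), rec.n_samples)
        for ax in AXES_RES:
            seg = channels[ax][i0:i1]
            if len(seg) >= 3 * rec.fs:
                try:
                    for m, v in psd_peak_features(seg, rec.fs).items():
                        if np.isfinite(v):
                            pass_peaks[ax][m].append(v)
                except GaitError:
                    pass
        span = _integer_stride_span(idx, feet)
        if span is not None:
            j0, j1, n_strides = span
            dur = (j1 - j0) / rec.fs
            f_str = n_strides / dur
            for ax in AXES:
                seg = channels[ax][j0:j1]
                hr_pass[ax].append(harmonic_ratio(seg, ax, f_str, rec.fs))
                ih_pass[ax].append(
                    index_of_harmonicity(seg, ax, f_str, rec.fs))
        # stride level: every ipsilateral heel-strike pair
        for i in range(len(idx) - 2):
            j0, j1 = idx[i], idx[i + 2]
            if j1 - j0 < 4:
                continue
            f_str = rec.fs / (j1 - j0)
            for ax in AXES:
                seg = channels[ax][j0:j1]
                hr_stride[ax].append(harmonic_ratio(seg, ax, f_str, rec.fs))
                ih_stride[ax].append(
                    index_of_harmonicity(seg, ax, f_str, rec.fs))

    for ax in AXES_RES:
        for m in PEAK_MEASURES:
            vals = pass_peaks[ax][m]
            if vals:
                out[f"fr_peak_{m}_{ax}_pass"] = float(np.mean(vals))
    for ax in AXES:
        for store, name in ((hr_pass, f"fr_hr_{ax}_pass"),
                            (ih_pass, f"fr_ih_{ax}_pass"),
                            (hr_stride, f"fr_hr_{ax}_stride"),
                            (ih_stride, f"fr_ih_{ax}_stride")):
            vals = [v for v in store[ax] if np.isfinite(v)]
            if vals:
                out[name] = float(np.mean(vals))
    return out
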