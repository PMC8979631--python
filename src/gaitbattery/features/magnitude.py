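"""Signal-magnitude characteristics (84 named scalars).

Seven measures (RMS, SD, max, min, range, jerk RMS, jerk ratio) on four
channels (VT, ML, AP, resultant) at three segmentation levels (per step,
per stride, per pass), each averaged across that level's segments.

RMS/max/min/range are computed on per-segment mean-removed samples (the
gravity/posture bias otherwise dominates VT).  The resultant channel is
the Euclidean norm of the mean-removed vector signal; its RMS is taken
without further mean removal so that RMS_res^2 = RMS_vt^2 + RMS_ml^2 +
RMS_ap^2 exactly.  Jerk is the central-difference derivative of
acceleration; jerk ratio = jerk RMS x segment duration / RMS is the
dimensionless smoothness normalisation.
"""

from __future__ import annotations

import logging

import numpy as np

from ..types import AXES_RES, GaitError, GaitEvents, RawRecording, WalkSegment
from ..segmentation import segment as make_segments

logger = logging.getLogger(__name__)

MEASURES = ("rms", "sd", "max", "min", "range", "jerk_rms", "jerk_ratio")
LEVELS = ("step", "stride", "pass")
MIN_SEGMENT_SAMPLES = 5

FEATURE_NAMES = tuple(
    f"mg_{m}_{ax}_{lvl}" for m in MEASURES for ax in AXES_RES for lvl in LEVELS
)


def _jerk(x: np.ndarray, fs: float) -> np.ndarray:
    return np.gradient(x, 1.0 / fs)


def magnitude_measures(seg_samples: np.ndarray, fs: float
                       ) -> dict[str, dict[str, float]]:
    """The 7 measures per channel for one segment (T x 3 samples)."""
    if seg_samples.shape[0] < MIN_SEGMENT_SAMPLES:
        logger.debug("segment of %d samples too short for magnitude "
                     "measures", seg_samples.shape[0])
        return {ax: dict.fromkeys(MEASURES, np.nan) for ax in AXES_RES}
    centered = seg_samples - seg_samples.mean(axis=0, keepdims=True)
    res = np.linalg.norm(centered, axis=1)
    channels = {"vt": centered[:, 0], "ml": centered[:, 1],
                "ap": centered[:, 2], "res": res}
    duration = seg_samples.shape[0] / fs
    out = {}
    for ax, x in channels.items():
        rms = float(np.sqrt(np.mean(x**2)))
        jerk_rms = float(np.sqrt(np.mean(_jerk(x, fs) ** 2)))
        out[ax] = {
            "rms": rms,
            "sd": float(np.std(x, ddof=1)),
            "max": float(x.max()),
            "min": float(x.min()),
            "range": float(x.max() - x.min()),
            "jerk_rms": jerk_rms,
            "jerk_ratio": jerk_rms * duration / rms if rms > 0 else np.nan,
        }
    return out


def magnitude_vector(rec: RawRecording, ev: GaitEvents) -> dict[str, float]:
    """All 84 magnitude characteristics: per-level unweighted means across
    segments; a level with no valid segments leaves its 28 cells NaN."""
    out = dict.fromkeys(FEATURE_NAMES, np.nan)
    for lvl in LEVELS:
        segs = make_segments(rec, ev, lvl)
        acc: dict[str, list[float]] = {}
        for s in segs:
            if s.n_samples < MIN_SEGMENT_SAMPLES:
                continue
            vals = magnitude_measures(s.slice(rec.samples), rec.fs)
            for ax in AXES_RES:
                for m in MEASURES:
                    v = vals[ax][m]
                    if np.isfinite(v):
                        acc.setdefault(f"{m}_{ax}", []).append(v)
        if not acc:
            logger.warning("%s: no valid %s segments for magnitude",
                           rec.subject_id, lvl)
            continue
        for key, vals in acc.items():
            out[f"mg_{key}_{lvl}"] = float(np.mean(vals))
    return out
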