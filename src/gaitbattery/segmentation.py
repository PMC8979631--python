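"""Preprocessing and event-driven segmentation of gait recordings.

Event times come from an instrumented walkway and are treated as ground
truth; no event detection is performed on the signal itself.  Sample
indexing is 0-based with half-open [start, end) intervals; event times are
mapped to the nearest sample.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .types import GaitError, GaitEvents, RawRecording, WalkSegment

logger = logging.getLogger(__name__)

LOWPASS_HZ = 20.0
LOWPASS_ORDER = 4
MIN_HEEL_STRIKES_PER_PASS = 4


def _rotation_to_vt(mean_vec: np.ndarray) -> np.ndarray:
    """Rotation matrix taking mean_vec/|mean_vec| onto the VT unit axis."""
    u = mean_vec / np.linalg.norm(mean_vec)
    e = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, e)
    s = np.linalg.norm(v)
    c = float(u @ e)
    if s < 1e-12:  # already aligned (or anti-aligned)
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def preprocess(rec: RawRecording) -> RawRecording:
    """Tilt-correct, remove gravity, low-pass filter.

    (i) rotate so the mean acceleration vector over the recording is
    purely VT, (ii) subtract the VT mean (gravity), (iii) 4th-order
    zero-phase Butterworth low-pass at 20 Hz.  Returns a new recording.
    """
    if rec.fs < 50:
        raise GaitError("preprocess requires fs >= 50 Hz")
    if rec.duration < 1.0:
        raise GaitError("recording shorter than 1 s cannot be preprocessed")
    mean_vec = rec.samples.mean(axis=0)
    # only tilt-correct when the mean vector is gravity-like; an already
    # gravity-free signal has an uninformative residual mean direction
    if np.linalg.norm(mean_vec) < 1.0:
        rotated = rec.samples.copy()
    else:
        rotated = rec.samples @ _rotation_to_vt(mean_vec).T
    rotated[:, 0] -= rotated[:, 0].mean()
    sos = sps.butter(LOWPASS_ORDER, LOWPASS_HZ, btype="low",
                     fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rotated, axis=0)
    return RawRecording(rec.subject_id, rec.fs, filtered)


def _nearest_idx(time_s: float, fs: float) -> int:
    return int(round(time_s * fs))


def _pass_events(rec: RawRecording, ev: GaitEvents):
    """Per pass: (heel-strike sample indices, feet), dropping short passes.

    Raises if any event lies outside the recording.
    """
    n = rec.n_samples
    offenders = [t for t, _ in ev.heel_strikes + ev.toe_offs
                 if not (0 <= _nearest_idx(t, rec.fs) <= n)]
    if offenders:
        raise GaitError(
            f"events outside recording at t={offenders[:5]}"
            + ("..." if len(offenders) > 5 else ""))
    out = []
    for p_idx, (start, end) in enumerate(ev.passes):
        if start < -1e-9 or end > rec.duration + 1e-9:
            raise GaitError(
                f"pass ({start:g}, {end:g}) lies outside the recording")
        hs = ev.heel_strikes_in(start, end)
        if len(hs) < MIN_HEEL_STRIKES_PER_PASS:
            logger.warning(
                "pass %d has %d heel strikes (< %d); dropped",
                p_idx, len(hs), MIN_HEEL_STRIKES_PER_PASS)
            continue
        feet = [f for _, f in hs]
        if any(f1 == f2 for f1, f2 in zip(feet, feet[1:])):
            raise GaitError(f"feet do not alternate within pass {p_idx}")
        idx = [min(_nearest_idx(t, rec.fs), n - 1) for t, _ in hs]
        out.append((p_idx, start, end, idx, feet))
    return out


def segment(rec: RawRecording, ev: GaitEvents, level: str) -> list[WalkSegment]:
    """Slice the recording into pass / stride / step segments."""
    if level not in ("pass", "stride", "step"):
        raise GaitError(f"unknown level {level!r}")
    segments: list[WalkSegment] = []
    for p_idx, start, end, idx, feet in _pass_events(rec, ev):
        n = rec.n_samples
        if level == "pass":
            segments.append(WalkSegment(
                "pass",
                max(_nearest_idx(start, rec.fs), 0),
                min(max(_nearest_idx(end, rec.fs), 1), n),
                "NA", p_idx))
        elif level == "step":
            for i in range(len(idx) - 1):
                segments.append(WalkSegment(
                    "step", idx[i], idx[i + 1], feet[i + 1], p_idx))
        else:  # stride: heel strike to next ipsilateral heel strike
            for i in range(len(idx) - 2):
                segments.append(WalkSegment(
                    "stride", idx[i], idx[i + 2], feet[i], p_idx))
    return segments


def segments_frame(segments: list[WalkSegment], subject_id: str):
    """Optional flat export of segments (one row per segment)."""
    import pandas as pd

    return pd.DataFrame([{
        "subject_id": subject_id, "level": s.level,
        "start_idx": s.start_idx, "end_idx": s.end_idx, "foot": s.foot,
        "pass_index": s.pass_index,
    } for s in segments])
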