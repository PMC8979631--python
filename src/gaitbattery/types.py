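"""Core containers for lumbar-accelerometry gait analysis.

Axis convention: acceleration samples are stored as a T x 3 array with
columns ordered (VT, ML, AP) = (vertical, mediolateral, anteroposterior),
in m/s^2.  After tilt calibration the VT column is gravity-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

G = 9.81  # m/s^2
SENSOR_RANGE_G = 8.0  # emulated sensor full-scale, in g

AXES = ("vt", "ml", "ap")
AXES_RES = ("vt", "ml", "ap", "res")


class GaitError(ValueError):
    """Raised on contract violations (invalid inputs, impossible requests)."""


@dataclass
class RawRecording:
    """One subject's tri-axial acceleration stream.

    samples: T x 3 float array, columns (VT, ML, AP), m/s^2.
    """

    subject_id: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise GaitError("samples must be a T x 3 array (VT, ML, AP)")
        if not np.all(np.isfinite(self.samples)):
            raise GaitError("samples contain missing/non-finite values")
        if np.max(np.abs(self.samples)) > SENSOR_RANGE_G * G + 1e-9:
            raise GaitError(
                f"samples exceed the +/-{SENSOR_RANGE_G:g} g sensor range"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def vt(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def ap(self) -> np.ndarray:
        return self.samples[:, 2]

    def copy(self) -> "RawRecording":
        return RawRecording(self.subject_id, self.fs, self.samples.copy())


@dataclass
class GaitEvents:
    """Heel-strike / toe-off instants (seconds) and straight-pass intervals.

    heel_strikes, toe_offs: sequences of (time_s, foot) with foot in {L, R}.
    passes: (start_s, end_s) half-open intervals of straight mat walking.
    """

    heel_strikes: list[tuple[float, str]]
    toe_offs: list[tuple[float, str]]
    passes: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for seq, name in ((self.heel_strikes, "heel_strikes"),
                          (self.toe_offs, "toe_offs")):
            times = [t for t, _ in seq]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise GaitError(f"{name} must be strictly increasing in time")
            if any(foot not in ("L", "R") for _, foot in seq):
                raise GaitError(f"{name} feet must be 'L' or 'R'")
        for start, end in self.passes:
            if end <= start:
                raise GaitError("pass intervals must have end > start")

    def hs_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.heel_strikes], dtype=float)

    def hs_feet(self) -> np.ndarray:
        return np.array([f for _, f in self.heel_strikes])

    def heel_strikes_in(self, start: float, end: float) -> list[tuple[float, str]]:
        return [(t, f) for t, f in self.heel_strikes if start <= t < end]

    def toe_offs_in(self, start: float, end: float) -> list[tuple[float, str]]:
        return [(t, f) for t, f in self.toe_offs if start <= t < end]


@dataclass
class Demographics:
    """Participant covariates forming the +DEM block of the design matrix."""

    age: float
    sex: str  # 'M' or 'F'
    height: float  # m
    weight: float  # kg
    bmi: float  # kg/m^2
    moca: int  # 0-30

    def __post_init__(self) -> None:
        if abs(self.bmi - self.weight / self.height**2) > 1e-6:
            raise GaitError("bmi must equal weight/height^2")
        if not (0 <= int(self.moca) <= 30) or int(self.moca) != self.moca:
            raise GaitError("moca must be an integer in [0, 30]")
        if self.sex not in ("M", "F"):
            raise GaitError("sex must be 'M' or 'F'")

    def as_row(self) -> dict:
        return {
            "age": self.age,
            "sex": 1.0 if self.sex == "M" else 0.0,
            "height": self.height,
            "weight": self.weight,
            "bmi": self.bmi,
            "moca": float(self.moca),
        }


DEMOGRAPHIC_COLUMNS = ("age", "sex", "height", "weight", "bmi", "moca")


@dataclass
class WalkSegment:
    """Half-open sample-index interval [start_idx, end_idx) at one level.

    A stride runs heel-strike to the next ipsilateral heel-strike; a step
    runs heel-strike to the next (contralateral) heel-strike and is labelled
    by the terminating foot.
    """

    level: str  # 'pass' | 'stride' | 'step'
    start_idx: int
    end_idx: int
    foot: str = "NA"  # 'L' | 'R' | 'NA'
    pass_index: int = -1
    parent: Optional["WalkSegment"] = None

    def __post_init__(self) -> None:
        if self.level not in ("pass", "stride", "step"):
            raise GaitError(f"unknown segment level {self.level!r}")
        if self.end_idx <= self.start_idx:
            raise GaitError("segment must satisfy end_idx > start_idx")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx

    def slice(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.start_idx:self.end_idx]


def resultant(samples: np.ndarray) -> np.ndarray:
    """Euclidean norm of the per-axis mean-removed vector signal."""
    centered = samples - samples.mean(axis=0, keepdims=True)
    return np.linalg.norm(centered, axis=1)
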