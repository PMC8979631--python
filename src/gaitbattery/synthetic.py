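"""Synthetic lumbar-accelerometry gait cohorts with ground-truth events.

The generator emulates a two-minute continuous walk at preferred speed
around a 25 m oval circuit whose straight section contains an instrumented
mat: stepping is continuous, but gait events (heel strikes, toe offs) and
pass intervals are only annotated while the walker is on the mat, exactly
as a pressure-sensitive walkway would record them.

The acceleration signal is a jittered harmonic series on the stride cycle
rather than a biomechanical simulation: it realises, with controllable
ground truth, precisely the statistical structure the downstream feature
battery measures — periodicity, left/right symmetry, harmonic content,
signal magnitude.  VT and AP energy sits on even stride harmonics (the
step frequency and its multiples), ML energy on odd stride harmonics,
which is the empirically observed structure of lower-back gait signals.

The VT amplitudes are calibrated so that the double-integrated vertical
displacement has a per-step peak-to-peak excursion consistent with the
subject's step length under the inverted-pendulum model, which makes
spatial parameters recoverable downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    G,
    Demographics,
    GaitError,
    GaitEvents,
    RawRecording,
)

logger = logging.getLogger(__name__)

# Relative harmonic structure per axis: (stride harmonic number, relative
# amplitude, phase rad).  VT/AP even harmonics, ML odd harmonics.
VT_HARMONICS = ((2, 1.00, 0.0), (4, 0.35, 0.4), (6, 0.12, 0.8), (8, 0.05, 1.2))
AP_HARMONICS = ((2, 1.00, 0.9), (4, 0.30, 1.3), (6, 0.10, 1.7), (8, 0.04, 2.1))
ML_HARMONICS = ((1, 1.00, 0.0), (3, 0.40, 0.5), (5, 0.15, 1.0), (7, 0.06, 1.5))

STANCE_FRACTION = 0.62  # of stride time; typical adult value


@dataclass
class SubjectParams:
    """Everything needed to synthesise one subject's walk."""

    group: str  # 'PD' or 'CL'
    stride_frequency: float  # Hz, strides per second
    step_length: float  # m
    sensor_height: float  # m, ~0.53 x body height (L5 level)
    step_time_jitter_sd: float  # s
    amplitude_jitter_cv: float  # unitless, per-step multiplicative
    noise_sd: float  # m/s^2, additive white noise
    asymmetry_factor: float  # in [0, 1]; 0 = perfectly symmetric
    seed: int
    ml_amplitude: float = 0.95  # m/s^2, ML fundamental amplitude
    ap_scale: float = 0.70  # AP amplitude relative to VT
    duration: float = 120.0  # s
    fs: float = 100.0  # Hz
    global_gain: float = 1.0  # multiplies the whole gait signal + noise
    mat_length: float = 5.5  # m of instrumented mat covered per pass
    circuit_length: float = 25.0  # m of the oval circuit
    axis_amplitudes: Optional[dict] = None  # {axis: [(h, amp, phase), ...]}

    def __post_init__(self) -> None:
        if not (0.5 < self.stride_frequency < 1.5):
            raise GaitError("stride_frequency must lie in (0.5, 1.5) Hz")
        if not (0.0 <= self.asymmetry_factor <= 1.0):
            raise GaitError("asymmetry_factor must lie in [0, 1]")
        for name in ("step_time_jitter_sd", "amplitude_jitter_cv", "noise_sd"):
            if getattr(self, name) < 0:
                raise GaitError(f"{name} must be >= 0")
        if self.step_length <= 0 or self.sensor_height <= 0:
            raise GaitError("step_length and sensor_height must be positive")
        if self.ml_amplitude < 0 or self.ap_scale < 0 or self.global_gain < 0:
            raise GaitError("amplitudes must be >= 0")

    @property
    def step_time(self) -> float:
        return 1.0 / (2.0 * self.stride_frequency)

    @property
    def step_velocity(self) -> float:
        return self.step_length / self.step_time


@dataclass
class SubjectTruth:
    """Generator-side ground truth for recovery tests."""

    step_boundaries: np.ndarray  # times of every heel strike (s), on & off mat
    feet: np.ndarray  # foot striking at each boundary
    step_times: np.ndarray  # t[k+1] - t[k]
    step_lengths: np.ndarray  # per-step inverted-pendulum length (m)
    pass_step_ranges: list  # [(k0, k1) half-open step-index ranges on mat]
    vertical_excursion: float  # nominal per-step VT displacement ptp (m)

    @property
    def mat_step_indices(self) -> np.ndarray:
        idx = [np.arange(k0, k1) for k0, k1 in self.pass_step_ranges]
        return np.concatenate(idx) if idx else np.array([], dtype=int)


@dataclass
class SyntheticSubject:
    recording: RawRecording
    events: GaitEvents
    demographics: Demographics
    truth: SubjectTruth
    params: SubjectParams


def _pendulum_excursion(step_length: float, sensor_height: float) -> float:
    """Vertical CoM excursion implied by step length under the inverted
    pendulum: L = 2*sqrt(2*l*h - h^2)  =>  h = l - sqrt(l^2 - L^2/4)."""
    l, L = sensor_height, step_length
    if L >= 2 * l:
        raise GaitError("step_length must be < 2 x sensor_height")
    return l - np.sqrt(l**2 - L**2 / 4.0)


def _pendulum_length(h: np.ndarray, sensor_height: float) -> np.ndarray:
    h = np.minimum(h, sensor_height)
    return 2.0 * np.sqrt(np.maximum(2.0 * sensor_height * h - h**2, 0.0))


def _vt_amplitude_scale(params: SubjectParams, harmonics) -> float:
    """Scale factor mapping relative VT harmonic amplitudes to absolute
    m/s^2 so the ideal per-step displacement peak-to-peak equals the
    pendulum excursion for the subject's step length."""
    h_target = _pendulum_excursion(params.step_length, params.sensor_height)
    f = params.stride_frequency
    phi = np.linspace(0.0, np.pi, 512)  # one step of stride phase
    disp = np.zeros_like(phi)
    for h, amp, psi in harmonics:
        disp -= amp / (2 * np.pi * h * f) ** 2 * np.cos(h * phi + psi)
    ptp_rel = disp.max() - disp.min()
    return h_target / ptp_rel


def default_axis_amplitudes(params: SubjectParams) -> dict:
    scale = _vt_amplitude_scale(params, VT_HARMONICS)
    return {
        "vt": [(h, scale * a, p) for h, a, p in VT_HARMONICS],
        "ml": [(h, params.ml_amplitude * a, p) for h, a, p in ML_HARMONICS],
        "ap": [(h, scale * params.ap_scale * a, p) for h, a, p in AP_HARMONICS],
    }


def minimum_duration(params: SubjectParams) -> float:
    """Shortest recording that still contains two complete mat passes."""
    steps_per_pass = max(4, round(params.mat_length / params.step_length))
    steps_per_lap = max(steps_per_pass + 4,
                        round(params.circuit_length / params.step_length))
    lead_in = (steps_per_lap - steps_per_pass) // 2
    n_needed = lead_in + steps_per_lap + steps_per_pass + 2
    return n_needed * params.step_time


def generate_subject(params: SubjectParams,
                     subject_id: Optional[str] = None,
                     demographics: Optional[Demographics] = None,
                     ) -> SyntheticSubject:
    """Synthesise one subject: signal, mat-annotated events, demographics."""
    rng = np.random.default_rng(params.seed)
    fs, dur = params.fs, params.duration

    min_dur = minimum_duration(params)
    if dur < min_dur:
        raise GaitError(
            f"duration {dur:g} s too short for >= 2 passes; "
            f"minimum is {min_dur:.1f} s for these parameters"
        )

    # --- step train ----------------------------------------------------
    n_steps = int(np.ceil(dur / params.step_time)) + 4
    intervals = params.step_time + rng.normal(
        0.0, params.step_time_jitter_sd, size=n_steps)
    intervals = np.maximum(intervals, 0.3 * params.step_time)
    boundaries = np.concatenate([[0.0], np.cumsum(intervals)])
    feet = np.where(np.arange(len(boundaries)) % 2 == 0, "L", "R")

    # per-step multiplicative envelope: amplitude jitter x L/R asymmetry
    amp_jit = 1.0 + rng.normal(0.0, params.amplitude_jitter_cv, size=n_steps)
    foot_scale = np.where(feet[:-1] == "L",
                          1.0 - params.asymmetry_factor / 2.0,
                          1.0 + params.asymmetry_factor / 2.0)
    envelope = np.maximum(amp_jit * foot_scale, 0.05)

    # --- signal ---------------------------------------------------------
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    # stride phase: advances by pi per step, piecewise linear in time
    phase = np.pi * np.interp(t, boundaries, np.arange(len(boundaries)))
    step_of_sample = np.clip(
        np.searchsorted(boundaries, t, side="right") - 1, 0, n_steps - 1)
    env_t = envelope[step_of_sample]

    amps = params.axis_amplitudes or default_axis_amplitudes(params)
    samples = np.empty((n, 3))
    for col, axis in enumerate(("vt", "ml", "ap")):
        sig = np.zeros(n)
        for h, a, psi in amps[axis]:
            sig += a * np.cos(h * phase + psi)
        sig = sig * env_t + rng.normal(0.0, params.noise_sd, size=n)
        samples[:, col] = params.global_gain * sig
    samples[:, 0] += G  # gravity on VT

    # --- mat passes -----------------------------------------------------
    steps_per_pass = max(4, round(params.mat_length / params.step_length))
    steps_per_lap = max(steps_per_pass + 4,
                        round(params.circuit_length / params.step_length))
    lead_in = (steps_per_lap - steps_per_pass) // 2
    pass_ranges = []
    k0 = lead_in
    while k0 + steps_per_pass + 1 < n_steps and \
            boundaries[k0 + steps_per_pass] < dur - 2.0 / fs:
        pass_ranges.append((k0, k0 + steps_per_pass))
        k0 += steps_per_lap

    heel_strikes: list[tuple[float, str]] = []
    toe_offs: list[tuple[float, str]] = []
    passes: list[tuple[float, float]] = []
    eps = 2.0 / fs
    for k0, k1 in pass_ranges:
        start, end = boundaries[k0] - eps, boundaries[k1] + eps
        passes.append((max(start, 0.0), min(end, dur)))
        for k in range(k0, k1 + 1):
            heel_strikes.append((boundaries[k], feet[k]))
        for k in range(k0, k1 + 1):
            if k + 2 < len(boundaries):
                to = boundaries[k] + STANCE_FRACTION * (
                    boundaries[k + 2] - boundaries[k])
                if boundaries[k0] - eps <= to < boundaries[k1] + eps:
                    toe_offs.append((to, feet[k]))

    # --- ground truth ---------------------------------------------------
    h_nominal = _pendulum_excursion(params.step_length, params.sensor_height)
    h_per_step = h_nominal * envelope * params.global_gain
    step_lengths = _pendulum_length(h_per_step, params.sensor_height)
    truth = SubjectTruth(
        step_boundaries=boundaries,
        feet=feet,
        step_times=intervals,
        step_lengths=step_lengths,
        pass_step_ranges=pass_ranges,
        vertical_excursion=h_nominal,
    )

    if demographics is None:
        demographics = _demographics_from_params(params, rng)
    sid = subject_id or f"{params.group}{params.seed % 100000:05d}"
    rec = RawRecording(subject_id=sid, fs=fs, samples=samples)
    ev = GaitEvents(heel_strikes=heel_strikes, toe_offs=toe_offs, passes=passes)
    return SyntheticSubject(rec, ev, demographics, truth, params)


# --------------------------------------------------------------------------
# group-level parameter distributions (the study conditions)
# --------------------------------------------------------------------------

# control (CL) distributions: (mean, sd, lower, upper)
CL_PARAM_DISTS = {
    "stride_frequency": (1.00, 0.06, 0.80, 1.30),
    "step_length": (0.68, 0.06, 0.45, 0.90),
    "step_time_jitter_sd": (0.010, 0.003, 0.002, 0.040),
    "amplitude_jitter_cv": (0.050, 0.015, 0.010, 0.200),
    "noise_sd": (0.12, 0.03, 0.04, 0.30),
    "asymmetry_factor": (0.030, 0.020, 0.0, 0.40),
    "ml_amplitude": (0.95, 0.12, 0.40, 1.60),
    "ap_scale": (0.70, 0.08, 0.35, 1.10),
}

# PD mean shifts in CL-SD units (magnitudes on the order of the ~1-SD
# group separations typical of early-disease cohorts), scaled by the
# cohort effect_scale
PD_PARAM_EFFECTS = {
    "noise_sd": 0.0,
    "stride_frequency": -0.3,
    "step_length": -0.8,
    "step_time_jitter_sd": +0.8,
    "amplitude_jitter_cv": +0.6,
    "asymmetry_factor": +0.5,
    "ml_amplitude": -0.8,
    "ap_scale": -0.4,
}

# demographics: (mean, sd, lower, upper) for CL, and PD shift in CL-SD units
CL_DEMO_DISTS = {
    "age": (69.0, 8.0, 45.0, 92.0),
    "height": (1.73, 0.09, 1.45, 2.00),
    "weight": (81.0, 13.0, 45.0, 130.0),
    "moca": (27.5, 1.8, 0.0, 30.0),
}
PD_DEMO_EFFECTS = {"age": 0.0, "height": -0.45, "weight": -0.4, "moca": -1.3}
P_MALE = {"CL": 0.50, "PD": 0.65}


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def draw_demographics(group: str, rng: np.random.Generator,
                      effect_scale: float = 1.0) -> Demographics:
    vals = {}
    for name, (m, s, lo, hi) in CL_DEMO_DISTS.items():
        shift = PD_DEMO_EFFECTS[name] * s * effect_scale if group == "PD" else 0.0
        vals[name] = _trunc_normal(rng, m + shift, s, lo, hi)
    sex = "M" if rng.random() < (
        P_MALE["CL"] + (P_MALE["PD"] - P_MALE["CL"]) * effect_scale
        if group == "PD" else P_MALE["CL"]) else "F"
    height = vals["height"]
    weight = vals["weight"]
    return Demographics(
        age=round(vals["age"], 1), sex=sex, height=round(height, 3),
        weight=round(weight, 1),
        bmi=round(weight, 1) / round(height, 3) ** 2,
        moca=int(round(np.clip(vals["moca"], 0, 30))),
    )


def draw_subject_params(group: str, rng: np.random.Generator,
                        effect_scale: float = 1.0,
                        duration: float = 120.0, fs: float = 100.0,
                        height: Optional[float] = None,
                        **overrides) -> SubjectParams:
    """Draw one subject's generator parameters from the group distribution.

    effect_scale multiplies every PD-vs-CL mean shift; 0 yields a null
    cohort in which both groups share the CL distribution.
    """
    if group not in ("PD", "CL"):
        raise GaitError(f"unknown group {group!r}")
    vals = {}
    for name, (m, s, lo, hi) in CL_PARAM_DISTS.items():
        shift = PD_PARAM_EFFECTS[name] * s * effect_scale if group == "PD" else 0.0
        vals[name] = _trunc_normal(rng, m + shift, s, lo, hi)
    if height is None:
        height = _trunc_normal(rng, *CL_DEMO_DISTS["height"])
    params = dict(
        group=group,
        stride_frequency=vals["stride_frequency"],
        step_length=vals["step_length"],
        sensor_height=0.53 * height,
        step_time_jitter_sd=vals["step_time_jitter_sd"],
        amplitude_jitter_cv=vals["amplitude_jitter_cv"],
        noise_sd=vals["noise_sd"],
        asymmetry_factor=vals["asymmetry_factor"],
        ml_amplitude=vals["ml_amplitude"],
        ap_scale=vals["ap_scale"],
        duration=duration,
        fs=fs,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return SubjectParams(**params)


def _demographics_from_params(params: SubjectParams,
                              rng: np.random.Generator) -> Demographics:
    demo = draw_demographics(params.group, rng)
    # keep height consistent with the sensor height used for the signal
    height = round(params.sensor_height / 0.53, 3)
    return Demographics(age=demo.age, sex=demo.sex, height=height,
                        weight=demo.weight, bmi=demo.weight / height**2,
                        moca=demo.moca)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort-level generation settings; defaults mirror the emulated
    protocol: 81 PD + 61 CL, two-minute walks sampled at 100 Hz."""

    n_pd: int = 81
    n_cl: int = 61
    seed: int = 0
    duration: float = 120.0
    fs: float = 100.0
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pd <= 0 or self.n_cl <= 0:
            raise GaitError("group sizes must be positive")


@dataclass
class Cohort:
    subjects: list  # of SyntheticSubject
    config: CohortConfig
    manifest: dict

    @property
    def demographics_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            d = s.demographics
            rows.append({
                "subject_id": s.recording.subject_id,
                "group": s.params.group,
                "age": d.age, "sex": d.sex, "height_m": d.height,
                "weight_kg": d.weight, "bmi": d.bmi, "moca": d.moca,
            })
        return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig,
                    out_dir: Optional[str | Path] = None) -> Cohort:
    """Generate a full cohort; optionally write it to disk as flat CSVs."""
    rng = np.random.default_rng(config.seed)
    subjects = []
    subject_seeds = {}
    for group, n in (("PD", config.n_pd), ("CL", config.n_cl)):
        for i in range(n):
            demo = draw_demographics(group, rng,
                                     effect_scale=config.effect_scale)
            params = draw_subject_params(
                group, rng, effect_scale=config.effect_scale,
                duration=config.duration, fs=config.fs,
                height=demo.height)
            sid = f"{group}{i + 1:03d}"
            subjects.append(
                generate_subject(params, subject_id=sid, demographics=demo))
            subject_seeds[sid] = params.seed

    manifest = {
        "config": asdict(config),
        "subject_seeds": subject_seeds,
        "n_subjects": len(subjects),
    }
    manifest["hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    cohort = Cohort(subjects=subjects, config=config, manifest=manifest)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        sid = s.recording.subject_id
        t = np.arange(s.recording.n_samples) / s.recording.fs
        pd.DataFrame({
            "time_s": t,
            "vt": s.recording.vt, "ml": s.recording.ml, "ap": s.recording.ap,
        }).to_csv(out / f"{sid}_accel.csv", index=False, float_format="%.6f")
        ev_rows = [{"time_s": t_, "event_type": "HS", "foot": f}
                   for t_, f in s.events.heel_strikes]
        ev_rows += [{"time_s": t_, "event_type": "TO", "foot": f}
                    for t_, f in s.events.toe_offs]
        ev = pd.DataFrame(ev_rows).sort_values("time_s")
        ev.to_csv(out / f"{sid}_events.csv", index=False, float_format="%.6f")
        pd.DataFrame(s.events.passes, columns=["start_s", "end_s"]).to_csv(
            out / f"{sid}_passes.csv", index=False, float_format="%.6f")
    cohort.demographics_frame.to_csv(out / "demographics.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
    return out


def load_cohort(cohort_dir: str | Path) -> list[dict]:
    """Load a written cohort back as dicts with recording/events/demographics.

    Ground truth is not serialised; loaded subjects carry truth=None.
    """
    out = Path(cohort_dir)
    demo = pd.read_csv(out / "demographics.csv")
    subjects = []
    for _, row in demo.iterrows():
        sid = row["subject_id"]
        acc = pd.read_csv(out / f"{sid}_accel.csv")
        fs = 1.0 / np.median(np.diff(acc["time_s"].to_numpy()))
        rec = RawRecording(subject_id=sid, fs=float(round(fs, 3)),
                           samples=acc[["vt", "ml", "ap"]].to_numpy())
        ev = pd.read_csv(out / f"{sid}_events.csv")
        hs = [(float(r.time_s), str(r.foot)) for r in
              ev[ev.event_type == "HS"].itertuples()]
        to = [(float(r.time_s), str(r.foot)) for r in
              ev[ev.event_type == "TO"].itertuples()]
        pa = pd.read_csv(out / f"{sid}_passes.csv")
        passes = [(float(r.start_s), float(r.end_s)) for r in pa.itertuples()]
        height = float(row["height_m"])
        demographics = Demographics(
            age=float(row["age"]), sex=str(row["sex"]), height=height,
            weight=float(row["weight_kg"]),
            bmi=float(row["weight_kg"]) / height**2, moca=int(row["moca"]))
        subjects.append({
            "subject_id": sid, "group": str(row["group"]),
            "recording": rec,
            "events": GaitEvents(hs, to, passes),
            "demographics": demographics,
            "sensor_height": 0.53 * height,
        })
    return subjects
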