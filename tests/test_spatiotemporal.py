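"""Spatiotemporal characteristics: event timings, pendulum step length,
and the 25-item vector."""

import numpy as np
import pytest

from conftest import make_params

from gaitbattery.features import spatiotemporal as st
from gaitbattery.synthetic import generate_subject
from gaitbattery.types import GaitError, GaitEvents


def test_temporal_definitions_on_worked_example():
    ev = GaitEvents(
        heel_strikes=[(0.0, "L"), (0.55, "R"), (1.10, "L")],
        toe_offs=[(0.70, "L")],
        passes=[(0.0, 1.2)],
    )
    tp = st.temporal_params(ev)
    assert tp["step_time"].tolist() == pytest.approx([0.55, 0.55])
    row = tp.iloc[0]
    assert row["stride_time"] == pytest.approx(1.10)
    assert row["stance_time"] == pytest.approx(0.70)
    assert row["swing_time"] == pytest.approx(0.40)


def test_single_heel_strike_rejected():
    ev = GaitEvents(heel_strikes=[(0.0, "L")], toe_offs=[],
                    passes=[(0.0, 1.0)])
    with pytest.raises(GaitError):
        st.temporal_params(ev)


def test_pendulum_closed_form():
    assert st.pendulum_step_length(0.0, 1.0) == 0.0
    assert st.pendulum_step_length(0.02, 1.0) == \
        pytest.approx(2 * np.sqrt(0.04 - 0.0004), abs=1e-10)
    assert st.pendulum_step_length(0.02, 1.0) == pytest.approx(0.39799,
                                                               abs=1e-5)
    assert st.pendulum_step_length(0.02, 1.0, corrected=True) == \
        pytest.approx(1.25 * 0.39799, abs=1e-4)
    with pytest.raises(GaitError):
        st.pendulum_step_length(1.5, 1.0)


def test_step_length_recovers_known_sinusoidal_displacement():
    # VT acceleration whose analytic displacement amplitude is known
    fs, f, dur = 100.0, 2.0, 6.0
    t = np.arange(int(fs * dur)) / fs
    amp_acc = 1.5
    vt = amp_acc * np.cos(2 * np.pi * f * t)
    h_true = 2 * amp_acc / (2 * np.pi * f) ** 2  # peak-to-peak
    l = 0.9
    est = st.step_length_pendulum(vt, l, fs)
    ref = st.pendulum_step_length(h_true, l)
    assert est == pytest.approx(ref, rel=0.10)
    with pytest.raises(GaitError):
        st.step_length_pendulum(np.array([]), l, fs)


def test_excessive_excursion_gives_missing(caplog):
    fs = 100.0
    t = np.arange(600) / fs
    vt = 80.0 * np.cos(2 * np.pi * 1.0 * t)  # huge displacement
    with caplog.at_level("WARNING"):
        out = st.step_length_pendulum(vt, 0.2, fs)
    assert np.isnan(out)


def test_clean_subject_step_time_sd_below_sample_period(clean_subject):
    tp = st.temporal_params(clean_subject.events)
    assert tp["step_time"].std() < 1.0 / clean_subject.recording.fs


def test_vector_has_25_features_and_symmetric_gait_zero_asymmetry(
        clean_subject, preprocessed_clean):
    s = clean_subject
    vec = st.spatiotemporal_vector(preprocessed_clean, s.events,
                                   s.params.sensor_height)
    assert len(vec) == 25
    assert set(vec) == set(st.FEATURE_NAMES)
    assert abs(vec["st_step_time_asym"]) < 1e-3 * vec["st_step_time_mean"]
    assert abs(vec["st_step_length_asym"]) < \
        1e-2 * vec["st_step_length_mean"]
    # internal consistency
    assert vec["st_cadence"] == pytest.approx(
        60.0 / vec["st_step_time_mean"], abs=1e-6)
    assert vec["st_stance_time_mean"] + vec["st_swing_time_mean"] == \
        pytest.approx(vec["st_stride_time_mean"], rel=0.02)


@pytest.fixture(scope="module")
def preprocessed_clean(clean_subject):
    from gaitbattery.segmentation import preprocess

    return preprocess(clean_subject.recording)


def test_doubling_event_spacing_halves_cadence():
    ev1 = GaitEvents(
        heel_strikes=[(0.0, "L"), (0.5, "R"), (1.0, "L"), (1.5, "R")],
        toe_offs=[], passes=[(0.0, 1.6)])
    ev2 = GaitEvents(
        heel_strikes=[(0.0, "L"), (1.0, "R"), (2.0, "L"), (3.0, "R")],
        toe_offs=[], passes=[(0.0, 3.2)])
    c1 = 60.0 / st.temporal_params(ev1)["step_time"].mean()
    c2 = 60.0 / st.temporal_params(ev2)["step_time"].mean()
    assert c2 == pytest.approx(c1 / 2.0, abs=1e-9)


def test_parameter_recovery_across_subjects():
    """Mean step time recovered to within one sample period; step length
    to within 15% (the pendulum's systematic bias is tolerated)."""
    from gaitbattery.segmentation import preprocess

    t_errs, l_rel_errs = [], []
    for seed in range(20):
        s = generate_subject(make_params(seed=seed, duration=45.0))
        rec = preprocess(s.recording)
        vec = st.spatiotemporal_vector(rec, s.events,
                                       s.params.sensor_height)
        mat = s.truth.mat_step_indices
        true_t = float(np.mean(s.truth.step_times[mat]))
        true_l = float(np.mean(s.truth.step_lengths[mat]))
        t_errs.append(abs(vec["st_step_time_mean"] - true_t))
        l_rel_errs.append(abs(vec["st_step_length_mean"] - true_l) / true_l)
    assert np.mean(t_errs) < 1.0 / 100.0
    assert np.mean(l_rel_errs) < 0.15


def test_time_cvs_invariant_to_amplitude_scaling(default_subject):
    from gaitbattery.segmentation import preprocess
    from gaitbattery.types import RawRecording

    s = default_subject
    rec = preprocess(s.recording)
    scaled = RawRecording(s.recording.subject_id, rec.fs, 2.0 * rec.samples)
    v1 = st.spatiotemporal_vector(rec, s.events, s.params.sensor_height)
    v2 = st.spatiotemporal_vector(scaled, s.events, s.params.sensor_height)
    for name in ("st_step_time_cv", "st_stride_time_cv", "st_cadence"):
        assert v2[name] == pytest.approx(v1[name], abs=1e-9)
    # sqrt-law of the pendulum keeps length CV nearly scale-free
    assert v2["st_step_length_cv"] == pytest.approx(
        v1["st_step_length_cv"], rel=0.10)
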