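"""Generator contracts: determinism, periodicity, event consistency,
group structure."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_clean_params, make_params

from gaitbattery.features.regularity import step_stride_regularity
from gaitbattery.synthetic import (
    CohortConfig,
    SubjectParams,
    draw_subject_params,
    generate_cohort,
    generate_subject,
    load_cohort,
    minimum_duration,
)
from gaitbattery.types import G, GaitError


def test_fixed_seed_gives_bit_identical_recordings():
    p = make_params(seed=123)
    a, b = generate_subject(p), generate_subject(p)
    assert np.array_equal(a.recording.samples, b.recording.samples)
    assert a.events.heel_strikes == b.events.heel_strikes
    assert a.events.passes == b.events.passes


def test_clean_gait_is_perfectly_regular(clean_subject):
    s = clean_subject
    vt = s.recording.vt - G
    ad1, ad2, sym = step_stride_regularity(
        vt, float(np.mean(s.truth.step_times)),
        2 * float(np.mean(s.truth.step_times)), s.recording.fs)
    assert ad1 == pytest.approx(1.0, abs=0.01)
    assert ad2 == pytest.approx(1.0, abs=0.01)


def test_dominant_vt_frequency_is_step_frequency():
    # independent FFT oracle on the generated signal
    s = generate_subject(make_clean_params(stride_frequency=1.0))
    vt = s.recording.vt - np.mean(s.recording.vt)
    freqs = np.fft.rfftfreq(len(vt), 1.0 / s.recording.fs)
    peak = freqs[np.argmax(np.abs(np.fft.rfft(vt)))]
    assert peak == pytest.approx(2.0, abs=0.05)


def test_event_annotations_match_ground_truth(default_subject):
    s = default_subject
    dur = s.recording.duration
    for start, end in s.events.passes:
        assert 0 <= start < end <= dur
    # heel-strike intervals reproduce the generator's step times
    hs = s.events.hs_times()
    bounds = s.truth.step_boundaries
    for t0, t1 in zip(hs, hs[1:]):
        if t1 - t0 > 1.0:  # gap between passes
            continue
        k = int(np.argmin(np.abs(bounds - t0)))
        assert t1 - t0 == pytest.approx(s.truth.step_times[k],
                                        abs=1.0 / s.recording.fs)


def test_feet_alternate_within_passes(default_subject):
    ev = default_subject.events
    for start, end in ev.passes:
        feet = [f for _, f in ev.heel_strikes_in(start, end)]
        assert len(feet) >= 4
        assert all(a != b for a, b in zip(feet, feet[1:]))


def test_too_short_duration_raises_with_minimum():
    p = make_params()
    min_dur = minimum_duration(p)
    with pytest.raises(GaitError, match="minimum"):
        generate_subject(make_params(duration=0.5 * min_dur))


@pytest.mark.parametrize("field,value", [
    ("stride_frequency", 0.4), ("stride_frequency", 1.6),
    ("asymmetry_factor", 1.5), ("step_time_jitter_sd", -0.01),
    ("noise_sd", -1.0),
])
def test_invalid_parameters_rejected(field, value):
    with pytest.raises(GaitError):
        make_params(**{field: value})


def test_more_step_jitter_means_less_stride_regularity():
    jitters = (0.005, 0.02, 0.05)
    means = []
    for j in jitters:
        vals = []
        for seed in range(20):
            s = generate_subject(make_params(
                step_time_jitter_sd=j, seed=seed, duration=45.0))
            st = float(np.mean(s.truth.step_times))
            _, ad2, _ = step_stride_regularity(
                s.recording.vt - G, st, 2 * st, s.recording.fs)
            vals.append(ad2)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


def test_vt_rms_scales_linearly_with_global_gain():
    base = generate_subject(make_clean_params(global_gain=1.0))
    double = generate_subject(make_clean_params(global_gain=2.0))
    rms = lambda s: np.sqrt(np.mean((s.recording.vt - G) ** 2))
    assert rms(double) / rms(base) == pytest.approx(2.0, rel=0.02)


def test_default_cohort_has_study_group_sizes():
    cohort = generate_cohort(CohortConfig(seed=3, duration=60.0))
    demo = cohort.demographics_frame
    assert (demo.group == "PD").sum() == 81
    assert (demo.group == "CL").sum() == 61
    assert set(demo.columns) == {"subject_id", "group", "age", "sex",
                                 "height_m", "weight_kg", "bmi", "moca"}


def test_nonpositive_group_size_rejected():
    with pytest.raises(GaitError):
        CohortConfig(n_pd=0)


def test_null_cohort_t_test_rejects_at_nominal_rate():
    """With all effects zeroed, a two-sample t-test on mean step velocity
    should reject at ~ the nominal 5% rate (Monte-Carlo over replicate
    parameter-level cohorts)."""
    rng = np.random.default_rng(99)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        pd_v = [draw_subject_params("PD", rng, effect_scale=0.0).step_velocity
                for _ in range(25)]
        cl_v = [draw_subject_params("CL", rng, effect_scale=0.0).step_velocity
                for _ in range(25)]
        if stats.ttest_ind(pd_v, cl_v, equal_var=False).pvalue < 0.05:
            rejections += 1
    assert 0.01 <= rejections / n_rep <= 0.11


def test_pd_parameters_shift_in_expected_directions():
    rng = np.random.default_rng(5)
    pd_p = [draw_subject_params("PD", rng) for _ in range(150)]
    cl_p = [draw_subject_params("CL", rng) for _ in range(150)]
    assert np.mean([p.step_length for p in pd_p]) < \
        np.mean([p.step_length for p in cl_p])
    assert np.mean([p.step_time_jitter_sd for p in pd_p]) > \
        np.mean([p.step_time_jitter_sd for p in cl_p])
    assert np.mean([p.ml_amplitude for p in pd_p]) < \
        np.mean([p.ml_amplitude for p in cl_p])


def test_manifest_hash_reproducible():
    a = generate_cohort(CohortConfig(n_pd=2, n_cl=2, seed=17, duration=60.0))
    b = generate_cohort(CohortConfig(n_pd=2, n_cl=2, seed=17, duration=60.0))
    assert a.manifest["hash"] == b.manifest["hash"]
    c = generate_cohort(CohortConfig(n_pd=2, n_cl=2, seed=18, duration=60.0))
    assert c.manifest["hash"] != a.manifest["hash"]


def test_cohort_disk_round_trip(tmp_path):
    cohort = generate_cohort(CohortConfig(n_pd=2, n_cl=2, seed=21,
                                          duration=60.0),
                             out_dir=tmp_path)
    loaded = load_cohort(tmp_path)
    assert len(loaded) == 4
    orig = cohort.subjects[0]
    back = next(s for s in loaded
                if s["subject_id"] == orig.recording.subject_id)
    assert np.allclose(back["recording"].samples, orig.recording.samples,
                       atol=1e-5)
    assert np.allclose(np.array(back["events"].passes),
                       np.array(orig.events.passes), atol=1e-5)
    assert back["demographics"].moca == orig.demographics.moca
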