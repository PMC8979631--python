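import numpy as np
import pytest

from gaitbattery.synthetic import (
    CL_PARAM_DISTS,
    PD_PARAM_EFFECTS,
    SubjectParams,
    generate_subject,
)

DEFAULT_HEIGHT = 1.73


def make_params(**kw) -> SubjectParams:
    """A realistic control subject; override any field."""
    base = dict(
        group="CL", stride_frequency=1.0, step_length=0.68,
        sensor_height=0.53 * DEFAULT_HEIGHT, step_time_jitter_sd=0.010,
        amplitude_jitter_cv=0.05, noise_sd=0.12, asymmetry_factor=0.03,
        seed=0, duration=60.0,
    )
    base.update(kw)
    return SubjectParams(**base)


def make_clean_params(**kw) -> SubjectParams:
    """Perfectly periodic, symmetric, noise-free gait."""
    base = dict(step_time_jitter_sd=0.0, amplitude_jitter_cv=0.0,
                noise_sd=0.0, asymmetry_factor=0.0, seed=1)
    base.update(kw)
    return make_params(**base)


def group_mean_params(group: str, seed: int, effect_scale: float = 1.0,
                      **kw) -> SubjectParams:
    """Subject at the exact group-mean generator parameters (no
    between-subject sampling); randomness then comes only from the
    within-subject jitter/noise streams."""
    vals = {name: m for name, (m, s, lo, hi) in CL_PARAM_DISTS.items()}
    if group == "PD":
        for name, eff in PD_PARAM_EFFECTS.items():
            vals[name] = vals[name] + eff * CL_PARAM_DISTS[name][1] * \
                effect_scale
    base = dict(
        group=group, stride_frequency=vals["stride_frequency"],
        step_length=vals["step_length"],
        sensor_height=0.53 * DEFAULT_HEIGHT,
        step_time_jitter_sd=vals["step_time_jitter_sd"],
        amplitude_jitter_cv=vals["amplitude_jitter_cv"],
        noise_sd=vals["noise_sd"],
        asymmetry_factor=vals["asymmetry_factor"],
        ml_amplitude=vals["ml_amplitude"], ap_scale=vals["ap_scale"],
        seed=seed, duration=60.0,
    )
    base.update(kw)
    return SubjectParams(**base)


@pytest.fixture(scope="session")
def clean_subject():
    return generate_subject(make_clean_params())


@pytest.fixture(scope="session")
def default_subject():
    return generate_subject(make_params(seed=42))


@pytest.fixture(scope="session")
def preprocessed_default(default_subject):
    from gaitbattery.segmentation import preprocess

    return preprocess(default_subject.recording)


@pytest.fixture(scope="session")
def default_features(default_subject):
    """Full 210-characteristic vector of the default subject."""
    from gaitbattery.pipeline import extract_subject

    s = default_subject
    return extract_subject(s.recording, s.events, s.params.sensor_height)


@pytest.fixture(scope="session")
def lorenz_signal():
    from chaoshelpers import lorenz_trajectory

    return lorenz_trajectory(duration=120.0, fs=100.0)


@pytest.fixture(scope="session")
def lorenz_oracle_lambda():
    from chaoshelpers import benettin_lyapunov

    return benettin_lyapunov(duration=60.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but classification-ready cohort (shared across tests)."""
    from gaitbattery.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_pd=10, n_cl=8, seed=11,
                                        duration=45.0))


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    from gaitbattery.pipeline import extract_features

    return extract_features(small_cohort)
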