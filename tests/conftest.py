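from dataclasses import replace

import numpy as np
import pytest

import fbgchew as fc


@pytest.fixture(scope="session")
def profiles():
    return fc.default_profiles()


@pytest.fixture(scope="session")
def zero_noise_profiles(profiles):
    """Deterministic waveforms: no additive noise, no amplitude/period jitter."""
    return {
        name: replace(
            p,
            noise_sd_microstrain=0.0,
            amplitude_jitter_cv=0.0,
            period_jitter_cv=0.0,
        )
        for name, p in profiles.items()
    }


@pytest.fixture(scope="session")
def sensor():
    return fc.SensorModel()


def make_session_dataset(profiles, sensor, per_class, seed):
    spec = fc.SessionSpec(
        segments=tuple((c, per_class) for c in fc.CLASSES), seed=seed
    )
    trace = fc.encode_wavelength(fc.generate_session(spec, profiles), sensor)
    movements = fc.segment_movements(trace)
    return fc.build_dataset(
        movements, spec.sampling_rate_hz, fc.FeatureParams(), per_class_cap=per_class
    )


@pytest.fixture(scope="session")
def small_noisy_dataset(profiles, sensor):
    """Default-noise dataset, 30 instances per class."""
    return make_session_dataset(profiles, sensor, per_class=30, seed=11)


@pytest.fixture(scope="session")
def zero_noise_dataset(zero_noise_profiles, sensor):
    """Perfectly separable dataset, 20 instances per class."""
    return make_session_dataset(zero_noise_profiles, sensor, per_class=20, seed=5)
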