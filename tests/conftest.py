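import numpy as np
import pytest

from adcconcord import synth
from adcconcord.fitting import FitConfig, fit_volume
from adcconcord.synth import (
    NoiseModel,
    add_noise,
    compute_trace,
    default_breast_spec,
    default_phantom_spec,
    make_breast,
    make_phantom,
)


@pytest.fixture(scope="session")
def phantom_spec():
    return default_phantom_spec()


@pytest.fixture(scope="session")
def phantom_study(phantom_spec):
    """Noiseless directional phantom study."""
    return make_phantom(phantom_spec)


@pytest.fixture(scope="session")
def phantom_trace(phantom_study):
    return compute_trace(phantom_study)


@pytest.fixture(scope="session")
def phantom_adc4_map(phantom_trace):
    """Canonical noiseless ADC4 map in 1e-6 mm^2/s."""
    return fit_volume(phantom_trace, FitConfig(method="loglinear"), "ADC4")


@pytest.fixture(scope="session")
def breast_spec():
    return default_breast_spec(seed=0)


@pytest.fixture(scope="session")
def breast_trace_noisy(breast_spec):
    """Breast trace study at the default b=0 SNR of 30."""
    study = make_breast(breast_spec)
    nm = NoiseModel("rician", sigma=breast_spec.s0 / synth.BREAST_SNR, seed=42)
    return compute_trace(add_noise(study, nm))


@pytest.fixture(scope="session")
def breast_adc4_reference(breast_trace_noisy):
    """Log-linear ADC4 map of the noisy breast study (harmonization reference)."""
    return fit_volume(breast_trace_noisy, FitConfig(method="loglinear"), "ADC4")
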