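import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import microdfc as m


@pytest.fixture(scope="session")
def truth_templates():
    return m.generate_template_maps(5, 32, seed=1)


@pytest.fixture(scope="session")
def noiseless_recording(truth_templates):
    """60-s single-subject recording with no noise and no residual activity."""
    cfg = m.SyntheticConfig(duration=60.0, noise_sd=0.0, residual_frac=0.0, seed=3)
    rec, truth = m.generate_subject_recording(truth_templates, cfg, "MCS", seed=7,
                                              subject_id="clean01")
    return rec, truth


@pytest.fixture(scope="session")
def noisy_recording(truth_templates):
    """Default-noise recording plus its 2-20 Hz filtered version."""
    cfg = m.SyntheticConfig(duration=120.0, seed=3)
    rec, truth = m.generate_subject_recording(truth_templates, cfg, "MCS", seed=11,
                                              subject_id="noisy01")
    filt = m.bandpass_filter(m.apply_average_reference(rec), 2.0, 20.0)
    return rec, filt, truth
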