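import numpy as np
import pytest

from vibrotap import (SubjectProfile, build_vt2_schedule, build_vt3_schedule,
                      preprocess, simulate_session)


@pytest.fixture(scope="session")
def high_snr_profile():
    """Strongly responding, clean subject: the pipeline should be near-perfect."""
    return SubjectProfile(p3_amplitude_uv=8.0, noise_sd_uv=1.0,
                          artifact_rate_per_min=0.0, compliance=1.0)


@pytest.fixture(scope="session")
def null_profile():
    """Non-responder: no evoked component at all."""
    return SubjectProfile(p3_amplitude_uv=0.0, noise_sd_uv=5.0,
                          artifact_rate_per_min=0.0)


@pytest.fixture(scope="session")
def quiet_profile():
    """Noise-free responder for exact evoked-shape checks."""
    return SubjectProfile(p3_amplitude_uv=4.0, noise_sd_uv=0.0,
                          alpha_amplitude_uv=0.0, artifact_rate_per_min=0.0)


@pytest.fixture(scope="session")
def vt2_small():
    """Short VT2 run (160 stimuli, 20 deviants) to keep simulations quick."""
    return build_vt2_schedule(n_stimuli=160, seed=11)


@pytest.fixture(scope="session")
def high_snr_vt2_features(vt2_small, high_snr_profile):
    rec = simulate_session(vt2_small, high_snr_profile, seed=21)
    return preprocess(rec)


@pytest.fixture(scope="session")
def high_snr_vt3_session(high_snr_profile):
    schedule = build_vt3_schedule(seed=13)
    return simulate_session(schedule, high_snr_profile, seed=23)
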