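import numpy as np
import pytest

from bioz import (
    ColeTissueModel,
    SubjectProfile,
    synthesize_recording,
    truth_from_hemodynamics,
)


@pytest.fixture(scope="session")
def whole_body_model() -> ColeTissueModel:
    """Reference whole-body 2R1C fixture: 681 ohm || (909 ohm + 3.3 nF)."""
    return ColeTissueModel(r_e=681.0, r_i=909.0, c=3.3e-9)


@pytest.fixture(scope="session")
def subject() -> SubjectProfile:
    return SubjectProfile(height=171.0)


@pytest.fixture(scope="session")
def clean_recording(subject):
    """Noiseless, respiration-free 10-beat recording with known truth."""
    truth = truth_from_hemodynamics(subject, z0=30.0, sv_target=45.63, hr=72.0, t_lve=0.3, n_beats=15)
    return truth, synthesize_recording(truth, fs=1000.0, respiration=None, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_recording(subject):
    """60 s recording with respiration and measurement noise (seeded)."""
    truth = truth_from_hemodynamics(subject, z0=30.0, sv_target=45.63, hr=72.0, t_lve=0.3, n_beats=70)
    rec = synthesize_recording(truth, fs=1000.0, respiration=(1.0, 0.25), noise_sd=0.05, seed=42)
    return truth, rec
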