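import numpy as np
import pytest

from spirodesat.dtw import warm_up
from spirodesat.features import extract_feature_vector
from spirodesat.segmentation import segment_record
from spirodesat.simulate import CaseProfile, generate_case

#: Short (but rule-satisfying) phase layout used by most signal-level tests:
#: pre 60 s, supine 640 s, transition 60 s, trendelenburg 640 s, post 60 s.
FAST_PHASES = (60.0, 640.0, 60.0, 640.0, 60.0)


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the DTW kernel once so individual tests time only the work."""
    warm_up()


@pytest.fixture(scope="session")
def fast_case():
    """One typical synthetic case with shortened phases."""
    profile = CaseProfile.from_severity(0.0, phase_durations_s=FAST_PHASES)
    return generate_case(profile, np.random.default_rng(42), case_id="fast")


@pytest.fixture(scope="session")
def fast_extraction(fast_case):
    """(record, trimmed segments, 176-feature vector) computed once."""
    segments = segment_record(fast_case)
    vector = extract_feature_vector(fast_case, segments)
    return fast_case, segments, vector


@pytest.fixture(scope="session")
def noise_free_profile():
    """Deterministic breathing: no channel noise, no breath-to-breath jitter."""
    return CaseProfile.from_severity(
        0.0, phase_durations_s=FAST_PHASES, noise_sd=(0.0, 0.0, 0.0),
        respiratory_period_sd_s=0.0, pip_breath_cv=0.0, vol_breath_cv=0.0)
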