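import numpy as np
import pytest

import betanf as b


@pytest.fixture(scope="session")
def default_calibration_session():
    """One synthetic calibration run with the default participant profile."""
    profile = b.SyntheticProfile(seed=11)
    schedule = b.build_calibration_schedule(seed=11)
    recording, markers = b.synthesize_session(profile, schedule)
    return profile, schedule, recording, markers


@pytest.fixture(scope="session")
def default_calibration(default_calibration_session):
    _, _, recording, markers = default_calibration_session
    return b.calibrate(recording, markers)


@pytest.fixture(scope="session")
def ic_epochs(default_calibration_session):
    """IC-anchored epochs wide enough to include the pre-trial baseline."""
    from betanf.calibration import CALIBRATION_EPOCH_S, epoch_by_event

    _, _, recording, markers = default_calibration_session
    return epoch_by_event(recording, markers, "ic", CALIBRATION_EPOCH_S)
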