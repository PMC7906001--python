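import numpy as np
import pytest

import gazehand as gh
from gazehand.pipeline import analyze_participant


@pytest.fixture(scope="session")
def default_spec():
    return gh.CohortSpec()


@pytest.fixture(scope="session")
def intermediate_participant(default_spec):
    """One simulated intermediate participant (10 tasks) with ground truth."""
    rng = np.random.default_rng(2024)
    return gh.simulate_participant(
        default_spec, gh.INTERMEDIATE, rng, "int00", "intermediate"
    )


@pytest.fixture(scope="session")
def analyzed_participant(intermediate_participant):
    """(participant, per-task records, eye events, hand events)."""
    p = intermediate_participant
    records, eye_ev, hand_ev = analyze_participant(p.gaze, p.hand, p.markers)
    return p, records, eye_ev, hand_ev


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
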