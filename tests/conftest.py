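import numpy as np
import pytest

from occucam.detection_data import DetectionHistory, SeasonLayout, TwoSpeciesHistory
from occucam.synthetic_data import make_study_fixture


def make_history(obs, label="winter", kind="binary", effort=None):
    """Single-season history from a small code matrix (-1 = missing)."""
    obs = np.asarray(obs, dtype=int)
    layout = SeasonLayout.from_lengths([(label, 2010)], obs.shape[1])
    if effort is None:
        effort = np.where(obs == -1, 0, 7)
    return DetectionHistory(
        [f"s{i}" for i in range(obs.shape[0])], layout, obs, effort, kind
    )


def make_pair(obs_a, obs_b, label="summer"):
    return TwoSpeciesHistory(
        make_history(obs_a, label), make_history(obs_b, label)
    )


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture(seed=7)
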