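import numpy as np
import pandas as pd
import pytest

from metacog.sdt import RatingCounts
from metacog.synthetic import ObserverParams, generate_design, simulate_observer


@pytest.fixture(scope="session")
def perception_design():
    spec, trials = generate_design("perception", seed=11)
    return spec, trials


@pytest.fixture(scope="session")
def fixed_evidence_design():
    """Single-difficulty design: |evidence| = 48 dots throughout."""
    spec, trials = generate_design("perception", conditions=(-48, 48),
                                   trials_per_condition=500, seed=12)
    return spec, trials


@pytest.fixture()
def tiny_trials():
    """Four trials covering all (stimulus, response) cells at extreme ratings."""
    return pd.DataFrame({
        "participant_id": "p0",
        "task": "perception",
        "evidence_level": [8, 8, -8, -8],
        "stimulus_side": ["left", "left", "right", "right"],
        "response_side": ["left", "right", "right", "left"],
        "confidence": [6, 1, 6, 1],
        "responded": True,
    })


def make_counts(counts, K=6):
    return RatingCounts(np.asarray(counts, dtype=float), K)
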