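import numpy as np
import pandas as pd
import pytest

from sfgamma.design import ExperimentDesign, generate_design
from sfgamma.montage import CHANNELS_POSTERIOR_14
from sfgamma.simulate import GroundTruthEffects, simulate_epochs


@pytest.fixture(scope="session")
def small_design():
    """Reduced-scale study: 3 participants, 20 trials/cell, posterior montage."""
    return ExperimentDesign(
        n_participants=3, trials_per_cell=20, channels=list(CHANNELS_POSTERIOR_14)
    )


@pytest.fixture(scope="session")
def schedule(small_design):
    return generate_design(small_design, seed=11)


@pytest.fixture(scope="session")
def truth():
    return GroundTruthEffects()


@pytest.fixture(scope="session")
def epochs_one(schedule, truth, small_design):
    """One simulated participant at reduced scale."""
    return simulate_epochs(schedule, truth, 11, design=small_design, participants=[1])


def single_cell_schedule(n_trials: int, participant: int = 1,
                         cell=("object", "BB")) -> pd.DataFrame:
    """Minimal schedule: n trials of one design cell for one participant."""
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n_trials),
            "block": 0,
            "objecthood": cell[0],
            "frequency": cell[1],
            "source_id": np.arange(n_trials) % 60,
            "category": "man-made",
        }
    )
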