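import numpy as np
import pandas as pd
import pytest

import facesd
from facesd import behavior, synthdata
from facesd.validation import small_erp_model


@pytest.fixture(scope="session")
def wheel():
    return facesd.MorphWheel()


@pytest.fixture(scope="session")
def small_trials():
    """4 participants x 2 blocks with default generator settings."""
    spec = facesd.DesignSpec(n_participants=4, n_blocks=2, seed=11)
    trials = facesd.generate_trials(spec)
    return facesd.simulate_responses(trials, facesd.ResponseModel(), seed=12)


@pytest.fixture(scope="session")
def small_epochs():
    """2 participants x 1 block of reduced-scale epochs (8 channels, 128 Hz)."""
    spec = facesd.DesignSpec(n_participants=2, n_blocks=1, seed=21)
    trials = facesd.generate_trials(spec)
    trials = behavior.add_derived_columns(trials)
    return synthdata.simulate_epochs(trials, small_erp_model(), seed=22)
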