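import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dalearn import cohort


@pytest.fixture(scope="session")
def small_spec():
    return cohort.default_cohort_spec(n_mice=2, n_sessions=3,
                                      trials_per_session=40, seed=11)


@pytest.fixture(scope="session")
def simulated_mouse(small_spec):
    """Three sessions of simulated trials with choices filled, one mouse."""
    w = cohort.make_weight_trajectories(small_spec, 0)
    frames = []
    for d in range(small_spec.n_sessions):
        tr = cohort.simulate_trials(small_spec, 0, d)
        tr = cohort.simulate_choices(tr, w, small_spec.alpha_true,
                                     small_spec.pi_true, seed=500 + d)
        frames.append(tr)
    return pd.concat(frames, ignore_index=True), w


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
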