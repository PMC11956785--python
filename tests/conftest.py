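import numpy as np
import pandas as pd
import pytest

from mmle import (
    CovariateProfile,
    GenerativeConfig,
    MultimorbidityDefinition,
    TransitionMatrixSet,
    TransitionModel,
    apply_exclusions,
    build_transition_records,
    derive_panel_states,
    generate_panel,
)

#: single-sex covariate mix used where only one stratum is needed
FEMALE_ONLY_MIX = {
    "sex": {"male": 0.0, "female": 1.0},
    "race": {"African": 0.799, "Asian/Indian": 0.012, "Coloured": 0.148, "white": 0.041},
    "education": {
        "less than secondary": 0.462,
        "secondary": 0.416,
        "post-secondary": 0.122,
    },
    "residence": {"urban": 0.502, "rural": 0.498},
}


@pytest.fixture(scope="session")
def small_panel():
    """A mid-sized panel under the default study conditions."""
    return generate_panel(GenerativeConfig(n_individuals=4000, seed=42))


@pytest.fixture(scope="session")
def derived_states(small_panel):
    panel, _ = apply_exclusions(small_panel.frame)
    return derive_panel_states(panel, MultimorbidityDefinition())


@pytest.fixture(scope="session")
def records(derived_states):
    return build_transition_records(derived_states)


@pytest.fixture(scope="session")
def fitted_female(records):
    return TransitionModel(records, sex="female").fit()


def random_matrix_set(seed: int, n_intervals: int = 33, start_age: float = 20.0):
    """A random valid transition-matrix set (structural zeros, row-stochastic)."""
    rng = np.random.default_rng(seed)
    mats = np.zeros((n_intervals, 4, 4))
    for k in range(n_intervals):
        mats[k, 0, :] = rng.dirichlet([20.0, 3.0, 1.0, 1.0])
        mats[k, 1, 1:] = rng.dirichlet([20.0, 3.0, 1.5])
        mats[k, 2, 2:] = rng.dirichlet([15.0, 2.0])
        mats[k, 3, 3] = 1.0
    return TransitionMatrixSet(
        start_age=start_age,
        truncation_age=start_age + 2.0 * n_intervals,
        matrices=mats,
        profile=CovariateProfile(),
    )
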