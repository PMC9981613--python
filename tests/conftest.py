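import warnings

import numpy as np
import pandas as pd
import pytest

from emavar.config import CohortConfig
from emavar.items import default_item_meta
from emavar.preprocess import rescale_responses
from emavar.synthetic import generate_cohort
from emavar.variability import patient_variability_matrix


@pytest.fixture(scope="session")
def item_meta():
    return default_item_meta()


@pytest.fixture(scope="session")
def small_cohort(item_meta):
    """A reduced cohort (n=90) shared across tests that only need shape."""
    cfg = CohortConfig(n_patients=90, n_noise_features=4, seed=2024)
    ema, features, labels = generate_cohort(cfg)
    return cfg, ema, features, labels


@pytest.fixture(scope="session")
def small_variability(small_cohort, item_meta):
    _, ema, features, labels = small_cohort
    scaled = rescale_responses(ema, item_meta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat, excluded, counts = patient_variability_matrix(scaled, item_meta)
    return mat, excluded, counts


def make_series(rng, n):
    """Random irregular series with strictly increasing times."""
    t = np.cumsum(rng.uniform(0.1, 3.0, size=n))
    y = rng.uniform(0, 100, size=n)
    return t, y
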