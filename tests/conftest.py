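import numpy as np
import pytest

import ranklomics as rk
from ranklomics.core import rows_to_dataset
from ranklomics.texture import extract_case_features


@pytest.fixture(scope="session")
def default_cohort_dataset():
    """The default two-class study cohort (32 wild-type + 7 mutant, seed 1234)."""
    cases = rk.generate_cohort(32, 7, seed=1234)
    return rows_to_dataset([extract_case_features(c) for c in cases])


@pytest.fixture(scope="session")
def balanced_cohort_dataset():
    """A balanced 20 + 20 cohort with the default class parameters."""
    cases = rk.generate_cohort(20, 20, seed=77)
    return rows_to_dataset([extract_case_features(c) for c in cases])


@pytest.fixture
def tie_free_image():
    """A float image with almost surely distinct values in (5, 240)."""
    rng = np.random.default_rng(42)
    return rk.GrayImage(rng.uniform(5.0, 240.0, size=(32, 32)))
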