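import numpy as np
import pandas as pd
import pytest

from refint.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with all artifact types, plus its truth."""
    cfg = SyntheticConfig(n_per_group=600, seed=11)
    frame, truth = generate_cohort(cfg)
    return cfg, frame, truth


@pytest.fixture
def tiny_raw_frame():
    """Hand-written raw table exercising every parsing corner."""
    return pd.DataFrame({
        "subject_id": ["A", "B", "C", "A", "D", "E", "F"],
        "sex": ["M", "F", "female", "male", "", "x", "F"],
        "age": ["42", "35.9", "", "42", "51", "60", "28"],
        "value": ["150.5", "80", "55", "160.0", "70", "90", "not-a-number"],
        "date": ["2012-01-05", "2013-06-01", "2014-02-02", "2011-03-02",
                 "2015-05-05", "2016-06-06", "2017-07-07"],
    })
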