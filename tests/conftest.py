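import pandas as pd
import pytest

import antkit as ak


@pytest.fixture(scope="session")
def toy_medians():
    """Six condition medians with known hand-computed scores."""
    return {
        "ncc": 600.0,
        "nci": 700.0,
        "ccc": 560.0,
        "cci": 680.0,
        "scc": 520.0,
        "sci": 630.0,
    }


@pytest.fixture(scope="session")
def toy_summary(toy_medians):
    """A tidy one-subject condition summary built from the toy medians."""
    rows = [
        {
            "subject": "s1",
            "condition": code,
            "n_trials": 27,
            "n_correct": 25,
            "accuracy": 25 / 27,
            "median_rt_ms": rt,
        }
        for code, rt in toy_medians.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject simulated cohort under the default generative model."""
    return ak.simulate_dataset(ak.SimConfig(n_subjects=6, seed=11))


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    return ak.preprocess(small_cohort)
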