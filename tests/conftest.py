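import numpy as np
import pytest

import btlqsar as bq

#: Conditions for the end-to-end recovery study: 120 compounds, 5 informative
#: descriptors in a pool of 40, activity noise 0.2 pKi units.
STUDY_SPEC = bq.SyntheticSpec(
    n_compounds=120, n_descriptors=40, n_informative=5, noise_sd=0.2, seed=7
)


@pytest.fixture(scope="session")
def study_dataset() -> bq.SyntheticDataset:
    return bq.generate_btl_like_dataset(STUDY_SPEC)


@pytest.fixture(scope="session")
def trained_battery(study_dataset):
    """Full battery trained once per session on the study dataset."""
    battery, report = bq.run_modeling_pipeline(
        study_dataset.descriptors, study_dataset.activities, seed=7
    )
    return battery, report


@pytest.fixture()
def tiny_dataset() -> bq.SyntheticDataset:
    """Small, fast dataset for unit-level checks."""
    return bq.generate_btl_like_dataset(
        bq.SyntheticSpec(n_compounds=40, n_descriptors=12, n_informative=3, seed=11)
    )
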