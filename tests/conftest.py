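"""Shared fixtures: cohorts and fitted models reused across test modules."""

import numpy as np
import pytest

from odtgc.model import ModelConfig
from odtgc.pipeline import fit_cohort, prepare_cohort
from odtgc.synthcohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=600, seed 7)."""
    return generate_cohort()


@pytest.fixture(scope="session")
def small_prepared():
    """A reduced prepared cohort for model-dependent tests."""
    return prepare_cohort(cohort_config=CohortConfig(n_patients=240, seed=11))


@pytest.fixture(scope="session")
def small_model(small_prepared):
    """A model fitted with a reduced epoch budget on the reduced cohort."""
    cfg = ModelConfig(epochs=12, pretrain_epochs=4, seed=3)
    return fit_cohort(small_prepared, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
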