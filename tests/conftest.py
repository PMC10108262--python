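import numpy as np
import pytest

from tpcgrowth.fit import DEFAULT_PROPORTIONAL_EFFECTS
from tpcgrowth.synthetic import (
    GeneratingModel,
    StudyDesign,
    default_proportional_model,
)


@pytest.fixture
def default_design():
    return StudyDesign()


@pytest.fixture
def small_design():
    """Reduced factorial layout for fast fitting tests."""
    return StudyDesign(
        clones_per_population=5,
        replicates_per_clone_per_temperature=3,
    )


@pytest.fixture
def proportional_model():
    return default_proportional_model()


@pytest.fixture
def noiseless_model():
    return GeneratingModel(
        fixed=DEFAULT_PROPORTIONAL_EFFECTS,
        sd_clone_intercept=0.0,
        sd_clone_slope=0.0,
        sd_residual=0.0,
    )
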