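import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sp_study_small():
    """Small seed-paired saccadic vs smooth cohort run through the pipeline."""
    from pursuitspect.study import simulate_sp_study

    return simulate_sp_study(n_per_group=10, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
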