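import numpy as np
import pandas as pd
import pytest

from plannsurv import GeneratorSpec, SurvivalDataset, generate, make_interval_grid


@pytest.fixture(scope="session")
def grid10():
    return make_interval_grid(10, 10)


@pytest.fixture(scope="session")
def small_cohort():
    """50-subject cohort for brute-force oracle comparisons."""
    return generate(GeneratorSpec(n=50, seed=11))


@pytest.fixture(scope="session")
def medium_cohort():
    """2000-subject proportional-hazards cohort."""
    return generate(GeneratorSpec(n=2000, seed=7))


@pytest.fixture()
def toy_dataset():
    """Hand-sized dataset with mixed censoring, no tied times."""
    return SurvivalDataset(
        time=np.array([0.5, 1.2, 2.0, 2.5, 3.5, 4.0, 5.0, 6.0]),
        event=np.array([1, 0, 1, 0, 1, 1, 0, 1]),
        covariates=pd.DataFrame({"x1": [1.0, 0, 1, 1, 0, 0, 1, 0],
                                 "x2": [0.2, -0.1, 0.5, 1.0, -0.7, 0.3, 0.0, 0.9]}),
    )
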