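import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from glycomeds.glycan import annotate_panel
from glycomeds.preprocess import AbundanceMatrix
from glycomeds.simulate import default_panel
from glycomeds.traits import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def panel68():
    return default_panel(68)


@pytest.fixture(scope="session")
def annotations68(panel68):
    return annotate_panel(panel68)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture()
def raw_matrix(panel68, rng):
    """Small random raw abundance matrix over the 68-analyte panel."""
    n = 40
    values = pd.DataFrame(
        rng.lognormal(0.0, 1.0, (n, len(panel68))),
        index=[f"s{i}" for i in range(n)],
        columns=panel68,
    )
    batch = pd.Series(
        [str(i % 3) for i in range(n)], index=values.index, name="batch"
    )
    return AbundanceMatrix(values=values, batch=batch, stage="raw")
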