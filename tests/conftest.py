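import numpy as np
import pandas as pd
import pytest

from metabvar.io import LayerKind, OmicsLayer, RunConfig
from metabvar.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort bundle shared by integration-style tests."""
    return simulate_cohort(
        n_samples=300, n_metabolites=24, n_snps=60, n_taxa=30,
        n_diet_items=20, n_followup=150, seed=11,
    )


@pytest.fixture(scope="session")
def config():
    return RunConfig(seed=11, thresholds={"permanova_permutations": 99})


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_layer():
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2"],
    )
    return OmicsLayer(LayerKind.METABOLOME, data)
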