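import numpy as np
import pandas as pd
import pytest

import sims
from sims.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return sims.default_registry()


@pytest.fixture(scope="session")
def whitelist():
    return sims.default_whitelist()


@pytest.fixture(scope="session")
def default_cohort(registry, whitelist):
    """Default-condition synthetic cohort (n=200, seed 1) plus its scores."""
    bundle, truth = generate_cohort(
        SimulationConfig(seed=1), registry, whitelist=whitelist
    )
    mirna_map = sims.synthetic_mirna_map(registry)
    result = sims.score_cohort(bundle, registry, mirna_map, whitelist)
    return bundle, truth, result


def random_scores(rng, n_nodes=6, n_patients=20, names=None):
    names = names or [f"N{i}" for i in range(n_nodes)]
    return pd.DataFrame(
        rng.integers(1, 11, size=(len(names), n_patients)),
        index=names,
        columns=[f"P{i:03d}" for i in range(n_patients)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
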