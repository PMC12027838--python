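import numpy as np
import pytest

from dsclpgan.phantom import PhantomSpec, make_dataset
from dsclpgan.training import fit, make_config


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_dataset(default_spec):
    """64 phantoms for cheap unit tests."""
    return make_dataset(default_spec, 64, seed=1)


@pytest.fixture(scope="session")
def smoke_runs(default_spec):
    """Three desk-preset training runs (256 phantoms, batch 16, 5 epochs).

    Shared across the tests that examine trained behaviour; each entry holds
    the seed, the training dataset, the trained state and the epoch history.
    """
    runs = []
    for seed in (0, 1, 2):
        dataset = make_dataset(default_spec, 256, seed=100 + seed)
        state, history = fit(dataset, make_config("desk", seed=seed))
        runs.append({"seed": seed, "dataset": dataset, "state": state,
                     "history": history})
    return runs
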