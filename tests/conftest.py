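import numpy as np
import pytest

import sweetdry as sd


@pytest.fixture(scope="session")
def study():
    return sd.load_study()


@pytest.fixture(scope="session")
def trained(study):
    """Default-configuration fit of the study network (shared: slow)."""
    model = sd.DryingMLP(study)
    return model.fit(sd.TrainConfig(seed=1))


@pytest.fixture(scope="session")
def quick_fit(study):
    """A cheap, reproducible fit for structural (non-accuracy) checks."""
    model = sd.DryingMLP(study)
    cfg = sd.TrainConfig(restarts=3, explore_maxiter=200, polish_top=1,
                         polish_maxiter=400, seed=7)
    return model.fit(cfg)


@pytest.fixture(scope="session")
def planted():
    return sd.plant_mlp_dataset(seed=11)


def toy_results(W1, B1, W2, B2, scaler=None):
    """Construct a results object directly from weight arrays."""
    return sd.MLPResults(None, np.asarray(W1, float), np.asarray(B1, float),
                         np.asarray(W2, float), np.asarray(B2, float), scaler)
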