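import numpy as np
import pytest

from nadquant.dataset import Dataset
from nadquant.pipeline import quantify_dataset
from nadquant.registry import load_registry
from nadquant.simulate import (
    SimConfig,
    simulate_experiment,
    simulate_standard_series,
)


@pytest.fixture(scope="session")
def panel():
    return load_registry()


def build_demo_dataset(seed=1, noise_free=False, crosstalk=True, replicates=1,
                       panel=None, extra=()):
    """Standard series + experimental replicates as one in-memory dataset."""
    config = SimConfig(seed=seed, crosstalk_enabled=crosstalk)
    if panel is not None:
        config = SimConfig(seed=seed, crosstalk_enabled=crosstalk, panel=panel)
    if noise_free:
        config = config.noise_free()
    rng = config.rng()
    injections = simulate_standard_series(config, rng=rng)
    samples, preps = simulate_experiment(config, replicates=replicates, rng=rng)
    injections.extend(samples)
    for maker in extra:
        injections.extend(maker(config, rng))
    return config, Dataset(injections, {p.sample_id: p for p in preps})


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free, crosstalk-free demo dataset with its quantification."""
    config, ds = build_demo_dataset(seed=1, noise_free=True, crosstalk=False)
    result = quantify_dataset(ds, config.panel)
    return config, ds, result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
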