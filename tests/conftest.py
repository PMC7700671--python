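import numpy as np
import pytest

from isspu import SimulatorConfig, generate_scene, load_example_matrices


@pytest.fixture(scope="session")
def example_matrices():
    """The ten bundled 6-class worked-example confusion matrices."""
    return load_example_matrices()


@pytest.fixture(scope="session")
def fast_config():
    """A small gradient-boosting configuration for cheap unit tests."""
    return SimulatorConfig(hyperparameters={"n_estimators": 30,
                                            "max_depth": 3})


@pytest.fixture(scope="session")
def small_scene():
    """A 3-class 64x64 scene shared across tests (read-only)."""
    return generate_scene(n_classes=3, size=(64, 64), spatial_scale=5.0,
                          spectral_separability=4.0, n_bands=3, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
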