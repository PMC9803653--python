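import numpy as np
import pytest

from holospm.config import PipelineConfig
from holospm.optics import OpticalConfig
from holospm.pipeline import run_experiment
from holospm.simulate import simulate_stack


@pytest.fixture(scope="session")
def experiment():
    """One full desk-scale study (simulate, train both branches, correct).

    Shared across the learning/correction tests because training the two
    network branches dominates the suite's runtime.
    """
    return run_experiment(PipelineConfig.test_profile(seed=1))


@pytest.fixture(scope="session")
def small_optics():
    return OpticalConfig(image_shape=(140, 140))


@pytest.fixture(scope="session")
def fine_stacks_small(small_optics):
    """Monodisperse fine stacks at 1 and 8 ug/ml on 140-px frames."""
    return {
        1.0: simulate_stack(1.0, 0.0, 4, small_optics, seed=101),
        8.0: simulate_stack(8.0, 0.0, 4, small_optics, seed=108),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
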