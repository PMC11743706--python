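import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plantarstiff import synthetic
from plantarstiff.model import PlantarStiffnessModel
from plantarstiff.network import NetworkArchitecture, TrainConfig
from plantarstiff.optimizer import OptimizerConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def linear_cohort():
    """Noise-free linear cohort: ground truth exactly recoverable."""
    cfg = synthetic.CohortConfig(noise_sd=0.0, nonlinearity_scale=0.0, seed=7)
    df = synthetic.cohort_to_frame(synthetic.generate_cohort(cfg))
    return cfg, df


@pytest.fixture(scope="session")
def small_fit(linear_cohort):
    """A fast but real end-to-end fit for Model/Results-level tests."""
    _, df = linear_cohort
    opt = OptimizerConfig(pso_iterations=5, ga_generations=10, seed=3)
    train = TrainConfig(max_epochs=500)
    model = PlantarStiffnessModel.from_dataframe(df)
    return model.fit(optimizer_config=opt, train_config=train)


def random_architecture(rng, n_input=None, n_hidden=None, n_output=None):
    return NetworkArchitecture(
        n_input=n_input or int(rng.integers(1, 6)),
        n_hidden=n_hidden or int(rng.integers(1, 7)),
        n_output=n_output or 1,
    )
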