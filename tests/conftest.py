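import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_experiment():
    """A 60-colony synthetic experiment with the default (study) parameters."""
    from antcomp.synthetic import TrueParameters, generate_experiment

    return generate_experiment(60, TrueParameters(), seed=11)


@pytest.fixture(scope="session")
def analysis_table(small_experiment):
    from antcomp.pipeline import prepare_analysis_table

    return prepare_analysis_table(small_experiment.censuses,
                                  small_experiment.densities)
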