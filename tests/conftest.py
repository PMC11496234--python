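import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_generator_config():
    """A reduced cohort (fast) keeping the default mixture structure."""
    from inflamcog.config import GeneratorConfig

    return GeneratorConfig(
        n_by_group={"SZ": 40, "BD": 30, "HC": 60},
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_generator_config):
    from inflamcog.cohort import generate_cohort, inject_missingness, latent_frame

    table, latent = generate_cohort(small_generator_config)
    table = inject_missingness(table, small_generator_config)
    return table, latent_frame(latent)


@pytest.fixture(scope="session")
def preprocessed_small(small_cohort):
    from inflamcog.preprocess import preprocess

    table, latent = small_cohort
    work, audit, fm = preprocess(table)
    return work, audit, fm, latent


def two_blobs(n_per=50, sep=10.0, seed=0, dim=2):
    """Two spherical Gaussian components `sep` pooled-s.d. apart."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per, dim))
    b = rng.standard_normal((n_per, dim))
    b[:, 0] += sep
    return np.vstack([a, b]), np.repeat([1, 2], n_per)
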