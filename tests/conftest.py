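import numpy as np
import pytest

from jamupls.simulate import GeneratorConfig, simulate_formulary


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Small structured formulary used across modules: 3 classes, clean signal."""
    return GeneratorConfig(
        I=150,
        J=24,
        K=10,
        L=3,
        class_proportions=(0.3, 0.3, 0.4),
        n_main_per_class=4,
        p_main=0.8,
        p_support=0.05,
        n_specific_activities_per_class=2,
        n_general_activities=2,
        p_activity_noise=0.02,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_formulary(small_config):
    return simulate_formulary(small_config)


@pytest.fixture(scope="session")
def separable_formulary():
    """Linearly separable: disjoint main plants, deterministic usage, no noise."""
    cfg = GeneratorConfig(
        I=90,
        J=15,
        K=8,
        L=3,
        class_proportions=(1 / 3, 1 / 3, 1 / 3),
        n_main_per_class=4,
        p_main=1.0,
        p_support=0.0,
        n_specific_activities_per_class=2,
        n_general_activities=2,
        p_activity_noise=0.0,
        seed=7,
    )
    return cfg, simulate_formulary(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
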