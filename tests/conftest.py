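import pytest

from summitplex.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The standard study cohort: influence effect 0.8, persistence 0.6,
    400 expeditions, seed 42 (the generator defaults)."""
    return generate_cohort(GeneratorConfig(rng_seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for quick structural tests."""
    cfg = GeneratorConfig(
        n_climbers=40, n_expeditions=60, expedition_size_range=(4, 7), rng_seed=5
    )
    return generate_cohort(cfg), cfg
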