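import pytest
from hypothesis import HealthCheck, settings

import combosearch as cs

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def fig1():
    """Planted two-gene showcase: overlapping marginals, separable jointly."""
    return cs.generate_figure1_pair(seed=5)


@pytest.fixture(scope="session")
def small_split():
    """Compact multi-cohort split with one planted pair, noise, and
    probesets planted to fail each filtration rule."""
    return cs.generate_cohort_split(
        n_noise_probesets=25,
        cohort_sizes={
            "training": 60,
            "filtration_1": 60,
            "filtration_2": 60,
            "validation": 60,
        },
        gray_fraction=0.2,
        seed=11,
        n_fail_low=5,
        n_fail_ratio=5,
        n_fail_nosymbol=3,
    )


@pytest.fixture(scope="session")
def small_model(small_split):
    split, phenos, _ = small_split
    return cs.InformativePairSearch(split, phenotypes=phenos)


@pytest.fixture(scope="session")
def small_results(small_model):
    return small_model.fit()
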