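import pytest
from hypothesis import HealthCheck, settings

import excurves as ex
from excurves.simulate import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vocabulary():
    """Default 895-topic catalog, lexicon, crosswalk."""
    return ex.default_vocabulary()


@pytest.fixture(scope="session")
def small_cohort(vocabulary):
    """8 residents, ~3k encounters — fast closed-loop fixture."""
    catalog, lexicon, crosswalk = vocabulary
    cfg = CohortConfig(
        class_sizes=(2, 2, 2, 2),
        pgy_volume_means=(40.0, 70.0, 110.0, 150.0),
        seed=11,
    )
    return generate_cohort(cfg, catalog, lexicon, crosswalk)


@pytest.fixture(scope="session")
def medium_cohort(vocabulary):
    """32 residents — large enough for distribution-recovery checks."""
    catalog, lexicon, crosswalk = vocabulary
    cfg = CohortConfig(
        class_sizes=(8, 8, 8, 8),
        pgy_volume_means=(60.0, 80.0, 100.0, 120.0),
        seed=0,
    )
    return generate_cohort(cfg, catalog, lexicon, crosswalk)


@pytest.fixture(scope="session")
def default_cohort(vocabulary):
    """The full default cohort (62 residents, ~244k encounters).

    Session-scoped: generated once and shared by the statistical
    structure tests and the end-to-end recovery check.
    """
    catalog, lexicon, crosswalk = vocabulary
    return generate_cohort(CohortConfig(seed=5), catalog, lexicon, crosswalk)
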