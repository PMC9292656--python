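import pytest

from donorflow import (
    BehaviourParams,
    DeferralRates,
    DistributionSpec,
    ProcessTimeCatalog,
    default_catalog,
)
from donorflow.schedule import baseline_day, generate_synthetic_day


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def degenerate_catalog():
    """Point-mass service times at the catalog means (hand-trace oracle)."""
    d = DistributionSpec.degenerate
    return ProcessTimeCatalog(
        {
            "registration_booked": d(1.77),
            "registration_unbooked": d(2.4),
            "consultation": d(18.33),
            "haemoglobin": d(1.67),
            "pre_setup": d(1.6),
            "phlebotomy": d(13.26),
            "post_setup": d(1.5),
            "resting": d(5.0),
            "refreshment": d(14.22),
        }
    )


@pytest.fixture(scope="session")
def no_deferrals():
    return DeferralRates(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def behaviour():
    return BehaviourParams()


@pytest.fixture(scope="session")
def study_day():
    """The reference study day (calibrated to the centre's observed load)."""
    return baseline_day(seed=1)


@pytest.fixture(scope="session")
def full_load_day():
    """A day calibrated to 100% of nominal physician capacity."""
    return generate_synthetic_day(seed=1, load_factor=1.0)
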