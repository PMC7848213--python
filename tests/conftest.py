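import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from agrisk import (  # noqa: E402
    EconomyParams,
    ExperimentConfig,
    TransmissionParams,
    TreatmentSpec,
    Visibility,
    run_experiment,
)
from agrisk.agents import CohortSpec, LotteryBehavior  # noqa: E402


@pytest.fixture(scope="session")
def economy():
    return EconomyParams()


@pytest.fixture(scope="session")
def transmission():
    return TransmissionParams()


@pytest.fixture(scope="session")
def no_transmission():
    return TransmissionParams(p_inf=0.0)


@pytest.fixture(scope="session")
def small_schedule():
    """Four handcrafted treatments covering all visibility kinds."""
    return [
        TreatmentSpec(Visibility.VISIBLE, Visibility.VISIBLE),
        TreatmentSpec(Visibility.HIDDEN, Visibility.HIDDEN),
        TreatmentSpec(
            Visibility.REVEALABLE,
            Visibility.REVEALABLE,
            reveal_price_disease=1000.0,
            reveal_price_biosecurity=2000.0,
        ),
        TreatmentSpec(Visibility.VISIBLE, Visibility.HIDDEN),
    ]


@pytest.fixture(scope="session")
def small_config(small_schedule):
    return ExperimentConfig(
        seed=11,
        schedule=small_schedule,
        cohorts=[
            CohortSpec(
                name="alpha",
                n_participants=4,
                reveal_propensity_mean=0.5,
                lottery=LotteryBehavior(switch_row_mean=5, switch_row_sd=1, error_rate=0.05),
            ),
            CohortSpec(
                name="beta",
                n_participants=4,
                reveal_propensity_mean=0.2,
                lottery=LotteryBehavior(switch_row_mean=7, switch_row_sd=1, error_rate=0.0),
            ),
        ],
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    """One shared end-to-end run on a tiny experiment."""
    return run_experiment(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
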