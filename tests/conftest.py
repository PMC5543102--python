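import numpy as np
import pytest

from mepmix import MixtureModel
from mepmix.cohort import GeneratorConfig

#: Published mixture of overall MEP changes: responder, non-responder and
#: paradox-responder modes on the percent-of-baseline scale.
TRIMODAL_MEANS = (69.7, 115.1, 158.4)
TRIMODAL_SDS = (4.2, 13.0, 26.4)
TRIMODAL_WEIGHTS = (0.19, 0.55, 0.26)

#: Generator seed of the bundled example cohort: a 31-subject draw whose
#: GMM and ABC responder sets coincide exactly (six subjects), the
#: configuration the two-route cross-check is designed around.
FIXTURE_COHORT_SEED = 13


@pytest.fixture(scope="session")
def trimodal_model() -> MixtureModel:
    return MixtureModel.from_arrays(TRIMODAL_MEANS, TRIMODAL_SDS, TRIMODAL_WEIGHTS)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def fixture_cohort():
    """The bundled 31-subject example cohort (trials, truth)."""
    from mepmix.cohort import generate_cohort

    return generate_cohort(GeneratorConfig(seed=FIXTURE_COHORT_SEED))


def mixture_mean(means=TRIMODAL_MEANS, weights=TRIMODAL_WEIGHTS) -> float:
    return float(np.dot(weights, means))


def mixture_var(means=TRIMODAL_MEANS, sds=TRIMODAL_SDS, weights=TRIMODAL_WEIGHTS) -> float:
    m = mixture_mean(means, weights)
    means = np.asarray(means)
    return float(np.dot(weights, np.asarray(sds) ** 2 + (means - m) ** 2))
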