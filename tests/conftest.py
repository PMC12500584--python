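import numpy as np
import pytest

from acasim.param_space import (
    DeclineParams,
    InstrumentSpec,
    LearningParams,
    RankParams,
)


def constant_instrument(
    mu: float = 50.0,
    sigma: float = 10.0,
    rho: float = 0.8,
    n_ranks: int = 5,
    ceiling: float | None = None,
) -> InstrumentSpec:
    """An instrument with identical parameters at every rank, for tests
    that need full control over the score process."""
    rp = RankParams(
        mu_first=mu, sigma_first=sigma, mu_second=mu, sigma_second=sigma, rho=rho
    )
    return InstrumentSpec(
        name="constant", rank_params=(rp,) * n_ranks, score_ceiling=ceiling
    )


@pytest.fixture
def flat_instrument() -> InstrumentSpec:
    return constant_instrument()


@pytest.fixture
def no_learning() -> LearningParams:
    return LearningParams(maximum=1.0, rate=0.2)


@pytest.fixture
def no_decline() -> DeclineParams:
    return DeclineParams(rate_per_run=0.0, stable_runs=14)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
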