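import math

import numpy as np
import pytest

from mrdsim import (
    CovariateSpec,
    HazardSpec,
    ScheduleSpec,
    SimulationConfig,
    SubgroupSpec,
    TrajectoryParams,
)


@pytest.fixture
def decay_params() -> TrajectoryParams:
    """Responder who never relapses: 1.0 -> 0.01 over te=10."""
    return TrajectoryParams(
        beta0=1.0, beta1=0.01, beta2=0.0, te=10.0, tr=math.inf, sigma=0.05
    )


@pytest.fixture
def relapse_params() -> TrajectoryParams:
    """Relapser: decay to 0.01 by te=10, regrowth at rate 0.3 from tr=20."""
    return TrajectoryParams(
        beta0=1.0, beta1=0.01, beta2=0.3, te=10.0, tr=20.0, sigma=0.05
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_params(rng: np.random.Generator) -> TrajectoryParams:
    """Random but valid trajectory parameters spanning typical MRD scales."""
    beta0 = math.exp(rng.uniform(-4, 1))
    beta1 = beta0 * math.exp(rng.uniform(-6, -0.5))
    te = rng.uniform(2, 15)
    if rng.uniform() < 0.5:
        tr = te + rng.uniform(0.1, 30)
    else:
        tr = math.inf
    return TrajectoryParams(
        beta0=beta0,
        beta1=beta1,
        beta2=rng.uniform(0, 0.5),
        te=te,
        tr=tr,
        sigma=rng.uniform(0, 0.1),
    )


def small_config(
    n: int = 10,
    alpha1: float = 0.0,
    link_scale: str = "raw",
    rate: float = 0.02,
    t_max: float = 48.0,
    relapse_prob: float = 0.5,
    sigma: float = 0.02,
    miss_prob: float = 0.0,
    lod: float | None = 1e-4,
    covariates: tuple = (),
    gamma: tuple = (),
    **hazard_kw,
) -> SimulationConfig:
    return SimulationConfig(
        subgroups=(
            SubgroupSpec(
                name="CR",
                n=n,
                beta0_meanlog=-2.0,
                beta0_sdlog=0.5,
                beta1_meanlog=-7.0,
                beta1_sdlog=0.7,
                te=6.0,
                relapse_prob=relapse_prob,
                relapse_mean=20.0,
                relapse_sd=5.0,
                beta2=0.25,
                sigma=sigma,
            ),
        ),
        hazard=HazardSpec(
            baseline_params={"rate": rate},
            alpha1=alpha1,
            link_scale=link_scale,
            t_max=t_max,
            gamma=gamma,
            **hazard_kw,
        ),
        schedule=ScheduleSpec(
            mode="regular", interval=3.0, horizon=t_max, miss_prob=miss_prob
        ),
        covariates=covariates,
        lod=lod,
    )
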