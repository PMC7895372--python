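import numpy as np
import pytest

from avbind import (
    FitResult,
    LikelihoodParams,
    ObserverParams,
    PriorParams,
    ResponseMap,
    default_group_params,
    enumerate_design,
)


@pytest.fixture(scope="session")
def design():
    return enumerate_design()


@pytest.fixture(scope="session")
def group_params():
    return default_group_params()


def make_observer(
    variant="ReducedJP",
    sigma2_A=(0.005, 0.02, 0.08),
    sigma2_V=(0.003, 0.02, 0.10),
    prior_sync=0.0,
    prior_async=0.05,
    means=(0.10, 0.90, 0.10, 0.80),
    bounds=(1 / 3, 2 / 3),
):
    """Hand-assemble an ObserverParams for tests."""
    kind = {"MLE": "mle", "ReducedJP": "joint_prior", "FullJP": "joint_prior",
            "ReducedBCI": "bci", "FullBCI": "bci"}[variant]
    lik = LikelihoodParams(
        mu_A_B=means[0], mu_A_G=means[1], mu_V_B=means[2], mu_V_G=means[3],
        sigma2_A=dict(zip(("high", "mid", "low"), sigma2_A)),
        sigma2_V=dict(zip(("high", "mid", "low"), sigma2_V)),
    )
    if kind == "mle":
        prior = PriorParams.mle()
    else:
        prior = PriorParams(kind=kind, value_sync=prior_sync, value_async=prior_async)
    return ObserverParams(
        likelihood=lik, prior=prior, response_map=ResponseMap(b1=bounds[0], b2=bounds[1]),
        variant=variant,
    )


def make_fit_result(params) -> FitResult:
    """Wrap hand-built parameters as a FitResult for evaluation-layer tests."""
    return FitResult(
        params=params, penalized_nll=0.0, nll=0.0, restart_trace=(0.0,), converged=True,
        z_opt=np.zeros(1),
    )
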