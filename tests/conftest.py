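import numpy as np
import pytest

from memrec import ChannelSpec, PriorSpec, solve_nu_for_delta

ALL_PRIORS = [
    PriorSpec("binary"),
    PriorSpec("sparse", 0.3),
    PriorSpec("low_coding", 0.3),
]


@pytest.fixture(params=ALL_PRIORS, ids=lambda p: p.family)
def prior(request) -> PriorSpec:
    return request.param


def channel_for_delta(delta: float, tau: float = 0.0) -> ChannelSpec:
    """Channel realising a requested effective noise (largest-nu root)."""
    return ChannelSpec(tau, solve_nu_for_delta(delta, tau)[-1])


def brute_posterior_mean_cov(prior: PriorSpec, A, b):
    """Literal brute-force tilted mean/covariance, plain Python loops."""
    import itertools
    import math

    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    P = len(b)
    support = list(prior.support)
    probs = list(prior.probabilities)
    weights, configs = [], []
    for idx in itertools.product(range(len(support)), repeat=P):
        x = [support[i] for i in idx]
        logw = sum(math.log(probs[i]) for i in idx)
        logw += sum(b[j] * x[j] for j in range(P))
        logw -= 0.5 * sum(
            x[j] * A[j, k] * x[k] for j in range(P) for k in range(P)
        )
        weights.append(math.exp(logw))
        configs.append(x)
    Z = sum(weights)
    mean = np.zeros(P)
    exx = np.zeros((P, P))
    for w, x in zip(weights, configs):
        x = np.asarray(x)
        mean += w / Z * x
        exx += w / Z * np.outer(x, x)
    return mean, exx - np.outer(mean, mean)
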