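import numpy as np
import pytest

from nrkuramoto import ModelParams, sample_initial_condition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def metastable_params():
    """Dense parameters of the metastable regime (eps1 >> eps2 > 0)."""
    return ModelParams(N=10, eps1=0.01, eps2=0.0001)


@pytest.fixture
def random_state_factory(rng):
    """Random (theta, k) states with |k| <= 1 and zero diagonal."""

    def make(n):
        ic = sample_initial_condition(n, seed=rng)
        return ic.as_state()

    return make


def naive_rhs_phases(state, params):
    """Double-loop reference evaluation of the phase velocities."""
    n = params.N
    omega = params.omega_vector
    out = np.zeros(n)
    if params.variant == "sparse":
        adj = params.adjacency
        for i in range(n):
            acc = 0.0
            deg = 0.0
            for j in range(n):
                acc += adj[i, j] * state.k[i, j] * np.sin(state.theta[j] - state.theta[i])
                deg += adj[i, j]
            out[i] = omega[i] + acc / deg
        return out
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if params.variant == "freq_adaptive":
                if i != j:
                    acc += state.k[i, j] * (
                        params.gamma0
                        - np.sin(state.theta[i] - state.theta[j] + params.alpha)
                    )
            else:
                acc += state.k[i, j] * np.sin(state.theta[j] - state.theta[i])
        out[i] = omega[i] + acc / n
    return out


def naive_rhs_couplings(state, params):
    """Double-loop reference evaluation of the coupling velocities."""
    n = params.N
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if i < j:
                eps, beta = params.eps1, params.beta1
            else:
                eps, beta = params.eps2, params.beta2
            val = -eps * (
                state.k[i, j] + np.sin(state.theta[i] - state.theta[j] + beta)
            )
            if params.variant == "sparse":
                val *= params.adjacency[i, j]
            out[i, j] = val
    return out
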