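"""Model core: right-hand sides, equilibrium construction, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrkuramoto import (
    ClusterPartition,
    DegenerateInputError,
    DimensionError,
    ModelParams,
    SystemState,
    UnsupportedConfigurationError,
    ValidationError,
    effective_frequencies,
    equilibrium_two_cluster,
    rhs_couplings,
    rhs_phases,
)
from conftest import naive_rhs_couplings, naive_rhs_phases


class TestRhsPhases:
    def test_identical_phases_are_stationary(self):
        state = SystemState(theta=np.zeros(2), k=np.array([[0.0, 0.7], [-0.3, 0.0]]))
        np.testing.assert_array_equal(
            rhs_phases(state, ModelParams(N=2)), np.zeros(2)
        )

    def test_quarter_turn_two_oscillators(self):
        # (1/2) * sin(+-pi/2) by hand
        state = SystemState(
            theta=np.array([0.0, np.pi / 2]), k=np.array([[0.0, 1.0], [1.0, 0.0]])
        )
        np.testing.assert_allclose(
            rhs_phases(state, ModelParams(N=2)), [0.5, -0.5], atol=1e-15
        )

    def test_freq_adaptive_reduces_to_dense(self, random_state_factory):
        state = random_state_factory(8)
        dense = ModelParams(N=8)
        fa = ModelParams(N=8, gamma0=0.0, alpha=0.0, variant="freq_adaptive")
        np.testing.assert_allclose(
            rhs_phases(state, fa), rhs_phases(state, dense), atol=1e-14
        )

    def test_sparse_complete_graph_matches_dense_up_to_prefactor(
        self, random_state_factory
    ):
        # complete graph: degree N-1 instead of N in the normalisation
        n = 6
        state = random_state_factory(n)
        adj = np.ones((n, n)) - np.eye(n)
        sparse = ModelParams(N=n, adjacency=adj, variant="sparse")
        dense = ModelParams(N=n)
        np.testing.assert_allclose(
            rhs_phases(state, sparse) * (n - 1),
            rhs_phases(state, dense) * n,
            atol=1e-13,
        )

    def test_dimension_mismatch_rejected(self, random_state_factory):
        with pytest.raises(DimensionError):
            rhs_phases(random_state_factory(4), ModelParams(N=5))

    def test_isolated_node_rejected(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        with pytest.raises((DegenerateInputError, ValidationError)):
            ModelParams(N=3, adjacency=adj, variant="sparse")


class TestRhsCouplings:
    def test_in_cluster_upper_coupling_relaxes_toward_plus_one(self):
        # theta_i = theta_j, beta1 = -pi/2: dk = -eps1 (k - 1)
        k = np.array([[0.0, 0.2], [0.0, 0.0]])
        state = SystemState(theta=np.zeros(2), k=k)
        params = ModelParams(N=2, eps1=0.05)
        dk = rhs_couplings(state, params)
        assert dk[0, 1] == pytest.approx(-0.05 * (0.2 - 1.0))

    def test_anti_phase_lower_coupling_relaxes_toward_plus_one(self):
        # theta_i - theta_j = pi, beta2 = +pi/2: dk = -eps2 (k - 1)
        k = np.array([[0.0, 0.0], [-0.4, 0.0]])
        state = SystemState(theta=np.array([0.0, np.pi]), k=k)
        params = ModelParams(N=2, eps2=0.01)
        dk = rhs_couplings(state, params)
        assert dk[1, 0] == pytest.approx(-0.01 * (-0.4 - 1.0), abs=1e-15)

    def test_diagonal_is_frozen(self, random_state_factory):
        dk = rhs_couplings(random_state_factory(7), ModelParams(N=7))
        np.testing.assert_array_equal(np.diag(dk), np.zeros(7))

    def test_relaxation_targets_bounded(self, random_state_factory):
        # fixed point of each coupling ODE is -sin(...) in [-1, 1]
        for _ in range(5):
            state = random_state_factory(9)
            params = ModelParams(N=9, eps1=1.0, eps2=1.0)
            dk = rhs_couplings(state, params)
            target = state.k + dk  # eps = 1: target = k + dk/eps
            off = ~np.eye(9, dtype=bool)
            assert np.all(np.abs(target[off]) <= 1.0 + 1e-12)


@pytest.mark.parametrize("n", [2, 3, 5, 8, 13, 20])
@pytest.mark.parametrize("variant", ["dense", "sparse", "freq_adaptive"])
def test_vectorized_rhs_matches_double_loop_oracle(
    n, variant, random_state_factory, rng
):
    kwargs = {}
    if variant == "sparse":
        adj = np.ones((n, n)) - np.eye(n)
        kwargs["adjacency"] = adj
    params = ModelParams(
        N=n,
        eps1=0.01,
        eps2=0.0001,
        omega=rng.normal(0, 1, n),
        gamma0=0.3 if variant == "freq_adaptive" else 0.0,
        alpha=0.1 if variant == "freq_adaptive" else 0.0,
        variant=variant,
        **kwargs,
    )
    for _ in range(4):
        state = random_state_factory(n)
        np.testing.assert_allclose(
            rhs_phases(state, params), naive_rhs_phases(state, params), atol=1e-12
        )
        np.testing.assert_allclose(
            rhs_couplings(state, params),
            naive_rhs_couplings(state, params),
            atol=1e-12,
        )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    shift=st.floats(-10, 10, allow_nan=False),
    n=st.integers(2, 12),
    seed=st.integers(0, 2**20),
)
def test_global_phase_shift_symmetry(shift, n, seed):
    """Adding a constant to every phase leaves both right-hand sides unchanged."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    k = rng.uniform(-1, 1, (n, n))
    np.fill_diagonal(k, 0.0)
    params = ModelParams(N=n)
    a = SystemState(theta=theta, k=k.copy())
    b = SystemState(theta=theta + shift, k=k.copy())
    np.testing.assert_allclose(
        rhs_phases(a, params), rhs_phases(b, params), atol=1e-12
    )
    np.testing.assert_allclose(
        rhs_couplings(a, params), rhs_couplings(b, params), atol=1e-12
    )


class TestEffectiveFrequencies:
    def test_zero_gain_returns_omega(self, random_state_factory):
        params = ModelParams(N=5, omega=2.0, variant="freq_adaptive")
        state = random_state_factory(5)
        np.testing.assert_array_equal(
            effective_frequencies(state, params), np.full(5, 2.0)
        )

    def test_uniform_couplings(self):
        n = 10
        k = np.ones((n, n)) - np.eye(n)
        state = SystemState(theta=np.zeros(n), k=k)
        params = ModelParams(N=n, gamma0=0.1, variant="freq_adaptive")
        np.testing.assert_allclose(
            effective_frequencies(state, params), np.full(n, 0.09)
        )

    def test_balanced_rows_cancel(self):
        n = 4
        k = np.zeros((n, n))
        k[0, 1], k[0, 2] = 1.0, -1.0
        state = SystemState(theta=np.zeros(n), k=k)
        params = ModelParams(N=n, gamma0=0.5, variant="freq_adaptive")
        assert effective_frequencies(state, params)[0] == 0.0


class TestEquilibrium:
    def test_explicit_couplings_for_2_2_split(self):
        part = ClusterPartition(labels=[0, 0, 1, 1])
        state = equilibrium_two_cluster(part, ModelParams(N=4))
        assert state.k[0, 1] == 1.0  # same cluster, upper
        assert state.k[0, 2] == -1.0  # opposite, upper
        assert state.k[1, 0] == -1.0  # same cluster, lower
        assert state.k[2, 0] == 1.0  # opposite, lower

    @pytest.mark.parametrize("labels", [[0, 1], [0, 0, 1], [0, 1, 0, 1, 1, 0, 1]])
    def test_equilibrium_zeroes_both_rhs(self, labels):
        params = ModelParams(N=len(labels))
        state = equilibrium_two_cluster(ClusterPartition(labels=labels), params)
        assert np.max(np.abs(rhs_phases(state, params))) < 1e-14
        assert np.max(np.abs(rhs_couplings(state, params))) < 1e-14

    def test_non_orthogonal_shifts_rejected(self):
        part = ClusterPartition(labels=[0, 1])
        with pytest.raises(UnsupportedConfigurationError):
            equilibrium_two_cluster(part, ModelParams(N=2, beta1=0.3))


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=1),
            dict(N=3, eps1=-0.1),
            dict(N=3, sigma=-1.0),
            dict(N=3, gamma0=1.5),
            dict(N=3, variant="bogus"),
        ],
    )
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ModelParams(**kwargs)

    def test_nonzero_diagonal_coupling_rejected(self):
        with pytest.raises(ValidationError):
            SystemState(theta=np.zeros(2), k=np.eye(2))

    def test_asymmetric_adjacency_rejected(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 1.0
        with pytest.raises(ValidationError):
            ModelParams(N=3, adjacency=adj)
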