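"""Core model definitions: parameters, state, and deterministic right-hand sides.

The system is a population of ``N`` phase oscillators with directed, adaptive
couplings.  In the dense (all-to-all) variant the phases obey

.. math::

    \\dot\\theta_i = \\omega_i + \\frac{1}{N}\\sum_j k_{ij}\\,
                     \\sin(\\theta_j - \\theta_i) + \\xi_i(t),

while every off-diagonal coupling relaxes toward a phase-dependent target,

.. math::

    \\dot k_{ij} = -\\varepsilon_1\\,[k_{ij} + \\sin(\\theta_i-\\theta_j+\\beta_1)]
    \\quad (i<j), \\qquad
    \\dot k_{ij} = -\\varepsilon_2\\,[k_{ij} + \\sin(\\theta_i-\\theta_j+\\beta_2)]
    \\quad (i>j),

with :math:`k_{ii}=0` frozen.  The defaults :math:`\\beta_1=-\\pi/2`
(Hebbian: in-phase pairs strengthen toward +1) and :math:`\\beta_2=+\\pi/2`
(anti-Hebbian) together with a large time-scale separation
:math:`\\varepsilon_1 \\gg \\varepsilon_2` make the coupling dynamics
non-reciprocal: :math:`k_{ij}` and :math:`k_{ji}` follow different rules.
This combination produces metastable anti-phase clusters punctuated by
switching events.

Two further variants are provided: ``sparse`` restricts both equations to the
links of an undirected adjacency matrix (phase sums normalised by node
degree), and ``freq_adaptive`` adds a coupling-dependent frequency term,
:math:`\\dot\\theta_i = \\omega_i + \\frac{1}{N}\\sum_j k_{ij}
[\\Gamma_0 - \\sin(\\theta_i-\\theta_j+\\alpha)]`.

Noise is handled by the integrator; all functions here are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateInputError,
    DimensionError,
    UnsupportedConfigurationError,
    ValidationError,
)

__all__ = [
    "ModelParams",
    "SystemState",
    "ClusterPartition",
    "VARIANTS",
    "rhs_phases",
    "rhs_couplings",
    "effective_frequencies",
    "equilibrium_two_cluster",
]

TWO_PI = 2.0 * np.pi
VARIANTS = ("dense", "sparse", "freq_adaptive")


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValidationError("adjacency must be a square matrix")
    if not np.array_equal(adj, adj.T):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValidationError("adjacency must have a zero diagonal")
    if not np.isin(adj, (0.0, 1.0)).all():
        raise ValidationError("adjacency entries must be 0 or 1")
    if not _is_connected(adj):
        raise ValidationError("adjacency must describe a connected graph")
    return adj


def _is_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


@dataclass
class ModelParams:
    """All model constants.

    Parameters
    ----------
    N
        Number of oscillators (>= 2).
    eps1, eps2
        Adaptation rates (1/time, >= 0) for the upper (i<j, Hebbian) and
        lower (i>j, anti-Hebbian) coupling triangles.  The metastable regime
        of interest has ``eps1 >> eps2 > 0``.
    beta1, beta2
        Plasticity phase shifts in radians; defaults -pi/2 (Hebbian) and
        +pi/2 (anti-Hebbian).
    sigma
        Intensity of additive Gaussian white phase noise (>= 0).
    omega
        Natural frequencies: scalar (broadcast) or length-N vector.
    gamma0
        Frequency-adaptation gain in [0, 1]; only used by ``freq_adaptive``.
    alpha
        Phase lag of the ``freq_adaptive`` interaction term (radians).
    adjacency
        Optional symmetric 0/1 connected matrix; required by ``sparse``.
    variant
        One of ``dense``, ``sparse``, ``freq_adaptive``.
    """

    N: int
    eps1: float = 0.01
    eps2: float = 0.0001
    beta1: float = -np.pi / 2
    beta2: float = +np.pi / 2
    sigma: float = 0.0
    omega: float | np.ndarray = 0.0
    gamma0: float = 0.0
    alpha: float = 0.0
    adjacency: np.ndarray | None = None
    variant: str = "dense"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValidationError("N must be at least 2")
        if self.eps1 < 0 or self.eps2 < 0:
            raise ValidationError("adaptation rates eps1, eps2 must be >= 0")
        if self.sigma < 0:
            raise ValidationError("noise intensity sigma must be >= 0")
        if not 0.0 <= self.gamma0 <= 1.0:
            raise ValidationError("gamma0 must lie in [0, 1]")
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}")
        if self.adjacency is not None:
            self.adjacency = _check_adjacency(self.adjacency)
            if self.adjacency.shape[0] != self.N:
                raise DimensionError("adjacency size does not match N")
        if self.variant == "sparse":
            if self.adjacency is None:
                raise ValidationError("sparse variant requires an adjacency matrix")
            if np.any(self.adjacency.sum(axis=1) < 1):
                raise DegenerateInputError("sparse variant forbids isolated nodes")

    @property
    def omega_vector(self) -> np.ndarray:
        """Natural frequencies broadcast to a length-N array."""
        return np.broadcast_to(np.asarray(self.omega, dtype=float), (self.N,)).copy()

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SystemState:
    """Instantaneous phases, coupling matrix and time.

    Phases are stored wrapped to ``[0, 2*pi)``; the diagonal of ``k`` is
    identically zero (no self-coupling).
    """

    theta: np.ndarray
    k: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        n = self.theta.shape[0]
        if self.theta.ndim != 1 or self.k.shape != (n, n):
            raise DimensionError("theta must be length N and k must be N x N")
        if np.any(np.diag(self.k) != 0.0):
            raise ValidationError("the diagonal of k must be exactly zero")

    @property
    def N(self) -> int:
        return self.theta.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(self.theta.copy(), self.k.copy(), self.t)


@dataclass
class ClusterPartition:
    """A two-way partition of the oscillators.

    ``labels[i]`` is 0 or 1; ``sizes`` = (NA, NB) with NA the size of
    cluster 0; ``reference_phase`` is the mean phase of cluster 0.
    """

    labels: np.ndarray
    reference_phase: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("partition labels must be 0 or 1")

    @property
    def N(self) -> int:
        return self.labels.shape[0]

    @property
    def sizes(self) -> tuple[int, int]:
        nb = int(self.labels.sum())
        return (self.N - nb, nb)

    def __eq__(self, other: object) -> bool:  # label-swap insensitive equality
        if not isinstance(other, ClusterPartition):
            return NotImplemented
        if self.N != other.N:
            return False
        return np.array_equal(self.labels, other.labels) or np.array_equal(
            self.labels, 1 - other.labels
        )


def _check_state(state: SystemState, params: ModelParams) -> None:
    if state.N != params.N:
        raise DimensionError(
            f"state has N={state.N} but params expect N={params.N}"
        )


def rhs_phases(state: SystemState, params: ModelParams) -> np.ndarray:
    """Deterministic phase velocities ``d(theta)/dt`` for the active variant.

    Noise is *not* included; the integrator adds the stochastic increment.
    """
    _check_state(state, params)
    theta, k = state.theta, state.k
    omega = params.omega_vector
    if params.variant == "dense":
        diff = theta[None, :] - theta[:, None]  # diff[i, j] = theta_j - theta_i
        return omega + (k * np.sin(diff)).sum(axis=1) / params.N
    if params.variant == "sparse":
        adj = params.adjacency
        deg = adj.sum(axis=1)
        if np.any(deg < 1):
            raise DegenerateInputError("sparse variant forbids isolated nodes")
        diff = theta[None, :] - theta[:, None]
        return omega + (adj * k * np.sin(diff)).sum(axis=1) / deg
    # freq_adaptive
    diff_ij = theta[:, None] - theta[None, :]  # theta_i - theta_j
    inter = k * (params.gamma0 - np.sin(diff_ij + params.alpha))
    np.fill_diagonal(inter, 0.0)  # k_ii = 0 keeps this a no-op; be explicit
    return omega + inter.sum(axis=1) / params.N


def rhs_couplings(state: SystemState, params: ModelParams) -> np.ndarray:
    """Coupling velocities ``dk/dt``: relaxation toward -sin(theta_i - theta_j + beta).

    Upper-triangle entries (i<j) use rate ``eps1`` and shift ``beta1``; lower
    entries use ``eps2`` and ``beta2``; the diagonal is frozen at zero.  In
    the sparse variant non-links are frozen as well.
    """
    _check_state(state, params)
    theta, k = state.theta, state.k
    n = params.N
    diff = theta[:, None] - theta[None, :]  # theta_i - theta_j
    dk = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    il = np.tril_indices(n, -1)
    dk[iu] = -params.eps1 * (k[iu] + np.sin(diff[iu] + params.beta1))
    dk[il] = -params.eps2 * (k[il] + np.sin(diff[il] + params.beta2))
    if params.variant == "sparse":
        dk *= params.adjacency
    return dk


def effective_frequencies(state: SystemState, params: ModelParams) -> np.ndarray:
    """Coupling-dependent frequencies of the ``freq_adaptive`` variant.

    ``omega_i + (gamma0 / N) * sum_j k_ij``; reduces to ``omega`` exactly when
    ``gamma0 = 0``.
    """
    _check_state(state, params)
    return params.omega_vector + params.gamma0 * state.k.sum(axis=1) / params.N


def equilibrium_two_cluster(
    partition: ClusterPartition, params: ModelParams
) -> SystemState:
    """Exact two-cluster anti-phase equilibrium of the dense model.

    Cluster 0 sits at ``partition.reference_phase``, cluster 1 at
    ``reference_phase + pi``.  Each coupling takes the unique root of its
    relaxation equation: with the orthogonal shifts ``beta1 = -pi/2``,
    ``beta2 = +pi/2`` this is +1 (upper, same cluster), -1 (upper, opposite),
    -1 (lower, same) and +1 (lower, opposite).  The returned state zeroes
    both right-hand sides to machine precision.
    """
    if params.variant != "dense":
        raise UnsupportedConfigurationError(
            "the two-cluster equilibrium is constructed for the dense variant"
        )
    if not (
        np.isclose(params.beta1, -np.pi / 2) and np.isclose(params.beta2, np.pi / 2)
    ):
        raise UnsupportedConfigurationError(
            "equilibrium construction requires beta1 = -pi/2 and beta2 = +pi/2"
        )
    if partition.N != params.N:
        raise DimensionError("partition size does not match params.N")
    labels = partition.labels
    theta = (partition.reference_phase + np.pi * labels) % TWO_PI
    same = labels[:, None] == labels[None, :]
    k = np.zeros((params.N, params.N))
    iu = np.triu_indices(params.N, 1)
    il = np.tril_indices(params.N, -1)
    k[iu] = np.where(same[iu], 1.0, -1.0)
    k[il] = np.where(same[il], -1.0, 1.0)
    return SystemState(theta=theta, k=k, t=0.0)
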