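"""Random inputs: initial conditions and connected random graphs.

Initial phases are uniform on [0, 2*pi); initial couplings are uniform on
[-1, 1] with a zero diagonal.  A second coupling mode draws all couplings
uniformly from [1 - delta, 1] (near full mutual attraction), which delays
the onset of metastability behind a long fully synchronized transient.

Sparse-topology runs use Erdos-Renyi graphs with edge probability
``mean_degree / (N - 1)``, resampled until connected so the degree
distribution stays clean.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import GraphGenerationError, ValidationError
from .model import TWO_PI, SystemState

__all__ = ["InitialCondition", "sample_initial_condition", "generate_connected_graph"]


@dataclass
class InitialCondition:
    """Sampled initial phases and couplings plus the seed that produced them."""

    theta0: np.ndarray
    k0: np.ndarray
    seed: object = None

    def as_state(self) -> SystemState:
        return SystemState(theta=self.theta0.copy(), k=self.k0.copy(), t=0.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_initial_condition(
    N: int,
    seed=None,
    coupling_mode: str = "uniform",
    delta: float = 0.01,
) -> InitialCondition:
    """Draw theta0 ~ U[0, 2*pi)^N and k0 ~ U[-1, 1]^(N x N) with k_ii = 0.

    ``coupling_mode="near_plus_one"`` instead draws every off-diagonal
    coupling from U[1 - delta, 1].
    """
    if N < 2:
        raise ValidationError("N must be at least 2")
    if coupling_mode not in ("uniform", "near_plus_one"):
        raise ValidationError("coupling_mode must be 'uniform' or 'near_plus_one'")
    rng = _rng(seed)
    theta0 = rng.uniform(0.0, TWO_PI, size=N)
    if coupling_mode == "uniform":
        k0 = rng.uniform(-1.0, 1.0, size=(N, N))
    else:
        k0 = rng.uniform(1.0 - delta, 1.0, size=(N, N))
    np.fill_diagonal(k0, 0.0)
    return InitialCondition(theta0=theta0, k0=k0, seed=seed)


def generate_connected_graph(
    N: int,
    mean_degree: float,
    seed=None,
    max_tries: int = 1000,
) -> np.ndarray:
    """Connected Erdos-Renyi adjacency matrix targeting ``mean_degree``.

    Edge probability is ``mean_degree / (N - 1)``; disconnected samples are
    rejected and redrawn.  Raises :class:`GraphGenerationError` when
    ``max_tries`` rejections are exhausted (very sparse regimes).
    """
    if not 1 <= mean_degree <= N - 1:
        raise ValidationError("mean_degree must lie in [1, N - 1]")
    rng = _rng(seed)
    p = mean_degree / (N - 1)
    for _ in range(max_tries):
        g = nx.fast_gnp_random_graph(N, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            adj = nx.to_numpy_array(g, nodelist=range(N), dtype=float)
            return adj
    raise GraphGenerationError(
        f"no connected graph with mean degree {mean_degree} after {max_tries} "
        "tries; increase mean_degree or max_tries"
    )
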