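"""Linear stability of the two-cluster anti-phase saddle.

Linearising the coupled phase/coupling system around the two-cluster
equilibrium gives a Jacobian in four blocks, ``J_theta_theta`` (N x N),
``J_theta_k`` (N x N^2), ``J_k_theta`` (N^2 x N) and ``J_k_k``
(N^2 x N^2, diagonal).  At the equilibrium every ``sin(theta_j - theta_i)``
vanishes, so the phase-coupling block ``J_theta_k`` is identically zero and
the spectrum splits into that of ``J_k_k`` -- all entries ``-eps1`` or
``-eps2``, hence stable -- and that of the phase block.

The phase block at the equilibrium has a remarkably simple closed form:
``+1/N`` above the diagonal, ``-1/N`` below, with a compensating diagonal
(zero row sums), *independently of the cluster partition*.  Index reversal
``chi`` anti-commutes with it (``chi J chi = -J``), forcing a spectrum of
symmetric pairs: ``+-(1 - 2k/N)`` for ``k = 1..m-1`` plus two zeros when
``N = 2m``, and ``k = 1..m`` plus one zero when ``N = 2m + 1``.  The number
of unstable directions therefore grows linearly with N, which is the
mechanism behind the increasingly frequent cluster switching of larger
systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnsupportedConfigurationError, ValidationError
from .model import ClusterPartition, ModelParams, SystemState, equilibrium_two_cluster

__all__ = [
    "JacobianBlocks",
    "SpectrumReport",
    "jacobian_blocks",
    "phase_block_at_equilibrium",
    "analytic_spectrum",
    "count_unstable_directions",
    "spectrum_report",
]

ZERO_TOL = 1e-9


@dataclass
class JacobianBlocks:
    """Exact Jacobian blocks of the dense model at a given state.

    Coupling coordinates are row-major over (i, j) including the frozen
    diagonal (zero rows/columns), so block shapes are regular.
    """

    J_theta_theta: np.ndarray
    J_theta_k: np.ndarray
    J_k_theta: np.ndarray
    J_k_k: np.ndarray
    evaluated_at: SystemState

    def full(self) -> np.ndarray:
        """Assembled (N + N^2) x (N + N^2) Jacobian."""
        top = np.hstack([self.J_theta_theta, self.J_theta_k])
        bottom = np.hstack([self.J_k_theta, self.J_k_k])
        return np.vstack([top, bottom])


@dataclass
class SpectrumReport:
    """Numerical phase-block spectrum versus the analytic prediction."""

    eigenvalues: np.ndarray
    predicted: np.ndarray
    n_positive: int
    n_negative: int
    n_zero: int
    max_deviation: float


def jacobian_blocks(state: SystemState, params: ModelParams) -> JacobianBlocks:
    """Exact partial derivatives of the dense right-hand sides at ``state``."""
    if params.variant != "dense":
        raise UnsupportedConfigurationError(
            "jacobian_blocks is defined for the dense variant"
        )
    if state.N != params.N:
        raise ValidationError("state does not match params.N")
    n = params.N
    theta, k = state.theta, state.k
    diff = theta[None, :] - theta[:, None]  # theta_j - theta_i
    cosd = np.cos(diff)
    sind = np.sin(diff)

    jtt = k * cosd / n
    np.fill_diagonal(jtt, 0.0)
    np.fill_diagonal(jtt, -jtt.sum(axis=1))

    jtk = np.zeros((n, n * n))
    for i in range(n):
        for j in range(n):
            if i != j:
                jtk[i, i * n + j] = sind[i, j] / n

    jkt = np.zeros((n * n, n))
    jkk = np.zeros((n * n, n * n))
    d_ij = theta[:, None] - theta[None, :]  # theta_i - theta_j
    for i in range(n):
        for j in range(n):
            m = i * n + j
            if i == j:
                continue
            if i < j:
                eps, beta = params.eps1, params.beta1
            else:
                eps, beta = params.eps2, params.beta2
            c = np.cos(d_ij[i, j] + beta)
            jkt[m, i] = -eps * c
            jkt[m, j] = +eps * c
            jkk[m, m] = -eps
    return JacobianBlocks(
        J_theta_theta=jtt,
        J_theta_k=jtk,
        J_k_theta=jkt,
        J_k_k=jkk,
        evaluated_at=state,
    )


def phase_block_at_equilibrium(N: int) -> np.ndarray:
    """Closed-form phase block at the two-cluster equilibrium.

    ``+1/N`` above the diagonal, ``-1/N`` below, diagonal chosen so every
    row sums to zero.  Independent of the cluster partition: at the
    equilibrium ``k_ij * cos(theta_j - theta_i)`` is ``+1`` above and ``-1``
    below the diagonal whether or not i and j share a cluster.
    """
    if N < 2:
        raise ValidationError("N must be at least 2")
    m = (np.triu(np.ones((N, N)), 1) - np.tril(np.ones((N, N)), -1)) / N
    np.fill_diagonal(m, -m.sum(axis=1))
    return m


def analytic_spectrum(N: int) -> np.ndarray:
    """Predicted phase-block eigenvalues, sorted ascending.

    ``{+-(1 - 2k/N)}`` for ``k = 1..m-1`` plus two zeros when ``N = 2m``;
    ``k = 1..m`` plus one zero when ``N = 2m + 1``.
    """
    if N < 2:
        raise ValidationError("N must be at least 2")
    m = N // 2
    if N % 2 == 0:
        pos = [1.0 - 2.0 * kk / N for kk in range(1, m)]
        zeros = [0.0, 0.0]
    else:
        pos = [1.0 - 2.0 * kk / N for kk in range(1, m + 1)]
        zeros = [0.0]
    return np.sort(np.array(pos + [-v for v in pos] + zeros))


def count_unstable_directions(N: int) -> int:
    """Number of strictly positive phase-block eigenvalues: m-1 (even N=2m), m (odd)."""
    if N < 2:
        raise ValidationError("N must be at least 2")
    return N // 2 - 1 if N % 2 == 0 else N // 2


def _charpoly_int(a: list[list[int]]) -> list[int]:
    """Characteristic polynomial of an integer matrix, exactly.

    Faddeev-LeVerrier over Python integers: returns coefficients
    ``[1, c1, ..., cN]`` of ``lambda^N + c1 lambda^(N-1) + ... + cN``.
    """
    n = len(a)
    m = [[1 if i == j else 0 for j in range(n)] for i in range(n)]  # identity
    coeffs = [1]
    for k in range(1, n + 1):
        # M_k = A @ (M_{k-1} + c_{k-1} I) done incrementally: here m holds
        # M_{k-1} + c_{k-1} I already; multiply by A
        am = [
            [sum(a[i][l] * m[l][j] for l in range(n)) for j in range(n)]
            for i in range(n)
        ]
        tr = sum(am[i][i] for i in range(n))
        if tr % k != 0:  # pragma: no cover - FL guarantees divisibility
            raise ValidationError("characteristic polynomial recurrence failed")
        ck = -tr // k
        coeffs.append(ck)
        m = [
            [am[i][j] + (ck if i == j else 0) for j in range(n)] for i in range(n)
        ]
    return coeffs


def _integer_eigenvalues(a: list[list[int]]) -> list[int]:
    """All eigenvalues of an integer matrix known to have an integer spectrum.

    Computes the exact characteristic polynomial, strips zero roots, then
    deflates integer roots within the Gershgorin bound by exact synthetic
    division.  Raises if any root is not an integer.
    """
    n = len(a)
    coeffs = _charpoly_int(a)
    roots: list[int] = []
    while len(coeffs) > 1 and coeffs[-1] == 0:
        roots.append(0)
        coeffs = coeffs[:-1]
    bound = max(sum(abs(v) for v in row) for row in a) if n else 0
    candidates = [0] + [s * v for v in range(1, bound + 1) for s in (1, -1)]
    for cand in candidates:
        while len(coeffs) > 1:
            # synthetic division by (lambda - cand)
            quotient = [coeffs[0]]
            for c in coeffs[1:]:
                quotient.append(c + cand * quotient[-1])
            if quotient[-1] != 0:
                break
            roots.append(cand)
            coeffs = quotient[:-1]
    if len(coeffs) > 1:
        raise ValidationError("spectrum contains non-integer eigenvalues")
    return roots


def spectrum_report(
    N: int,
    partition: ClusterPartition | None = None,
    params: ModelParams | None = None,
    tol: float = ZERO_TOL,
    method: str = "exact",
) -> SpectrumReport:
    """Spectrum of the phase block at the two-cluster equilibrium versus the
    analytic formula.

    By default the block is built from the exact Jacobian at the equilibrium
    of an equal (or near-equal) split; any partition of the same N gives the
    same spectrum.

    ``method="exact"`` exploits that ``N * J_theta_theta`` is an integer
    matrix and extracts its eigenvalues through the exact characteristic
    polynomial; this sidesteps the ~sqrt(eps) splitting that a float64
    eigensolver inflicts on the defective double-zero mode of even N.
    ``method="float64"`` uses the plain dense eigensolver (zero modes then
    carry an O(1e-8) error, see the methods note).
    """
    if method not in ("exact", "float64"):
        raise ValidationError("method must be 'exact' or 'float64'")
    if params is None:
        params = ModelParams(N=N)
    if partition is None:
        labels = np.zeros(N, dtype=int)
        labels[N // 2 :] = 1
        partition = ClusterPartition(labels=labels)
    state = equilibrium_two_cluster(partition, params)
    jtt = jacobian_blocks(state, params).J_theta_theta
    if method == "exact":
        scaled = N * jtt
        a_int = np.rint(scaled).astype(np.int64)
        if np.max(np.abs(scaled - a_int)) > 1e-9:
            raise ValidationError(
                "phase block is not the expected rational matrix; "
                "use method='float64' for general states"
            )
        ev = np.sort(
            np.array(_integer_eigenvalues(a_int.tolist()), dtype=float) / N
        )
    else:
        ev_c = np.linalg.eigvals(jtt)
        if np.max(np.abs(ev_c.imag)) > 1e-7:
            raise ValidationError(
                "phase-block spectrum has unexpected imaginary parts"
            )
        ev = np.sort(ev_c.real)
    pred = analytic_spectrum(N)
    return SpectrumReport(
        eigenvalues=ev,
        predicted=pred,
        n_positive=int(np.sum(ev > tol)),
        n_negative=int(np.sum(ev < -tol)),
        n_zero=int(np.sum(np.abs(ev) <= tol)),
        max_deviation=float(np.max(np.abs(ev - pred))),
    )
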