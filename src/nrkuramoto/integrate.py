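"""Time integration of the coupled phase/coupling system.

The scheme is Euler-Maruyama with a fixed step ``dt``: the deterministic
drift is advanced by ``dt * rhs`` and the phases additionally receive a
Gaussian increment ``sigma * sqrt(dt) * N(0, 1)`` per oscillator per step
(couplings are noise-free).  Phases are wrapped to ``[0, 2*pi)`` every step;
an unwrapped copy accumulates the raw increments so that boundary-crossing
detection can measure angular distances without wrap artifacts.

A note on coupling bounds: each coupling update is
``k <- k + dt*eps*(target - k)`` with ``target = -sin(...) in [-1, 1]``, a
convex combination whenever ``eps*dt < 1``; couplings started inside
``[-1, 1]`` therefore remain there for all time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .errors import DimensionError, NumericalError, ValidationError
from .model import TWO_PI, ModelParams, SystemState, rhs_couplings, rhs_phases

__all__ = ["SimConfig", "Trajectory", "em_step", "simulate"]

_VARIANT_CODE = {
    "dense": _kernel.DENSE,
    "sparse": _kernel.SPARSE,
    "freq_adaptive": _kernel.FREQ_ADAPTIVE,
}


@dataclass
class SimConfig:
    """Integration controls.

    ``n_steps`` defaults to the long production value 1.8e6 at ``dt = 0.01``;
    experiments override it.  ``transient_fraction`` is the fraction of the
    run discarded before long-time averages (default 30%).  ``record_stride``
    controls how often full phase/coupling snapshots are stored; the scalar
    series R, R2 and psi2 are always stored at every step.
    ``store_phases`` keeps the full-resolution unwrapped phase series, which
    switching detection and escape forecasting require.
    """

    dt: float = 0.01
    n_steps: int = 1_800_000
    transient_fraction: float = 0.3
    record_stride: int = 1000
    seed: int | None = None
    store_couplings: bool = False
    store_theta_frames: bool = False
    store_phases: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if not 0 <= self.transient_fraction < 1:
            raise ValidationError("transient_fraction must lie in [0, 1)")
        if self.record_stride < 1:
            raise ValidationError("record_stride must be >= 1")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")

    @property
    def transient_steps(self) -> int:
        return int(self.transient_fraction * self.n_steps)


@dataclass
class Trajectory:
    """Recorded time series of a single run.

    ``R``, ``R2`` and ``psi2`` have length ``n_steps + 1`` (every step,
    including the initial state).  ``theta_frames``/``k_frames`` are strided
    snapshots; ``theta_full`` is the optional full-resolution unwrapped phase
    series with shape ``(n_steps + 1, N)``.
    """

    times: np.ndarray
    R: np.ndarray
    R2: np.ndarray
    psi2: np.ndarray
    frame_stride: int
    theta_frames: np.ndarray | None = None
    k_frames: np.ndarray | None = None
    theta_full: np.ndarray | None = None
    seed: int | None = None
    params: ModelParams | None = None
    config: SimConfig | None = None
    final_state: SystemState | None = None

    @property
    def n_steps(self) -> int:
        return self.R.shape[0] - 1

    def mean_order_parameters(
        self, start: int | None = None, stop: int | None = None
    ) -> tuple[float, float]:
        """Long-time averages (<R>, <R2>) over ``[start, stop)`` steps.

        ``start`` defaults to the configured transient cutoff.
        """
        if start is None:
            start = self.config.transient_steps if self.config else 0
        return float(self.R[start:stop].mean()), float(self.R2[start:stop].mean())


def em_step(
    state: SystemState,
    params: ModelParams,
    dt: float,
    noise_draw: np.ndarray | None = None,
) -> SystemState:
    """One Euler-Maruyama step (reference implementation).

    ``noise_draw`` is a length-N vector of standard normals; omit it (or pass
    zeros) for the deterministic map.  The compiled loop in :func:`simulate`
    reproduces this update; this function is the readable single-step form.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    dtheta = rhs_phases(state, params) * dt
    if noise_draw is not None:
        noise_draw = np.asarray(noise_draw, dtype=float)
        if noise_draw.shape != state.theta.shape:
            raise DimensionError("noise_draw must be a length-N vector")
        dtheta = dtheta + params.sigma * np.sqrt(dt) * noise_draw
    theta = (state.theta + dtheta) % TWO_PI
    k = state.k + dt * rhs_couplings(state, params)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(k))):
        raise NumericalError("non-finite state after one step", step=0)
    return SystemState(theta=theta, k=k, t=state.t + dt)


def simulate(
    params: ModelParams, config: SimConfig, initial: SystemState
) -> Trajectory:
    """Integrate ``config.n_steps`` steps from ``initial``; record a Trajectory.

    Deterministic given ``(params, config, initial)``: the only randomness is
    the phase noise, drawn from a generator seeded with ``config.seed``
    (required when ``sigma > 0``).
    """
    if initial.N != params.N:
        raise DimensionError("initial state does not match params.N")
    if params.sigma > 0 and config.seed is None:
        raise ValidationError("a seed is required when sigma > 0")
    n, n_steps = params.N, config.n_steps
    theta = initial.theta.copy() % TWO_PI
    k = initial.k.copy()
    unwrapped = initial.theta.copy()
    r = np.empty(n_steps + 1)
    r2 = np.empty(n_steps + 1)
    psi2 = np.empty(n_steps + 1)
    n_frames = n_steps // config.record_stride + 1
    theta_full = (
        np.empty((n_steps + 1, n)) if config.store_phases else np.empty((0, 0))
    )
    theta_frames = (
        np.empty((n_frames, n)) if config.store_theta_frames else np.empty((0, 0))
    )
    k_frames = (
        np.empty((n_frames, n, n))
        if config.store_couplings
        else np.empty((0, 0, 0))
    )
    adj = (
        params.adjacency
        if params.adjacency is not None
        else np.zeros((0, 0))
    )
    fail = _kernel.integrate(
        theta,
        k,
        unwrapped,
        params.omega_vector,
        np.ascontiguousarray(adj, dtype=float),
        _VARIANT_CODE[params.variant],
        params.eps1,
        params.eps2,
        params.beta1,
        params.beta2,
        params.sigma,
        params.gamma0,
        params.alpha,
        config.dt,
        n_steps,
        int(config.seed) if config.seed is not None else 0,
        r,
        r2,
        psi2,
        theta_full,
        theta_frames,
        k_frames,
        config.record_stride,
    )
    if fail >= 0:
        raise NumericalError(
            f"integration produced non-finite values at step {fail}", step=int(fail)
        )
    return Trajectory(
        times=initial.t + config.dt * np.arange(n_steps + 1),
        R=r,
        R2=r2,
        psi2=psi2,
        frame_stride=config.record_stride,
        theta_frames=theta_frames if config.store_theta_frames else None,
        k_frames=k_frames if config.store_couplings else None,
        theta_full=theta_full if config.store_phases else None,
        seed=config.seed,
        params=params,
        config=config,
        final_state=SystemState(theta=theta, k=k, t=initial.t + config.dt * n_steps),
    )
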