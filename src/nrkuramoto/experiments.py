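"""Parameter studies: phase diagram, noise sweep, connectivity, frequency adaptation.

Every experiment is deterministic given its master seed: realization ``r`` of
pixel/point ``p`` draws its initial condition from the substream
``SeedSequence([seed, p, r])``, so results are independent of execution
order and reproducible piecewise.

All experiments accept explicit scale parameters (grid steps, realization
counts, step counts) so that reduced-scale versions run quickly; the
full-scale defaults follow the production protocol (dense grids, 200
realizations per pixel, long runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .integrate import SimConfig, simulate
from .model import ModelParams
from .observables import (
    R_THRESHOLD,
    assign_clusters,
    classify_state,
    detect_switch_events,
    dwell_intervals,
    merge_dwell_intervals,
)
from .sampling import generate_connected_graph, sample_initial_condition

__all__ = [
    "SweepSpec",
    "PhaseDiagram",
    "BoundaryFit",
    "sweep_epsilon_grid",
    "fit_transition_boundary",
    "noise_sweep",
    "connectivity_sweep",
    "gamma_alpha_scan",
]


@dataclass
class SweepSpec:
    """Grid specification for the (eps1, eps2) phase diagram.

    Full-scale defaults: eps1 in [0, 0.01] and eps2 in [0, 0.003], step
    1e-4 on both axes, 200 realizations of 4e4 steps per pixel with the
    order parameters averaged over the final 1000 steps.
    """

    N: int = 10
    eps1_max: float = 0.01
    eps2_max: float = 0.003
    eps1_step: float = 1e-4
    eps2_step: float = 1e-4
    n_realizations: int = 200
    n_steps: int = 40_000
    averaging_steps: int = 1000
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps1_step <= 0 or self.eps2_step <= 0:
            raise ValidationError("grid steps must be positive")
        if self.n_realizations < 1:
            raise ValidationError("n_realizations must be >= 1")

    @property
    def eps1_values(self) -> np.ndarray:
        n = int(round(self.eps1_max / self.eps1_step))
        return np.round(np.arange(n + 1) * self.eps1_step, 12)

    @property
    def eps2_values(self) -> np.ndarray:
        n = int(round(self.eps2_max / self.eps2_step))
        return np.round(np.arange(n + 1) * self.eps2_step, 12)


@dataclass
class PhaseDiagram:
    """Per-pixel mean order parameters and categorical labels."""

    eps1_values: np.ndarray
    eps2_values: np.ndarray
    mean_R: np.ndarray  # shape (len(eps1), len(eps2))
    mean_R2: np.ndarray
    labels: np.ndarray  # same shape, dtype object (classification strings)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e1 in enumerate(self.eps1_values):
            for j, e2 in enumerate(self.eps2_values):
                rows.append(
                    dict(
                        eps1=e1,
                        eps2=e2,
                        mean_R=self.mean_R[i, j],
                        mean_R2=self.mean_R2[i, j],
                        label=self.labels[i, j],
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class BoundaryFit:
    """Quadratic least-squares fit eps2 = a*eps1^2 + b*eps1 + c of the boundary."""

    coefficients: np.ndarray  # (a, b, c)
    points: np.ndarray  # (n, 2) boundary pixels used
    residuals: np.ndarray


def sweep_epsilon_grid(spec: SweepSpec) -> PhaseDiagram:
    """Categorical phase diagram over the (eps1, eps2) grid.

    Each pixel runs ``n_realizations`` independent noise-free realizations,
    averages R and R2 over the final ``averaging_steps`` steps of each run,
    then averages over realizations and classifies the pixel once from the
    realization means.
    """
    e1s, e2s = spec.eps1_values, spec.eps2_values
    mean_r = np.empty((e1s.size, e2s.size))
    mean_r2 = np.empty((e1s.size, e2s.size))
    labels = np.empty((e1s.size, e2s.size), dtype=object)
    cfg = SimConfig(
        dt=spec.dt, n_steps=spec.n_steps, record_stride=spec.n_steps, seed=None
    )
    tail = spec.n_steps - spec.averaging_steps
    for i, e1 in enumerate(e1s):
        for j, e2 in enumerate(e2s):
            pix = i * e2s.size + j
            acc_r = 0.0
            acc_r2 = 0.0
            params = ModelParams(N=spec.N, eps1=float(e1), eps2=float(e2))
            for r in range(spec.n_realizations):
                ic = sample_initial_condition(
                    spec.N, seed=np.random.SeedSequence([spec.seed, pix, r])
                )
                traj = simulate(params, cfg, ic.as_state())
                acc_r += traj.R[tail:].mean()
                acc_r2 += traj.R2[tail:].mean()
            mean_r[i, j] = acc_r / spec.n_realizations
            mean_r2[i, j] = acc_r2 / spec.n_realizations
            labels[i, j] = classify_state(mean_r[i, j], mean_r2[i, j])
    return PhaseDiagram(
        eps1_values=e1s,
        eps2_values=e2s,
        mean_R=mean_r,
        mean_R2=mean_r2,
        labels=labels,
    )


def fit_transition_boundary(diagram: PhaseDiagram) -> BoundaryFit | None:
    """Quadratic fit of the anti-phase/incoherent boundary, or None.

    For each eps1 column the boundary point is the smallest eps2 whose pixel
    is labelled incoherent; columns without an incoherent pixel are skipped.
    Returns None when fewer than 3 boundary points exist.
    """
    pts = []
    for i, e1 in enumerate(diagram.eps1_values):
        col = diagram.labels[i]
        idx = [j for j, lab in enumerate(col) if lab == "incoherent"]
        if idx:
            pts.append((e1, diagram.eps2_values[min(idx)]))
    if len(pts) < 3:
        return None
    pts_arr = np.asarray(pts, dtype=float)
    coeffs = np.polyfit(pts_arr[:, 0], pts_arr[:, 1], deg=2)
    residuals = pts_arr[:, 1] - np.polyval(coeffs, pts_arr[:, 0])
    return BoundaryFit(coefficients=coeffs, points=pts_arr, residuals=residuals)


def noise_sweep(
    sigmas,
    params: ModelParams,
    config: SimConfig,
    seed: int = 0,
    detect_events: bool = True,
) -> list[dict]:
    """Re-run the identical initial condition under several noise strengths.

    Returns one record per sigma with the trajectory, the long-time
    classification and (optionally) the switching-event count.
    """
    ic = sample_initial_condition(params.N, seed=np.random.SeedSequence([seed]))
    out = []
    for s_i, sigma in enumerate(sigmas):
        p = params.with_(sigma=float(sigma))
        cfg = SimConfig(
            dt=config.dt,
            n_steps=config.n_steps,
            transient_fraction=config.transient_fraction,
            record_stride=config.record_stride,
            seed=(seed + 1 + s_i),
            store_phases=detect_events,
        )
        traj = simulate(p, cfg, ic.as_state())
        mr, mr2 = traj.mean_order_parameters()
        label = classify_state(mr, mr2)
        n_events = None
        if detect_events and label != "incoherent":
            n_events = len(detect_switch_events(traj))
        out.append(
            dict(
                sigma=float(sigma),
                trajectory=traj,
                mean_R=mr,
                mean_R2=mr2,
                label=label,
                n_events=n_events,
            )
        )
    return out


def connectivity_sweep(
    N: int,
    mean_degrees,
    n_realizations: int,
    config: SimConfig | None = None,
    eps1: float = 0.01,
    eps2: float = 0.0001,
    seed: int = 0,
    rth: float = R_THRESHOLD,
    merge_gap: int = 50,
) -> pd.DataFrame:
    """Mean/std two-cluster dwell time versus average degree (sparse variant).

    Per degree, ``n_realizations`` connected Erdos-Renyi graphs and initial
    conditions are drawn; dwell intervals (R < rth while R2 > rth, debounced
    with :func:`merge_dwell_intervals`) are pooled over the post-transient
    window of every realization.  Durations are in simulation steps.
    """
    if config is None:
        config = SimConfig()
    rows = []
    for d_i, deg in enumerate(mean_degrees):
        durations: list[int] = []
        realized = []
        for r in range(n_realizations):
            ss = np.random.SeedSequence([seed, d_i, r])
            child = ss.spawn(2)
            adj = generate_connected_graph(N, deg, seed=np.random.default_rng(child[0]))
            realized.append(adj.sum() / N)
            params = ModelParams(
                N=N, eps1=eps1, eps2=eps2, adjacency=adj, variant="sparse"
            )
            ic = sample_initial_condition(N, seed=np.random.default_rng(child[1]))
            traj = simulate(params, config, ic.as_state())
            start = config.transient_steps
            ivs = dwell_intervals(traj.R[start:], traj.R2[start:], rth=rth)
            for iv in merge_dwell_intervals(ivs, merge_gap=merge_gap):
                durations.append(iv.duration)
        durations_arr = np.asarray(durations, dtype=float)
        rows.append(
            dict(
                mean_degree=float(deg),
                realized_mean_degree=float(np.mean(realized)),
                dwell_mean=float(durations_arr.mean()) if durations else float("nan"),
                dwell_std=float(durations_arr.std()) if durations else float("nan"),
                n_intervals=len(durations),
            )
        )
    return pd.DataFrame(rows)


def gamma_alpha_scan(
    gamma0_values,
    alpha_values,
    N: int = 10,
    config: SimConfig | None = None,
    eps1: float = 0.01,
    eps2: float = 0.0001,
    seed: int = 0,
) -> pd.DataFrame:
    """Classification and inter-cluster phase gap over a (gamma0, alpha) grid.

    Uses the frequency-adaptive variant.  The phase gap is the circular
    distance between the two cluster mean phases of the final snapshot
    (NaN when no two-cluster structure is present).
    """
    if config is None:
        config = SimConfig(n_steps=40_000)
    rows = []
    for g_i, g0 in enumerate(gamma0_values):
        for a_i, alpha in enumerate(alpha_values):
            params = ModelParams(
                N=N,
                eps1=eps1,
                eps2=eps2,
                gamma0=float(g0),
                alpha=float(alpha),
                variant="freq_adaptive",
            )
            pix = g_i * len(alpha_values) + a_i
            ic = sample_initial_condition(
                N, seed=np.random.SeedSequence([seed, pix])
            )
            traj = simulate(params, config, ic.as_state())
            mr, mr2 = traj.mean_order_parameters()
            label = classify_state(mr, mr2)
            gap = float("nan")
            part = assign_clusters(traj.final_state.theta)
            if part is not None and 0 < part.sizes[1] < N:
                theta = traj.final_state.theta
                z0 = np.exp(1j * theta[part.labels == 0]).mean()
                z1 = np.exp(1j * theta[part.labels == 1]).mean()
                gap = abs(float(np.angle(z1 / z0)))
            rows.append(
                dict(
                    gamma0=float(g0),
                    alpha=float(alpha),
                    mean_R=mr,
                    mean_R2=mr2,
                    label=label,
                    phase_gap=gap,
                )
            )
    return pd.DataFrame(rows)
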