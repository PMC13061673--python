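"""Snapshot-based estimated-time-of-escape (ETE) forecasting.

Between two switching events the system lingers near a saddle: the phases
sit close to the two cluster positions and drift slowly.  Given a single
snapshot taken ``tau_win`` steps before a detected event, the per-oscillator
escape time is extrapolated linearly,

.. math::

    \\eta_i = \\frac{|\\theta_B - \\theta_i(t_{snap})|}
                   {\\dot\\theta_i(t_{snap})\\,dt},

in units of simulation steps, with the boundary at ``theta_B = pi`` (the
anti-podal point of the oscillator's own cluster, measured in the co-moving
``psi2/2`` frame).  Oscillators whose ETE exceeds ``eta_max`` are excluded.
The leading oscillator is the argmin; the predicted switcher set collects
every oscillator within ``delta_eta`` steps of the leader.  Predictions are
compared with the actual crossing set and scored Perfect / Good / Partial /
Missed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .integrate import SimConfig, simulate
from .model import ModelParams
from .observables import (
    R_THRESHOLD,
    detect_switch_events,
    relative_phases,
    track_crossings,
)
from .sampling import sample_initial_condition

__all__ = [
    "EscapeForecast",
    "PredictionSummary",
    "CATEGORIES",
    "estimate_escape_times",
    "predict_switcher_set",
    "score_prediction",
    "run_prediction_experiment",
]

CATEGORIES = ("Perfect", "Good", "Partial", "Missed")


@dataclass
class EscapeForecast:
    """Per-event forecast: ETEs, leader, predicted set and (later) category."""

    t_snap: int
    eta: np.ndarray
    excluded: np.ndarray
    leader: int | None
    predicted_set: frozenset[int]
    category: str | None = None


@dataclass
class PredictionSummary:
    """Aggregate scoring over all detected events of an experiment."""

    counts: dict[str, int]
    n_realizations: int
    n_events_per_realization: list[int] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.n_events
        if total == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: 100.0 * self.counts.get(c, 0) / total for c in CATEGORIES}

    @property
    def success_rate(self) -> float:
        """Perfect + Good, in percent of all scored events."""
        p = self.percentages
        return p["Perfect"] + p["Good"]


def estimate_escape_times(
    theta_snap: np.ndarray,
    theta_dot_snap: np.ndarray,
    dt: float,
    theta_b: float = np.pi,
    eta_max: float = 500.0,
    velocity_mode: str = "signed",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-oscillator ETE in steps, with exclusions.

    ``theta_snap`` holds signed angular offsets from each oscillator's own
    cluster reference (so the boundary sits at ``+-theta_b``) and
    ``theta_dot_snap`` the instantaneous phase velocities in the same frame
    (rad per unit time; ``theta_dot * dt`` is the displacement per step).

    ``eta_i = (theta_b - |theta_i|) / (|theta_dot_i| * dt)``.  An oscillator
    is excluded when its ETE strictly exceeds ``eta_max``, when its velocity
    vanishes, or -- in the default ``"signed"`` mode -- when its velocity
    points back toward its own cluster so the linear model never reaches the
    boundary.  ``velocity_mode="magnitude"`` skips the direction test.

    Returns ``(eta, excluded)``; excluded entries of ``eta`` are ``inf``.
    """
    if velocity_mode not in ("signed", "magnitude"):
        raise ValidationError("velocity_mode must be 'signed' or 'magnitude'")
    x = np.abs(np.asarray(theta_snap, dtype=float))
    v = np.asarray(theta_dot_snap, dtype=float)
    if x.shape != v.shape:
        raise ValidationError("theta_snap and theta_dot_snap must match in shape")
    step_disp = np.abs(v) * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.where(step_disp > 0, (theta_b - x) / step_disp, np.inf)
    eta = np.where(x >= theta_b, 0.0, eta)  # already at/past the boundary
    excluded = ~np.isfinite(eta) | (eta > eta_max)
    if velocity_mode == "signed":
        away = (np.sign(v) * np.sign(np.asarray(theta_snap, dtype=float)) < 0) & (
            x > 0
        ) & (x < theta_b)
        excluded |= away
    eta = np.where(excluded, np.inf, eta)
    return eta, excluded


def predict_switcher_set(
    eta: np.ndarray, delta_eta: float = 150.0
) -> tuple[int | None, frozenset[int]]:
    """Leader (argmin ETE) and predicted set {j : eta_j <= eta* + delta_eta}.

    Excluded oscillators (``eta = inf``) never enter the set.  With every
    oscillator excluded the forecast is empty and the leader ``None``.
    """
    eta = np.asarray(eta, dtype=float)
    finite = np.isfinite(eta)
    if not finite.any():
        return None, frozenset()
    leader = int(np.argmin(np.where(finite, eta, np.inf)))
    cut = eta[leader] + delta_eta
    return leader, frozenset(np.flatnonzero(finite & (eta <= cut)).tolist())


def score_prediction(P: frozenset[int] | set[int], A: frozenset[int] | set[int]) -> str:
    """Four-way comparison of predicted set P with actual switcher set A.

    Perfect: P = A.  Good: A a proper subset of P.  Partial: the sets
    intersect but A is not contained in P.  Missed: disjoint.
    """
    P, A = frozenset(P), frozenset(A)
    if not A:
        raise ValidationError("scoring requires a non-empty actual switcher set")
    if P == A:
        return "Perfect"
    if A < P:
        return "Good"
    if P & A:
        return "Partial"
    return "Missed"


def forecast_events(
    traj,
    tau_win: int = 200,
    eta_max: float = 500.0,
    delta_eta: float = 150.0,
    grouping_window: int = 50,
    t_min: int | None = None,
    velocity_mode: str = "signed",
    rth: float = R_THRESHOLD,
    max_transit: int | None = None,
) -> list[EscapeForecast]:
    """Forecast and score every detected switching event of a trajectory.

    The snapshot is taken ``tau_win`` steps before each event's first
    crossing; phase offsets and velocities are measured in the co-moving
    ``psi2/2`` frame (velocities from the one-step displacement of the
    relative phase, which for the noise-free runs equals the deterministic
    drift exactly).  Events whose snapshot would fall before the two-cluster
    anchor step are skipped.
    """
    from .observables import MAX_TRANSIT_STEPS

    if max_transit is None:
        max_transit = MAX_TRANSIT_STEPS
    events = detect_switch_events(
        traj,
        grouping_window=grouping_window,
        t_min=t_min,
        rth=rth,
        max_transit=max_transit,
    )
    if not events:
        return []
    crossings, homes0, anchor = track_crossings(traj, rth=rth)
    u = relative_phases(traj)
    dt = traj.config.dt if traj.config else 0.01
    # reconstruct each oscillator's home position as a function of time
    forecasts: list[EscapeForecast] = []
    cross_idx = 0
    homes = homes0.copy()
    n_cross = len(crossings)
    for ev in events:
        snap = ev.t_event - tau_win
        if snap <= anchor or snap + 1 > traj.n_steps:
            continue
        while cross_idx < n_cross and crossings[cross_idx].step <= snap:
            rec = crossings[cross_idx]
            homes[rec.oscillator] += np.pi * rec.direction
            cross_idx += 1
        offsets = u[snap] - homes
        vel = (u[snap + 1] - u[snap]) / dt
        eta, _excl = estimate_escape_times(
            offsets, vel, dt, eta_max=eta_max, velocity_mode=velocity_mode
        )
        leader, pred = predict_switcher_set(eta, delta_eta=delta_eta)
        cat = score_prediction(pred, ev.actual_set)
        forecasts.append(
            EscapeForecast(
                t_snap=snap,
                eta=eta,
                excluded=~np.isfinite(eta),
                leader=leader,
                predicted_set=pred,
                category=cat,
            )
        )
    return forecasts


def run_prediction_experiment(
    params: ModelParams,
    config: SimConfig,
    n_realizations: int,
    tau_win: int = 200,
    eta_max: float = 500.0,
    delta_eta: float = 150.0,
    grouping_window: int = 50,
    seed: int = 0,
    velocity_mode: str = "signed",
) -> PredictionSummary:
    """Full protocol: simulate, detect, forecast and score over realizations.

    Each realization draws fresh uniform initial phases and couplings from an
    independent substream of ``seed``; events before 30% of the run are
    discarded.  Realizations without events contribute zero counts.
    """
    counts: Counter[str] = Counter()
    per_real: list[int] = []
    cfg = SimConfig(
        dt=config.dt,
        n_steps=config.n_steps,
        transient_fraction=config.transient_fraction,
        record_stride=config.record_stride,
        seed=config.seed,
        store_phases=True,
    )
    for r in range(n_realizations):
        ic = sample_initial_condition(params.N, seed=np.random.SeedSequence([seed, r]))
        traj = simulate(params, cfg, ic.as_state())
        fcs = forecast_events(
            traj,
            tau_win=tau_win,
            eta_max=eta_max,
            delta_eta=delta_eta,
            grouping_window=grouping_window,
            t_min=int(cfg.transient_fraction * cfg.n_steps),
        )
        per_real.append(len(fcs))
        for fc in fcs:
            counts[fc.category] += 1
    return PredictionSummary(
        counts=dict(counts),
        n_realizations=n_realizations,
        n_events_per_realization=per_real,
    )
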