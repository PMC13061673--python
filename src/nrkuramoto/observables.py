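"""Order parameters, state classification, cluster membership and switching.

The first and second Kuramoto order parameters,

.. math::

    R e^{i\\psi} = \\frac{1}{N}\\sum_j e^{i\\theta_j}, \\qquad
    R_2 e^{i\\psi_2} = \\frac{1}{N}\\sum_j e^{2i\\theta_j},

distinguish in-phase synchrony (R, R2 both near 1), two anti-phase clusters
(R near 0, R2 near 1) and incoherence (both small).  Long-time averages are
thresholded at ``Rth = 0.8`` to classify a run.

Cluster membership is decided in the frame of the second-order mean field:
the direction ``psi2 / 2`` points along one cluster, so an oscillator joins
cluster 0 when ``cos(theta - psi2/2) > 0``.  Switching events are crossings
of the anti-podal point: an oscillator switches when its unwrapped angular
distance from its own cluster's reference direction first reaches pi.
Working in the (slowly moving) ``psi2/2`` frame makes detection immune to
global phase drift; with the clusters at 0 and pi it reduces to crossing the
fixed boundary at pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import UnsupportedConfigurationError, ValidationError
from .integrate import Trajectory
from .model import TWO_PI, ClusterPartition

__all__ = [
    "OrderParameters",
    "SwitchEvent",
    "DwellInterval",
    "R_THRESHOLD",
    "order_parameters",
    "classify_state",
    "assign_clusters",
    "relative_phases",
    "CrossingRecord",
    "track_crossings",
    "detect_switch_events",
    "dwell_intervals",
]

R_THRESHOLD = 0.8


@dataclass(frozen=True)
class OrderParameters:
    """First/second Kuramoto order parameters and mean-field angles."""

    R: float
    psi: float
    R2: float
    psi2: float


@dataclass
class SwitchEvent:
    """A grouped cluster-switching event.

    ``t_event`` is the step index of the first boundary crossing in the
    group; ``actual_set`` the oscillators (0-based ids) that crossed within
    the grouping window; ``pre_partition``/``post_partition`` the cluster
    assignments immediately before and after the event.
    """

    t_event: int
    actual_set: frozenset[int]
    pre_partition: ClusterPartition
    post_partition: ClusterPartition


@dataclass(frozen=True)
class DwellInterval:
    """Half-open step range ``[start, end)`` spent in the two-cluster state."""

    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrossingRecord:
    """A single oscillator crossing the pi boundary at ``step``.

    ``direction`` is +1/-1 for the sign of the angular excursion;
    ``transit`` is the number of steps the oscillator spent outside its own
    basin (beyond pi/2 from home) before completing the crossing.
    """

    step: int
    oscillator: int
    direction: int
    transit: int


def order_parameters(theta: np.ndarray) -> OrderParameters:
    """Compute (R, psi, R2, psi2) from a phase vector."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValidationError("order parameters require at least one phase")
    z = np.exp(1j * theta).mean()
    z2 = np.exp(2j * theta).mean()
    return OrderParameters(
        R=float(abs(z)), psi=float(np.angle(z)), R2=float(abs(z2)), psi2=float(np.angle(z2))
    )


def classify_state(
    mean_R: float, mean_R2: float, rth: float = R_THRESHOLD
) -> str:
    """Three-way collective-state label from long-time averages.

    ``in_phase`` when both averages exceed ``rth``; ``anti_phase_clusters``
    when ``<R> <= rth < <R2>``; ``incoherent`` otherwise.  The comparison at
    the boundary is deliberately non-strict for <R>.
    """
    eps = 1e-9  # tolerate floating-point spill just past the unit interval
    for v in (mean_R, mean_R2):
        if not -eps <= v <= 1 + eps:
            raise ValidationError("order-parameter averages must lie in [0, 1]")
    if mean_R > rth and mean_R2 > rth:
        return "in_phase"
    if mean_R <= rth and mean_R2 > rth:
        return "anti_phase_clusters"
    return "incoherent"


def assign_clusters(
    theta: np.ndarray, r2_floor: float = 0.2
) -> ClusterPartition | None:
    """Two-cluster membership from a snapshot, or None.

    Uses the reference direction ``psi2 / 2``: oscillator ``i`` joins cluster
    0 when ``cos(theta_i - psi2/2) >= 0`` (ties included).  Labels are
    normalised so that oscillator 0 carries label 0.  When ``R2`` falls below
    ``r2_floor`` there is no meaningful two-cluster structure and ``None`` is
    returned.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size < 2:
        raise ValidationError("cluster assignment requires N >= 2")
    op = order_parameters(theta)
    if op.R2 < r2_floor:
        return None
    ref = op.psi2 / 2.0
    labels = (np.cos(theta - ref) < 0).astype(int)
    if labels[0] == 1:
        labels = 1 - labels
        ref = ref + np.pi
    members = theta[labels == 0]
    ref_phase = float(np.angle(np.exp(1j * members).mean())) % TWO_PI
    return ClusterPartition(labels=labels, reference_phase=ref_phase)


def relative_phases(traj: Trajectory) -> np.ndarray:
    """Unwrapped phases in the co-moving ``psi2/2`` frame, shape (T+1, N).

    The reference angle is the temporally unwrapped second-order mean-field
    angle halved; subtracting it from the unwrapped phase series gives a
    series in which each cluster sits near a constant multiple of pi.
    """
    if traj.theta_full is None:
        raise UnsupportedConfigurationError(
            "switching analysis needs full-resolution phases; "
            "run simulate with store_phases=True"
        )
    ref = np.unwrap(traj.psi2) / 2.0
    return traj.theta_full - ref[:, None]


@njit(cache=True)
def _track(u, h, start):  # pragma: no cover - exercised via track_crossings
    n = u.shape[1]
    steps = []
    oscs = []
    dirs = []
    transits = []
    last_inside = np.full(n, start, dtype=np.int64)
    half_pi = np.pi / 2.0
    for t in range(start, u.shape[0]):
        for i in range(n):
            d = u[t, i] - h[i]
            if -half_pi < d < half_pi:
                last_inside[i] = t
            elif d >= np.pi or d <= -np.pi:
                sgn = 1 if d > 0 else -1
                steps.append(t)
                oscs.append(i)
                dirs.append(sgn)
                transits.append(t - last_inside[i])
                h[i] += np.pi * sgn
                last_inside[i] = t
    return steps, oscs, dirs, transits


#: Crossings that take longer than this many steps from basin boundary to the
#: anti-podal point are quasi-static lock slips, not switching events.
MAX_TRANSIT_STEPS = 5000


def track_crossings(
    traj: Trajectory, rth: float = R_THRESHOLD
) -> tuple[list[CrossingRecord], np.ndarray, int]:
    """All pi-boundary crossings of a trajectory.

    Home positions are anchored (as the nearest multiple of pi of each
    relative phase) at the first step where ``R2 > rth``, i.e. once the
    two-cluster structure has formed; every time an oscillator's relative
    phase departs pi from its home, a crossing is recorded and the home moves
    to the newly reached position.

    Each record also carries the transit time: the number of steps since the
    oscillator last sat inside its own basin (within pi/2 of home).  A
    dynamical switch jumps across in at most a few hundred steps, whereas a
    quasi-static lock slip -- the slow coupling drift moving a settled
    anti-podal lock past the threshold -- takes tens of thousands; the
    transit time is what event detection uses to tell them apart.

    Returns ``(crossings, homes_at_anchor, anchor_step)``.
    """
    u = relative_phases(traj)
    anchored = np.flatnonzero(traj.R2 > rth)
    if anchored.size == 0:
        raise UnsupportedConfigurationError(
            "trajectory never forms a two-cluster structure (R2 stays below rth)"
        )
    anchor = int(anchored[0])
    homes = np.pi * np.round(u[anchor] / np.pi)
    steps, oscs, dirs, transits = _track(u, homes.copy(), anchor + 1)
    crossings = [
        CrossingRecord(step=int(t), oscillator=int(i), direction=int(d), transit=int(tr))
        for t, i, d, tr in zip(steps, oscs, dirs, transits)
    ]
    return crossings, homes, anchor


def _partition_from_homes(homes: np.ndarray, reference_phase: float) -> ClusterPartition:
    labels = (np.round(homes / np.pi).astype(int) % 2).astype(int)
    if labels[0] == 1:
        labels = 1 - labels
    return ClusterPartition(labels=labels, reference_phase=reference_phase % TWO_PI)


def detect_switch_events(
    traj: Trajectory,
    grouping_window: int = 50,
    t_min: int | None = None,
    rth: float = R_THRESHOLD,
    max_transit: int = MAX_TRANSIT_STEPS,
) -> list[SwitchEvent]:
    """Grouped switching events of a metastable run.

    Only dynamical crossings (transit time <= ``max_transit`` steps) count
    as switching; quasi-static lock slips still advance the bookkeeping but
    are not reported.  Dynamical crossings closer than ``grouping_window``
    steps to the previous one are merged into a single collective event.
    Events whose first crossing occurs at or before ``t_min`` (default: 30%
    of the run, the transient cutoff) are discarded.  Each event carries the
    set of oscillators that crossed and the cluster partitions before and
    after the group.
    """
    crossings, homes, _anchor = track_crossings(traj, rth=rth)
    if t_min is None:
        t_min = int(0.3 * traj.n_steps)
    events: list[SwitchEvent] = []
    homes = homes.copy()
    ref = np.unwrap(traj.psi2) / 2.0
    idx = 0
    n_cross = len(crossings)
    while idx < n_cross:
        first = crossings[idx]
        if first.transit > max_transit:  # lock slip: bookkeeping only
            homes[first.oscillator] += np.pi * first.direction
            idx += 1
            continue
        pre = _partition_from_homes(homes, ref[first.step])
        members: set[int] = set()
        last_step = first.step
        while idx < n_cross and crossings[idx].step - last_step <= grouping_window:
            rec = crossings[idx]
            if rec.transit <= max_transit:
                members.add(rec.oscillator)
            homes[rec.oscillator] += np.pi * rec.direction
            last_step = rec.step
            idx += 1
        post = _partition_from_homes(homes, ref[last_step])
        if first.step > t_min:
            events.append(
                SwitchEvent(
                    t_event=first.step,
                    actual_set=frozenset(members),
                    pre_partition=pre,
                    post_partition=post,
                )
            )
    return events


def periodicity_peak(
    series: np.ndarray, min_lag: int, max_lag: int, lag_step: int = 1
) -> tuple[int, float]:
    """Best normalized autocorrelation of a series over a lag range.

    Scans lags in ``[min_lag, max_lag]`` and returns ``(lag, corr)`` for the
    largest per-lag Pearson correlation between the series and its shifted
    copy.  A strictly periodic signal scores ~1 at (multiples of) its period;
    used to test whether coupling traces retrace after the transient.
    """
    x = np.asarray(series, dtype=float)
    if max_lag >= x.size:
        raise ValidationError("max_lag must be smaller than the series length")
    best = (min_lag, -1.0)
    for lag in range(min_lag, max_lag + 1, lag_step):
        c = float(np.corrcoef(x[:-lag], x[lag:])[0, 1])
        if c > best[1]:
            best = (lag, c)
    return best


def dwell_intervals(
    R_series: np.ndarray, R2_series: np.ndarray, rth: float = R_THRESHOLD
) -> list[DwellInterval]:
    """Maximal runs with ``R < rth`` and ``R2 > rth`` (two-cluster dwells).

    Durations are in steps; intervals truncated by the series boundaries are
    included as observed.
    """
    R_series = np.asarray(R_series, dtype=float)
    R2_series = np.asarray(R2_series, dtype=float)
    if R_series.shape != R2_series.shape:
        raise ValidationError("R and R2 series must have equal length")
    mask = (R_series < rth) & (R2_series > rth)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [DwellInterval(int(a), int(b)) for a, b in zip(starts, ends)]


def merge_dwell_intervals(
    intervals: list[DwellInterval], merge_gap: int = 50
) -> list[DwellInterval]:
    """Debounce a dwell-interval list: close gaps shorter than ``merge_gap``.

    Lifetime measurements from hard thresholds fragment when an order
    parameter hovers at the threshold (e.g. the 9-1 partition of N = 10 has
    R = 0.8 exactly); gaps shorter than the event-grouping scale are not
    genuine departures from the two-cluster state, so adjacent intervals
    separated by less than ``merge_gap`` steps are merged.
    """
    if not intervals:
        return []
    merged = [intervals[0]]
    for iv in intervals[1:]:
        last = merged[-1]
        if iv.start - last.end < merge_gap:
            merged[-1] = DwellInterval(last.start, iv.end)
        else:
            merged.append(iv)
    return merged
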