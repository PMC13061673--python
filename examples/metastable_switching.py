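"""Metastable anti-phase clusters in the non-reciprocal adaptive model.

Simulates N = 10 oscillators with fast Hebbian (eps1 = 0.01) and slow
anti-Hebbian (eps2 = 1e-4) coupling adaptation, then reports the long-time
classification, the switching events, and the dwell-time statistics of the
two-cluster state.
"""

import numpy as np

from nrkuramoto import (
    ModelParams,
    SimConfig,
    classify_state,
    detect_switch_events,
    dwell_intervals,
    sample_initial_condition,
    simulate,
)

params = ModelParams(N=10, eps1=0.01, eps2=0.0001)
config = SimConfig(n_steps=1_800_000, store_phases=True)
ic = sample_initial_condition(params.N, seed=np.random.SeedSequence(1))
traj = simulate(params, config, ic.as_state())

mean_R, mean_R2 = traj.mean_order_parameters()
print(f"<R>  = {mean_R:.3f}   (global synchrony: low, the clusters cancel)")
print(f"<R2> = {mean_R2:.3f}   (two-cluster order: high)")
print(f"state: {classify_state(mean_R, mean_R2)}")

events = detect_switch_events(traj)
print(f"\n{len(events)} switching events after the 30% transient:")
for ev in events:
    na, nb = ev.pre_partition.sizes
    na2, nb2 = ev.post_partition.sizes
    print(
        f"  step {ev.t_event:>9d}: oscillators {sorted(ev.actual_set)} "
        f"switched cluster ({na}-{nb} -> {na2}-{nb2})"
    )

start = config.transient_steps
ivs = dwell_intervals(traj.R[start:], traj.R2[start:])
durations = np.array([iv.duration for iv in ivs])
print(
    f"\n{len(ivs)} anti-phase dwell intervals; mean duration "
    f"{durations.mean():,.0f} steps ({durations.mean() * config.dt:,.0f} time units)"
)
# R2 stays pinned near 1 while the system dwells at a saddle:
r2 = np.concatenate([traj.R2[start + iv.start : start + iv.end] for iv in ivs])
print(f"mean R2 inside dwells: {r2.mean():.4f} (well above the 0.8 threshold)")
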