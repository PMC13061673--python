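# Methods

## Model and variants

The package integrates `N` coupled phase oscillators whose directed
couplings adapt to the phase dynamics:

    dθ_i/dt = ω_i + (1/N) Σ_j k_ij sin(θ_j − θ_i) + ξ_i(t),
    dk_ij/dt = −ε₁ [k_ij + sin(θ_i − θ_j + β₁)]   (i < j),
    dk_ij/dt = −ε₂ [k_ij + sin(θ_i − θ_j + β₂)]   (i > j),
    k_ii = 0,   ⟨ξ_i(t) ξ_j(t′)⟩ = σ² δ_ij δ(t − t′).

Each off-diagonal coupling relaxes at rate `ε` toward the bounded target
`−sin(θ_i − θ_j + β) ∈ [−1, 1]`.  With `β₁ = −π/2` the upper triangle is
Hebbian — couplings between in-phase (anti-phase) pairs grow toward +1
(−1) — and with `β₂ = +π/2` the lower triangle is anti-Hebbian.  The sign
convention is fixed by the in-cluster slopes: for two co-clustered
oscillators the upper coupling obeys `k̇ = −ε₁(k − 1)` and the lower
`k̇ = −ε₂(k + 1)`; the rate multiplies the whole bracket.

Default rates `ε₁ = 0.01`, `ε₂ = 10⁻⁴` separate three time scales: phases
O(1) (≈10² steps at `dt = 0.01`), fast couplings O(1/ε₁) (≈10⁴ steps),
slow couplings O(1/ε₂) (≈10⁶ steps).  Metastability lives in this
separation: the fast triangle stabilizes a two-cluster anti-phase state,
the slow triangle erodes it.

Variants:

- `sparse` — both equations are restricted to the links of a symmetric,
  connected 0/1 adjacency; the phase sum is normalized by the node degree.
  Couplings of non-links retain their initial values but are frozen and
  never influence the dynamics or reports.
- `freq_adaptive` — `dθ_i/dt = ω_i + (1/N) Σ_j k_ij [Γ₀ − sin(θ_i − θ_j + α)]`
  with effective frequencies `ω̃_i = ω_i + (Γ₀/N) Σ_j k_ij`.  With
  `Γ₀ = α = 0` it coincides exactly with the dense variant.

`ε₁, ε₂ ≥ 0` is accepted (a zero rate freezes that triangle) so the phase
diagram can include its `ε = 0` boundary rows.

## Integration

Euler–Maruyama with fixed `dt = 0.01`: drift `dt · rhs`, phase noise
`σ √dt 𝒩(0,1)` per oscillator per step, couplings noise-free, phases
wrapped to `[0, 2π)` every step.  An unwrapped copy accumulates raw
increments for crossing detection.  Each coupling update is a convex
combination of the current value and a target in `[−1, 1]` whenever
`ε dt < 1`, so `|k_ij| ≤ 1` is preserved exactly — asserted at recorded
frames.  The compiled inner loop (numba) evaluates the trigonometry through
per-oscillator sin/cos products and records `R`, `R2` and the second-order
mean-field angle `ψ₂` at every step; full phase snapshots are strided
unless a consumer (event detection, forecasting) requests the
full-resolution series.  Runs are deterministic given (params, config,
initial state, seed); experiment sweeps derive independent substreams per
(point, realization) from a master seed, so results are independent of
execution order.

Homogeneous nonzero `ω` is equivalent to the co-rotating `ω = 0` run plus
a linear drift.  The equivalence is exact for the idealized map but not
bit-exact in floating point (the wrapped phases at which sin/cos are
evaluated differ), accumulating ≤10⁻⁸ rad over 10⁵ steps; tests assert it
at 10⁻⁶.

## Order parameters, classification, clusters

`R e^{iψ} = (1/N) Σ e^{iθ_j}` and `R2 e^{iψ₂} = (1/N) Σ e^{2iθ_j}`.
Long-time averages discard the first 30% of a run.  Classification at
`Rth = 0.8`: in-phase if both averages exceed `Rth`; two anti-phase
clusters if `⟨R⟩ ≤ Rth < ⟨R2⟩`; incoherent otherwise.  The comparisons are
deliberately non-strict for `⟨R⟩`, so the boundary value 0.8 classifies as
clustered.

Cluster membership is read off in the frame of the second-order mean
field: the direction `ψ₂/2` points along one cluster, and oscillator `i`
joins cluster 0 iff `cos(θ_i − ψ₂/2) ≥ 0`.  With `ω = 0` the global phase
is only marginally stable (one zero eigenvalue), so all crossing detection
works with relative phases `u_i(t) = θ_i^unwrap(t) − unwrap(ψ₂)(t)/2`,
which reduces to the fixed clusters-at-0-and-π convention when there is no
drift.  When `R2` is below 0.2 no meaningful partition exists and none is
reported.

## Switching events

Each oscillator has a *home* position (the nearest multiple of π of its
relative phase, anchored when `R2` first exceeds `Rth`).  A **crossing** is
recorded when `|u_i − home_i| ≥ π`; the home then advances by π.  Crossings
within 50 steps of the previous one merge into a single collective event;
events in the first 30% of the run are discarded.

One subtlety matters: the anti-podal lock is approached only
asymptotically, and the lock point itself creeps as the slow couplings
drift.  An oscillator that has long since joined the other cluster can
therefore sit at a distance of 0.95π–1.0π for 10⁴–10⁵ steps before its
wobble finally touches the exact-π threshold — a *quasi-static lock slip*
that does not perturb `R2` and has essentially zero velocity.  Crossings
therefore carry a **transit time** — steps elapsed since the oscillator
last sat inside its own basin (within π/2 of home) — and only crossings
with transit ≤ 5000 steps count as switching events.  Dynamical switches
take ~10²–10³ steps and slips ≥5×10⁴, so the cutoff sits comfortably
between the two populations; slips still advance the home bookkeeping.
Without this filter the late, zero-velocity slip timestamps masquerade as
unpredictable events and inflate the Missed rate by an order of magnitude.

## Escape forecasting

Given an event at step `t`, the snapshot at `t_snap = t − τ_win`
(`τ_win = 200`) supplies per-oscillator offsets `x_i = u_i − home_i` and
velocities.  The estimated time of escape, in steps, extrapolates linearly:

    η_i = (π − |x_i|) / (|θ̇_i| dt).

Velocities are the one-step displacement of the relative phase at the
snapshot — identical to the deterministic drift (minus frame drift) for
the noise-free protocol.  Excluded from consideration: `η_i > η_max = 500`
(strictly; `η = η_max` is kept), zero velocity, and — by default — velocity
pointing back toward the oscillator's own cluster, since the linear model
then never reaches the boundary (`velocity_mode="magnitude"` disables the
direction test).  The leader is `i* = argmin η_i` and the predicted set
`P = {j : η_j ≤ η_{i*} + Δη}` with `Δη = 150` steps.  Scoring against the
actual crossing set `A`: Perfect (`P = A`), Good (`A ⊂ P`, strict),
Partial (overlap but `A ⊄ P`), Missed (disjoint); an all-excluded forecast
is an empty `P`, scored Missed.

## Dwell times

A dwell is a maximal run of steps with `R < Rth` and `R2 > Rth`.  For
lifetime statistics, gaps shorter than 50 steps are merged away
(debouncing): some partitions put `R` exactly at the threshold — the 9–1
split of `N = 10` has `R = 0.8` at equilibrium — and would otherwise
fragment one dwell into thousands of one-step slivers.  Boundary-truncated
intervals are included as observed.  Durations are reported in steps and
converted by `dt` only for display.

## Saddle spectrum

At the two-cluster equilibrium (phases at `ref` and `ref + π`, couplings
at their fixed points ±1) the Jacobian splits: the phase–coupling block
vanishes (all `sin(θ_j − θ_i) = 0`), the coupling–coupling block is
diagonal with entries `−ε₁`/`−ε₂`, and the phase block takes the
partition-independent closed form `+1/N` above the diagonal, `−1/N` below,
with a row-sum-compensating diagonal.  Index reversal `χ` anti-commutes
with it, forcing the paired spectrum `±(1 − 2k/N)`: for `N = 2m`,
`k = 1..m−1` plus a double zero; for `N = 2m+1`, `k = 1..m` plus one zero.

Numerically the even-`N` double zero is *defective* (a 2×2 Jordan block:
the constant vector is an exact kernel vector, its pair only a generalized
eigenvector), so a float64 eigensolver splits it by O(√ε_mach) ≈ 10⁻⁸.
`spectrum_report` therefore defaults to an exact route: `N·Jθθ` is an
integer matrix, its characteristic polynomial is computed exactly
(Faddeev–LeVerrier over Python integers) and its integer roots deflated by
exact synthetic division.  The float64 eigensolver remains available as a
cross-checked secondary method with the documented 10⁻⁷ tolerance on zero
modes.  The zero-eigenvalue tolerance elsewhere is |λ| < 10⁻⁹.

## Experiments and scales

- **Phase diagram**: full scale is `ε₁ ∈ [0, 0.01]`, `ε₂ ∈ [0, 0.003]`,
  step 10⁻⁴ on both axes, 200 noise-free realizations of 4×10⁴ steps per
  pixel, `R`/`R2` averaged over the final 1000 steps of each run, then
  over realizations, then classified once per pixel.  The transition
  boundary is the smallest incoherent `ε₂` per `ε₁` column, fitted by a
  least-squares quadratic; residuals are reported, not hidden.  Tests and
  examples run reduced grids (the sweep cost scales linearly in pixels ×
  realizations × steps).
- **Prediction protocol**: production scale is 1000 realizations of
  1.8×10⁶ steps per system size.  The acceptance script uses 60 (`N = 6`)
  and 40 (`N = 10`) realizations at full length, giving event totals in
  the hundreds; the test suite additionally runs 150+150 realizations at
  4×10⁵ steps.  At `N = 6` switching requires the slow triangle to
  develop, so short runs produce almost no events — percentages for
  `N = 6` are only meaningful at full run length.
- **Connectivity sweep**: `N = 10`, mean degrees {3, 5, 7, 9}, connected
  Erdős–Rényi graphs (edge probability `⟨k⟩/(N−1)`, resampled until
  connected), dwell intervals pooled over realizations.
- **Noise sweep**: identical initial conditions across σ values.  At
  `σ = 0.1`, `N = 50` the measured `⟨R2⟩ ≈ 0.87` still sits above the 0.8
  threshold — remnants of the two-cluster organization survive — so the
  package reports degraded coherence rather than a clean incoherent label.
- **(Γ₀, α) scan**: metastable two-cluster behavior with heterogeneous
  instantaneous frequencies for `Γ₀ ≲ 0.2`; at intermediate gain the
  cluster gap shrinks below π and the coherence becomes borderline at the
  reduced scan length; incoherence for `Γ₀ ≳ 0.6`.

## Synthetic inputs

All inputs are generated: uniform phases on `[0, 2π)`, uniform couplings
on `[−1, 1]` (`k_ii = 0`), optionally couplings near +1 (`[1−δ, 1]`,
δ = 0.01) which prepend a long fully synchronized transient; connected
Erdős–Rényi graphs by rejection.  The generator mirrors the model's stated
initial-condition distributions exactly, so passing tests certify the
algorithmic pipeline, not robustness to empirical data artifacts (no
measurement noise models, missing data, or heterogeneous `dt`).

## Known limitations

- The `N = 4` switching cycle is not strictly periodic in double
  precision: during dwells the transverse phase distances contract below
  resolution and escapes are timed by rounding noise, so dwell intervals
  jitter by tens of percent and the coupling path does not retrace; the
  idealized single-saddle cycle is only approximately visible.
- Exact-π crossing timestamps are meaningful only together with the
  transit-time filter (above); the filter's 5000-step cutoff is a scale
  choice, valid while 1/ε₂ ≫ 5000 ≫ phase-locking time.
- The predictor presupposes that an event occurs (it forecasts *who*
  switches, not *whether*); events whose snapshot falls before the
  two-cluster anchor are skipped.
- Waiting-time distributions and post-switch partitions are not predicted.
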