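"""Compiled Euler-Maruyama inner loop.

The kernel advances phases and couplings in lock-step and records, at every
step, the two Kuramoto order parameters and the angle of the second-order
mean field.  Optionally it stores the full-resolution *unwrapped* phase
series (needed for crossing detection and escape forecasting) and strided
snapshots of phases and couplings.

Trigonometry is factored through per-oscillator sin/cos so each step costs
O(N^2) multiplications rather than O(N^2) transcendental calls:
``sin(theta_i - theta_j + beta) = sd*cos(beta) + cd*sin(beta)`` with
``sd = s_i c_j - c_i s_j`` and ``cd = c_i c_j + s_i s_j``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DENSE = 0
SPARSE = 1
FREQ_ADAPTIVE = 2


@njit(cache=True)
def integrate(
    theta,          # (N,) wrapped phases, modified in place
    k,              # (N, N) couplings, modified in place
    unwrapped,      # (N,) unwrapped phase accumulator, modified in place
    omega,          # (N,) natural frequencies
    adj,            # (N, N) adjacency (ignored unless variant == SPARSE)
    variant,        # DENSE / SPARSE / FREQ_ADAPTIVE
    eps1, eps2, beta1, beta2, sigma, gamma0, alpha,
    dt, n_steps, seed,
    r_out,          # (n_steps+1,)
    r2_out,         # (n_steps+1,)
    psi2_out,       # (n_steps+1,)
    theta_full,     # (n_steps+1, N) unwrapped phases, or (0, 0) if unused
    theta_frames,   # (n_frames, N) wrapped snapshots, or (0, 0)
    k_frames,       # (n_frames, N, N), or (0, 0, 0)
    frame_stride,
):
    """Run ``n_steps`` Euler-Maruyama steps; return failing step or -1."""
    n = theta.shape[0]
    store_full = theta_full.shape[0] > 0
    store_theta = theta_frames.shape[0] > 0
    store_k = k_frames.shape[0] > 0
    cb1, sb1 = np.cos(beta1), np.sin(beta1)
    cb2, sb2 = np.cos(beta2), np.sin(beta2)
    ca, sa = np.cos(alpha), np.sin(alpha)
    sq = sigma * np.sqrt(dt)
    if sigma > 0.0:
        np.random.seed(seed)
    s = np.empty(n)
    c = np.empty(n)
    dth = np.empty(n)
    deg = np.empty(n)
    if variant == SPARSE:
        for i in range(n):
            deg[i] = adj[i].sum()
    two_pi = 2.0 * np.pi

    for t in range(n_steps + 1):
        sums = 0.0
        sumc = 0.0
        sum2s = 0.0
        sum2c = 0.0
        for i in range(n):
            s[i] = np.sin(theta[i])
            c[i] = np.cos(theta[i])
            sums += s[i]
            sumc += c[i]
            # double angle from single-angle sin/cos
            sum2s += 2.0 * s[i] * c[i]
            sum2c += c[i] * c[i] - s[i] * s[i]
        r_out[t] = np.sqrt(sums * sums + sumc * sumc) / n
        r2_out[t] = np.sqrt(sum2s * sum2s + sum2c * sum2c) / n
        psi2_out[t] = np.arctan2(sum2s, sum2c)
        if not np.isfinite(r_out[t]):
            return t
        if store_full:
            for i in range(n):
                theta_full[t, i] = unwrapped[i]
        if t % frame_stride == 0:
            f = t // frame_stride
            if store_theta:
                for i in range(n):
                    theta_frames[f, i] = theta[i]
            if store_k:
                for i in range(n):
                    for j in range(n):
                        k_frames[f, i, j] = k[i, j]
        if t == n_steps:
            break

        # --- phase velocities (deterministic part) ---
        if variant == DENSE:
            for i in range(n):
                acc_s = 0.0
                acc_c = 0.0
                for j in range(n):
                    acc_s += k[i, j] * s[j]
                    acc_c += k[i, j] * c[j]
                # sum_j k_ij sin(theta_j - theta_i) = c_i * (k s)_i - s_i * (k c)_i
                dth[i] = omega[i] + (c[i] * acc_s - s[i] * acc_c) / n
        elif variant == SPARSE:
            for i in range(n):
                acc_s = 0.0
                acc_c = 0.0
                for j in range(n):
                    w = adj[i, j] * k[i, j]
                    acc_s += w * s[j]
                    acc_c += w * c[j]
                dth[i] = omega[i] + (c[i] * acc_s - s[i] * acc_c) / deg[i]
        else:  # FREQ_ADAPTIVE
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    sd = s[i] * c[j] - c[i] * s[j]  # sin(theta_i - theta_j)
                    cd = c[i] * c[j] + s[i] * s[j]
                    acc += k[i, j] * (gamma0 - (sd * ca + cd * sa))
                dth[i] = omega[i] + acc / n

        # --- coupling update (deterministic; non-links frozen when sparse) ---
        for i in range(n):
            for j in range(i + 1, n):
                if variant == SPARSE and adj[i, j] == 0.0:
                    continue
                sd = s[i] * c[j] - c[i] * s[j]  # sin(theta_i - theta_j)
                cd = c[i] * c[j] + s[i] * s[j]
                k[i, j] += dt * (-eps1) * (k[i, j] + sd * cb1 + cd * sb1)
                # element (j, i): sin(theta_j - theta_i) = -sd, cos unchanged
                k[j, i] += dt * (-eps2) * (k[j, i] + (-sd) * cb2 + cd * sb2)

        # --- phase update with optional noise ---
        for i in range(n):
            inc = dt * dth[i]
            if sigma > 0.0:
                inc += sq * np.random.normal(0.0, 1.0)
            unwrapped[i] += inc
            theta[i] = (theta[i] + inc) % two_pi
    return -1
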