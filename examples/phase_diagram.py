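"""Reduced-scale (eps1, eps2) phase diagram with a quadratic boundary fit.

Fast Hebbian adaptation (eps1 large, eps2 small) produces two anti-phase
clusters; strengthening the slow anti-Hebbian rate destroys coherence.  The
full-scale protocol uses a 101 x 31 grid with 200 realizations per pixel;
here both are reduced so the script finishes in about a minute.
"""

from nrkuramoto import SweepSpec, fit_transition_boundary, sweep_epsilon_grid

spec = SweepSpec(
    N=10,
    eps1_step=0.001,     # full scale: 0.0001
    eps2_step=0.0003,    # full scale: 0.0001
    n_realizations=5,    # full scale: 200
    n_steps=20_000,      # full scale: 40_000
    seed=0,
)
diagram = sweep_epsilon_grid(spec)

symbols = {"anti_phase_clusters": "#", "incoherent": ".", "in_phase": "O"}
print("eps2 ->")
for i, e1 in enumerate(diagram.eps1_values):
    row = "".join(symbols[lab] for lab in diagram.labels[i])
    print(f"eps1={e1:.4f}  {row}")
print("\n'#' = two anti-phase clusters, '.' = incoherent")

fit = fit_transition_boundary(diagram)
if fit is None:
    print("boundary fit unavailable (need both labels present)")
else:
    a, b, c = fit.coefficients
    print(
        f"\nboundary fit: eps2 = {a:.3g}*eps1^2 + {b:.3g}*eps1 + {c:.3g} "
        f"({fit.points.shape[0]} boundary pixels, "
        f"max residual {abs(fit.residuals).max():.2g})"
    )
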