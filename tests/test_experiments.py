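"""Experiment orchestration: phase diagram, boundary fit, sweeps."""

import numpy as np
import pytest

from nrkuramoto import (
    ModelParams,
    PhaseDiagram,
    SimConfig,
    SweepSpec,
    connectivity_sweep,
    fit_transition_boundary,
    gamma_alpha_scan,
    noise_sweep,
    sweep_epsilon_grid,
)


@pytest.fixture(scope="module")
def tiny_diagram():
    spec = SweepSpec(
        N=10,
        eps1_max=0.01,
        eps2_max=0.003,
        eps1_step=0.005,
        eps2_step=0.0015,
        n_realizations=3,
        n_steps=20_000,
        seed=5,
    )
    return spec, sweep_epsilon_grid(spec)


class TestSweepEpsilonGrid:

    def test_grid_axes_match_spec(self, tiny_diagram):
        spec, diagram = tiny_diagram
        np.testing.assert_allclose(diagram.eps1_values, [0.0, 0.005, 0.01])
        np.testing.assert_allclose(diagram.eps2_values, [0.0, 0.0015, 0.003])
        assert diagram.labels.shape == (3, 3)

    def test_metastable_pixel_is_anti_phase(self):
        spec = SweepSpec(
            N=10,
            eps1_max=0.01,
            eps2_max=0.0001,
            eps1_step=0.01,
            eps2_step=0.0001,
            n_realizations=5,
            n_steps=40_000,
            seed=2,
        )
        diagram = sweep_epsilon_grid(spec)
        # pixel at (eps1=0.01, eps2=0.0001): the production metastable regime
        assert diagram.labels[-1, -1] == "anti_phase_clusters"

    def test_hebbian_dominated_vs_anti_hebbian_dominated(self, tiny_diagram):
        _, diagram = tiny_diagram
        # strong eps1, small eps2 -> clustered; eps2 comparable to eps1 -> incoherent
        assert diagram.labels[-1, 1] == "anti_phase_clusters"
        assert diagram.labels[1, -1] == "incoherent"

    def test_deterministic_given_seed(self):
        spec = SweepSpec(
            N=6,
            eps1_max=0.01,
            eps2_max=0.0002,
            eps1_step=0.01,
            eps2_step=0.0002,
            n_realizations=1,
            n_steps=5000,
            seed=9,
        )
        a, b = sweep_epsilon_grid(spec), sweep_epsilon_grid(spec)
        np.testing.assert_array_equal(a.mean_R, b.mean_R)
        np.testing.assert_array_equal(a.mean_R2, b.mean_R2)


class TestBoundaryFit:
    def _synthetic_diagram(self, a):
        e1 = np.linspace(0, 0.01, 11)
        e2 = np.linspace(0, 0.003, 31)
        labels = np.empty((11, 31), dtype=object)
        for i, x in enumerate(e1):
            for j, y in enumerate(e2):
                labels[i, j] = "incoherent" if y >= a * x * x else "anti_phase_clusters"
        return PhaseDiagram(
            eps1_values=e1,
            eps2_values=e2,
            mean_R=np.zeros((11, 31)),
            mean_R2=np.zeros((11, 31)),
            labels=labels,
        )

    def test_recovers_known_quadratic(self):
        a = 20.0
        fit = fit_transition_boundary(self._synthetic_diagram(a))
        # boundary pixels snap up to the grid, so allow one pixel of slack
        pred = np.polyval(fit.coefficients, np.linspace(0, 0.01, 11))
        truth = a * np.linspace(0, 0.01, 11) ** 2
        assert np.max(np.abs(pred - truth)) < 1e-4  # one eps2 grid step

    def test_exact_grid_aligned_quadratic_recovered_to_high_precision(self):
        e1 = np.arange(5, dtype=float)
        e2 = np.arange(20, dtype=float)
        labels = np.empty((5, 20), dtype=object)
        for i, x in enumerate(e1):
            for j, y in enumerate(e2):
                labels[i, j] = "incoherent" if y >= x * x else "anti_phase_clusters"
        d = PhaseDiagram(e1, e2, np.zeros((5, 20)), np.zeros((5, 20)), labels)
        fit = fit_transition_boundary(d)
        np.testing.assert_allclose(fit.coefficients, [1.0, 0.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_single_label_diagram_unavailable(self):
        e1 = np.linspace(0, 0.01, 5)
        e2 = np.linspace(0, 0.003, 5)
        labels = np.full((5, 5), "anti_phase_clusters", dtype=object)
        d = PhaseDiagram(e1, e2, np.zeros((5, 5)), np.zeros((5, 5)), labels)
        assert fit_transition_boundary(d) is None


class TestNoiseSweep:
    def test_metastability_survives_weak_noise(self):
        cfg = SimConfig(n_steps=100_000)
        recs = noise_sweep([0.0, 1e-5], ModelParams(N=50), cfg, seed=4)
        assert [r["label"] for r in recs] == ["anti_phase_clusters"] * 2

    def test_strong_noise_degrades_cluster_coherence(self):
        """sigma = 0.1 leaves only remnants of the two-cluster state: R2 is
        pulled well below its weak-noise value and dips under the threshold
        repeatedly."""
        cfg = SimConfig(n_steps=100_000)
        recs = noise_sweep(
            [1e-5, 0.1], ModelParams(N=50), cfg, seed=4, detect_events=False
        )
        weak, strong = recs
        assert strong["mean_R2"] < weak["mean_R2"] - 0.04
        assert strong["mean_R2"] < 0.96
        assert strong["mean_R"] < 0.8

    def test_shared_initial_condition_across_sigmas(self):
        cfg = SimConfig(n_steps=200)
        recs = noise_sweep([0.0, 0.0], ModelParams(N=8), cfg, seed=6, detect_events=False)
        np.testing.assert_array_equal(
            recs[0]["trajectory"].R, recs[1]["trajectory"].R
        )


class TestConnectivitySweep:
    def test_complete_graph_point_runs_and_reports(self):
        cfg = SimConfig(n_steps=150_000)
        tab = connectivity_sweep(10, [9], 2, config=cfg, seed=8)
        assert tab.shape[0] == 1
        assert tab.realized_mean_degree.iloc[0] == pytest.approx(9.0)
        assert tab.n_intervals.iloc[0] >= 1


class TestGammaAlphaScan:
    def test_moderate_gain_keeps_two_clusters_strong_gain_destroys_them(self):
        cfg = SimConfig(n_steps=40_000)
        tab = gamma_alpha_scan([0.1, 0.8], [0.0], N=10, config=cfg, seed=3)
        row_weak = tab[tab.gamma0 == 0.1].iloc[0]
        row_strong = tab[tab.gamma0 == 0.8].iloc[0]
        assert row_weak.label == "anti_phase_clusters"
        assert row_weak.phase_gap == pytest.approx(np.pi, abs=0.3)
        assert row_strong.label == "incoherent"
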