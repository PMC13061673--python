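"""Order parameters, classification, clustering, switching and dwell times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrkuramoto import (
    ClusterPartition,
    ModelParams,
    SimConfig,
    ValidationError,
    assign_clusters,
    classify_state,
    detect_switch_events,
    dwell_intervals,
    equilibrium_two_cluster,
    order_parameters,
    sample_initial_condition,
    simulate,
)
from nrkuramoto.observables import merge_dwell_intervals


class TestOrderParameters:
    def test_full_synchrony(self):
        op = order_parameters(np.full(7, 1.3))
        assert op.R == pytest.approx(1.0)
        assert op.R2 == pytest.approx(1.0)

    def test_two_balanced_anti_phase_clusters(self):
        op = order_parameters(np.array([0.0, 0.0, np.pi, np.pi]))
        assert op.R == pytest.approx(0.0, abs=1e-15)
        assert op.R2 == pytest.approx(1.0)

    def test_four_fold_symmetry_kills_both(self):
        op = order_parameters(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert op.R == pytest.approx(0.0, abs=1e-15)
        assert op.R2 == pytest.approx(0.0, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            order_parameters(np.array([]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        shift=st.floats(-7, 7, allow_nan=False),
        n=st.integers(1, 15),
        seed=st.integers(0, 2**20),
    )
    def test_magnitudes_invariant_under_global_shift(self, shift, n, seed):
        theta = np.random.default_rng(seed).uniform(0, 2 * np.pi, n)
        a, b = order_parameters(theta), order_parameters(theta + shift)
        assert a.R == pytest.approx(b.R, abs=1e-12)
        assert a.R2 == pytest.approx(b.R2, abs=1e-12)


class TestClassifyState:
    @pytest.mark.parametrize(
        "r, r2, expected",
        [
            (0.95, 0.97, "in_phase"),
            (0.30, 0.95, "anti_phase_clusters"),
            (0.80, 0.95, "anti_phase_clusters"),  # boundary: <= is anti-phase
            (0.85, 0.70, "incoherent"),
            (0.10, 0.20, "incoherent"),
            (0.81, 0.80, "incoherent"),  # R2 must strictly exceed the threshold
        ],
    )
    def test_rule_table(self, r, r2, expected):
        assert classify_state(r, r2) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_state(1.4, 0.5)


class TestAssignClusters:
    def test_balanced_noisy_split(self):
        theta = np.array([0.1, -0.1, np.pi + 0.05, np.pi - 0.05])
        part = assign_clusters(theta)
        assert part.sizes == (2, 2)

    def test_three_one_split(self):
        part = assign_clusters(np.array([0.0, 0.0, 0.0, np.pi]))
        assert part.sizes == (3, 1)

    def test_round_trip_with_equilibrium(self):
        labels = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1])
        params = ModelParams(N=9)
        state = equilibrium_two_cluster(ClusterPartition(labels=labels), params)
        part = assign_clusters(state.theta)
        assert part == ClusterPartition(labels=labels)

    def test_no_structure_returns_none(self):
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        assert assign_clusters(theta) is None

    @pytest.mark.parametrize("labels", [[0, 0, 1, 1], [0, 0, 0, 1], [0, 1, 1, 1, 1]])
    def test_equilibrium_R_equals_imbalance_over_N(self, labels):
        """Two-cluster equilibrium has R = |NA - NB| / N and R2 = 1 exactly."""
        labels = np.array(labels)
        state = equilibrium_two_cluster(
            ClusterPartition(labels=labels), ModelParams(N=labels.size)
        )
        op = order_parameters(state.theta)
        d = abs((labels == 0).sum() - (labels == 1).sum())
        assert op.R == pytest.approx(d / labels.size, abs=1e-12)
        assert op.R2 == pytest.approx(1.0)


@pytest.fixture(scope="module")
def metastable_traj():
    params = ModelParams(N=10)
    cfg = SimConfig(n_steps=400_000, store_phases=True)
    ic = sample_initial_condition(10, seed=np.random.SeedSequence(1))
    return simulate(params, cfg, ic.as_state())


class TestSwitchDetection:
    def test_events_detected_in_metastable_run(self, metastable_traj):
        events = detect_switch_events(metastable_traj)
        assert len(events) >= 1
        for ev in events:
            assert len(ev.actual_set) >= 1
            assert ev.t_event > int(0.3 * metastable_traj.n_steps)

    def test_events_change_the_partition(self, metastable_traj):
        for ev in detect_switch_events(metastable_traj):
            moved = np.flatnonzero(
                ev.pre_partition.labels != ev.post_partition.labels
            )
            # oscillators that crossed an odd number of times changed label
            assert set(moved) <= set(ev.actual_set) | set()

    def test_events_sit_near_R2_minima(self, metastable_traj):
        """Soft consistency: each event within a window of a local R2 dip."""
        r2 = metastable_traj.R2
        for ev in detect_switch_events(metastable_traj):
            lo = max(ev.t_event - 3000, 0)
            hi = min(ev.t_event + 3000, r2.size)
            assert r2[lo:hi].min() < r2.mean()

    def test_reciprocal_hebbian_control_has_no_events(self):
        params = ModelParams(
            N=10, eps1=0.001, eps2=0.001, beta1=-np.pi / 2, beta2=-np.pi / 2
        )
        cfg = SimConfig(n_steps=150_000, store_phases=True)
        ic = sample_initial_condition(10, seed=np.random.SeedSequence(2))
        traj = simulate(params, cfg, ic.as_state())
        assert detect_switch_events(traj) == []

    def test_requires_full_resolution_phases(self, metastable_params):
        cfg = SimConfig(n_steps=1000, store_phases=False, record_stride=1000)
        ic = sample_initial_condition(10, seed=np.random.SeedSequence(3))
        traj = simulate(metastable_params, cfg, ic.as_state())
        from nrkuramoto.errors import UnsupportedConfigurationError

        with pytest.raises(UnsupportedConfigurationError):
            detect_switch_events(traj)


class TestDwellIntervals:
    def test_single_full_interval(self):
        ivs = dwell_intervals(np.full(100, 0.3), np.full(100, 0.95))
        assert len(ivs) == 1 and ivs[0].duration == 100

    def test_dip_splits_interval(self):
        r2 = np.full(100, 0.95)
        r2[50] = 0.5
        ivs = dwell_intervals(np.full(100, 0.3), r2)
        assert len(ivs) == 2
        assert ivs[0].end == 50 and ivs[1].start == 51

    def test_incoherent_series_has_no_dwells(self):
        assert dwell_intervals(np.full(50, 0.2), np.full(50, 0.2)) == []

    def test_merge_closes_short_gaps(self):
        r2 = np.full(100, 0.95)
        r2[50] = 0.5
        ivs = dwell_intervals(np.full(100, 0.3), r2)
        merged = merge_dwell_intervals(ivs, merge_gap=10)
        assert len(merged) == 1 and merged[0].duration == 100
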