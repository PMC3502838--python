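"""Tests of the synthetic EDL forward simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgi.exceptions import ValidationError
from ecgi.synthetic import (ApTemplate, SimulationConfig, add_noise,
                            assign_templates, default_templates,
                            forward_project, make_activation_map,
                            make_ap_waveform, make_transfer_matrix,
                            simulate_dataset, simulate_tmps, spheroid_points,
                            split_train_test)


class TestApWaveform:
    def test_rest_before_activation(self):
        tp = ApTemplate()
        assert make_ap_waveform(tp, 10.0, 9.0) == tp.resting_potential

    def test_plateau_reached_mid_apd(self):
        # with a short upstroke and no sag, mid-APD sits on the plateau
        tp = ApTemplate(upstroke_duration=2.0, apd=250.0, plateau_decay=0.0)
        v = make_ap_waveform(tp, 5.0, 5.0 + tp.apd / 2)
        assert abs(v - tp.plateau_potential) < 1.0

    def test_upstroke_monotone(self):
        tp = ApTemplate()
        t = np.arange(20.0, 20.0 + tp.upstroke_duration + 1e-9, 1.0)
        v = make_ap_waveform(tp, 20.0, t)
        assert np.all(np.diff(v) >= 0)

    def test_returns_to_rest_after_repolarization(self):
        tp = ApTemplate(plateau_decay=0.03)
        t_end = 5.0 + tp.apd + tp.repolarization_duration
        assert make_ap_waveform(tp, 5.0, t_end + 1.0) == tp.resting_potential

    @pytest.mark.parametrize("bad", [
        dict(upstroke_duration=-1.0),
        dict(apd=-5.0),
        dict(plateau_potential=-95.0),        # below rest
        dict(apd=1.0, upstroke_duration=2.0),  # apd <= upstroke
    ])
    def test_invalid_template_rejected(self, bad):
        with pytest.raises(ValidationError):
            ApTemplate(**bad)


class TestActivationMap:
    def test_breakthrough_site_activates_at_zero(self, rng):
        pos = rng.normal(0, 1, (20, 3))
        am = make_activation_map(pos, [4], 1.0)
        assert am.activation_time[4] == 0.0

    def test_distance_over_velocity(self):
        pos = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        am = make_activation_map(pos, [0], 1.0)
        assert am.activation_time[1] == pytest.approx(5.0)

    def test_two_sites_elementwise_min(self, rng):
        pos = rng.normal(0, 5, (30, 3))
        # brute-force oracle: elementwise min of unshifted per-site maps
        d = [np.linalg.norm(pos - pos[s], axis=1) / 2.0 for s in (3, 17)]
        expected = np.minimum(*d)
        expected -= expected.min()
        both = make_activation_map(pos, [3, 17], 2.0)
        np.testing.assert_allclose(both.activation_time, expected, atol=1e-12)

    def test_empty_sites_rejected(self, rng):
        with pytest.raises(ValidationError):
            make_activation_map(rng.normal(0, 1, (5, 3)), [], 1.0)


class TestSimulateTmps:
    def test_all_resting_before_activation(self):
        pos = spheroid_points(10)
        am = make_activation_map(pos, [0], 1e-3)  # very slow conduction
        tp = ApTemplate()
        tmps = simulate_tmps([tp] * 10, am, np.array([0.0]))
        # only the breakthrough node has begun depolarizing at t=0
        assert np.all(tmps[1:, 0] == tp.resting_potential)

    def test_matches_per_node_waveform(self, rng):
        pos = rng.normal(0, 3, (8, 3))
        am = make_activation_map(pos, [2], 1.0)
        classes = default_templates(2)
        templates = assign_templates(8, classes)
        times = np.arange(0.0, 50.0, 5.0)
        tmps = simulate_tmps(templates, am, times)
        for i in range(8):      # row oracle: standalone waveform trace
            np.testing.assert_array_equal(
                tmps[i],
                make_ap_waveform(templates[i], am.activation_time[i], times))

    def test_wrong_template_count_rejected(self, rng):
        pos = rng.normal(0, 1, (5, 3))
        am = make_activation_map(pos, [0], 1.0)
        with pytest.raises(ValidationError):
            simulate_tmps([ApTemplate()] * 4, am, np.arange(3.0))


class TestTransferMatrix:
    def test_shape_and_condition(self):
        tm = make_transfer_matrix(40, 50, 1e6, seed=0)
        assert tm.A.shape == (40, 50)
        realized = np.linalg.cond(tm.A)
        assert abs(realized / 1e6 - 1) < 0.01

    def test_paper_scale_condition(self):
        # full-scale operator: 412 leads x 478 nodes at condition 5.6e12
        tm = make_transfer_matrix(412, 478, 5.6e12, seed=1)
        assert tm.A.shape == (412, 478)
        sv = np.linalg.svd(tm.A, compute_uv=False)
        assert abs(sv[0] / sv[-1] / 5.6e12 - 1) < 0.01

    def test_unit_condition_gives_equal_singular_values(self):
        tm = make_transfer_matrix(6, 8, 1.0, seed=3)
        sv = np.linalg.svd(tm.A, compute_uv=False)
        np.testing.assert_allclose(sv, sv[0], rtol=1e-12)

    def test_deterministic_given_seed(self):
        a = make_transfer_matrix(10, 12, 1e4, seed=9).A
        b = make_transfer_matrix(10, 12, 1e4, seed=9).A
        np.testing.assert_array_equal(a, b)

    def test_condition_below_one_rejected(self):
        with pytest.raises(ValidationError):
            make_transfer_matrix(5, 5, 0.5, seed=0)


class TestForwardProject:
    def test_identity(self, rng):
        from ecgi.synthetic import TransferMatrix
        tmps = rng.normal(0, 1, (4, 6))
        out = forward_project(np.eye(4), tmps)
        np.testing.assert_array_equal(out, tmps)

    def test_hand_computed_product(self):
        A = np.array([[1.0, 2.0], [0.0, 1.0], [3.0, -1.0]])
        tmps = np.array([[1.0, 0.0], [2.0, 1.0]])
        expected = np.array([[5.0, 2.0], [2.0, 1.0], [1.0, -1.0]])
        np.testing.assert_array_equal(forward_project(A, tmps), expected)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            forward_project(rng.normal(0, 1, (3, 4)), rng.normal(0, 1, (5, 2)))


class TestNoise:
    def test_none_disables_noise(self, rng):
        b = rng.normal(0, 1, (10, 10))
        np.testing.assert_array_equal(add_noise(b, None, 0), b)

    def test_realized_snr_close_to_requested(self, rng):
        b = rng.normal(0, 3, (400, 300))     # >= 1e5 entries
        noisy = add_noise(b, 30.0, seed=5)
        noise = noisy - b
        snr = 10 * np.log10(np.mean(b ** 2) / np.mean(noise ** 2))
        assert abs(snr - 30.0) < 0.5

    def test_seeded_reproducibility(self, rng):
        b = rng.normal(0, 1, (20, 20))
        np.testing.assert_array_equal(add_noise(b, 20.0, 3),
                                      add_noise(b, 20.0, 3))


class TestSplit:
    def test_protocol_counts(self):
        """358 instants at 1 ms, test grid 3,9,...,357 -> 60 test, 298 train."""
        times = np.arange(0.0, 358.0)
        train, test = split_train_test(times, 3.0, 6.0)
        assert test.size == 60
        assert train.size == 298

    def test_step_beyond_range_single_test(self):
        times = np.arange(1.0, 11.0)
        train, test = split_train_test(times, 1.0, 1000.0)
        assert test.size == 1 and times[test[0]] == 1.0

    @given(start=st.integers(1, 7), step=st.integers(1, 9),
           n=st.integers(10, 80))
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration(self, start, step, n):
        times = np.arange(float(n))
        expected = {t for t in times
                    if t >= start and (t - start) % step == 0}
        if not expected:
            return
        train, test = split_train_test(times, float(start), float(step))
        assert {times[i] for i in test} == expected
        assert set(train) | set(test) == set(range(n))
        assert set(train) & set(test) == set()

    def test_no_match_rejected(self):
        with pytest.raises(ValidationError):
            split_train_test(np.arange(5.0), 100.0, 7.0)


class TestDatasetGeneration:
    def test_forward_consistency_and_metadata(self, small_dataset):
        ds = small_dataset
        np.testing.assert_allclose(ds.bsps_clean, ds.transfer.A @ ds.tmps,
                                   rtol=0, atol=1e-9)
        assert ds.train_indices.size == 298 and ds.test_indices.size == 60
        assert set(ds.train_indices) & set(ds.test_indices) == set()
        assert ds.snr_db == 30.0

    def test_bit_reproducible(self):
        cfg = SimulationConfig(n_leads=8, n_nodes=10, duration_ms=30.0,
                               condition=100.0, seed=3)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        np.testing.assert_array_equal(a.bsps_noisy, b.bsps_noisy)
        np.testing.assert_array_equal(a.tmps, b.tmps)

    def test_roundtrip_save_load(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(
            n_leads=6, n_nodes=8, duration_ms=20.0, condition=50.0,
            test_start_ms=3.0, test_step_ms=6.0, seed=2))
        ds.save(tmp_path)
        back = ds.load(tmp_path)
        np.testing.assert_allclose(back.tmps, ds.tmps, rtol=1e-8)
        np.testing.assert_array_equal(back.test_indices, ds.test_indices)
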