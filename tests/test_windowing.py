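"""Stride computation, segmentation, normalization, rotation, weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fogdetect import (
    Cohort,
    SensorLocation,
    augment_rotation,
    compute_stride,
    compute_weights,
    majority_label,
    normalize_windows,
    segment,
)
from fogdetect.windowing import expected_window_count

from conftest import make_recording


class TestComputeStride:
    def test_single_walk_unit_stride(self):
        assert compute_stride([102.0], 2.0, 101, 64.0) == 1.0

    def test_non_overlapping(self):
        assert compute_stride([10.0], 2.0, 5, 64.0) == 2.0

    def test_ten_thousand_window_rule(self):
        """60 equal walks, target 10,000 -> achieved within [10000, 10500]."""
        durations = [88.8 * 60 / 60] * 60  # 88.8 min over 60 walks
        stride = compute_stride(durations, 2.0, 10_000, 64.0)
        achieved = expected_window_count(durations, 2.0, stride)
        assert 10_000 <= achieved <= 10_500
        # largest such stride: one sample more falls below target
        bigger = stride + 1 / 64.0
        assert expected_window_count(durations, 2.0, bigger) < 10_000

    def test_infeasible_target_reports_maximum(self):
        with pytest.raises(ValueError, match="achievable"):
            compute_stride([4.0], 2.0, 1000, 64.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        durations=st.lists(st.floats(4.0, 60.0), min_size=1, max_size=8),
        target=st.integers(8, 400),
    )
    def test_largest_feasible_on_grid(self, durations, target):
        try:
            stride = compute_stride(durations, 2.0, target, 64.0)
        except ValueError:
            assert expected_window_count(durations, 2.0, 1 / 64.0) < target
            return
        assert expected_window_count(durations, 2.0, stride) >= target
        assert expected_window_count(durations, 2.0, stride + 1 / 64.0) < target


class TestMajorityLabel:
    @pytest.mark.parametrize(
        "n_true,n_total,expected",
        [(65, 128, True), (0, 128, False), (64, 128, True), (63, 128, False)],
    )
    def test_counts(self, n_true, n_total, expected):
        labels = np.zeros(n_total, dtype=bool)
        labels[:n_true] = True
        assert majority_label(labels) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_label(np.array([], dtype=bool))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_matches_brute_count(self, labels):
        arr = np.array(labels)
        assert majority_label(arr) == (sum(labels) >= len(labels) - sum(labels))


class TestSegment:
    def _one_walk_cohort(self, n=640, labels=None, seed=0):
        rec = make_recording(n_samples=n, seed=seed,
                             sensors=(SensorLocation.ANKLE_L, SensorLocation.HEAD))
        if labels is not None:
            rec.labels = labels
        other = make_recording(n_samples=n, participant_id="P02", seed=seed + 1,
                               sensors=(SensorLocation.ANKLE_L, SensorLocation.HEAD))
        return Cohort([rec, other]), rec

    def test_window_count_and_starts(self):
        cohort, _ = self._one_walk_cohort()  # 10 s walks at 64 Hz
        ws = segment(cohort, ["ankle_L"], 2.0, 2.0)
        per_walk = ws.start_s[ws.participant_ids == "P01"]
        assert list(per_walk) == [0.0, 2.0, 4.0, 6.0, 8.0]
        assert len(ws) == 10

    def test_stride_one_second(self):
        cohort, _ = self._one_walk_cohort()
        ws = segment(cohort, ["ankle_L"], 2.0, 1.0)
        assert (ws.participant_ids == "P01").sum() == 9

    def test_all_false_labels(self):
        cohort, rec = self._one_walk_cohort(labels=np.zeros(640, dtype=bool))
        ws = segment(cohort, ["ankle_L"], 2.0, 1.0)
        assert not ws.labels[ws.participant_ids == "P01"].any()

    def test_window_labels_are_majorities(self):
        cohort, rec = self._one_walk_cohort(seed=3)
        ws = segment(cohort, ["ankle_L"], 2.0, 1.0)
        sel = ws.participant_ids == "P01"
        for start, lab in zip(ws.start_s[sel], ws.labels[sel]):
            i = int(start * 64)
            assert lab == majority_label(rec.labels[i:i + 128])

    def test_closed_form_count_invariant(self, tiny_cohort):
        for stride in (0.5, 1.0, 2.0):
            ws = segment(tiny_cohort, ["ankle_L"], 2.0, stride)
            expected = expected_window_count(
                [w.duration_s for w in tiny_cohort.walks], 2.0, stride
            )
            assert len(ws) == expected

    def test_channel_order_is_canonical(self, tiny_cohort):
        ws = segment(tiny_cohort, ["ankle_L", "head"], 2.0, 2.0)
        # canonical order puts head before ankle_L regardless of request order
        assert ws.sensor_set == (SensorLocation.HEAD, SensorLocation.ANKLE_L)
        assert ws.n_channels == 12

    def test_missing_sensor_named(self, tiny_cohort):
        with pytest.raises(ValueError, match="lumbar"):
            segment(tiny_cohort, ["lumbar"], 2.0, 2.0)


class TestNormalize:
    def test_hand_computed_row(self):
        row = np.array([[1.0, 2.0, 3.0, 4.0]])
        out = normalize_windows(row)
        expected = np.array([-1.342, -0.447, 0.447, 1.342])
        assert np.allclose(out[0], expected, atol=1e-3)

    def test_constant_row_zeroed(self):
        out = normalize_windows(np.full((3, 16), 5.0))
        assert np.all(out == 0.0)

    def test_idempotent(self, rng):
        x = rng.standard_normal((4, 6, 64))
        once = normalize_windows(x)
        assert np.allclose(normalize_windows(once), once, atol=1e-9)

    def test_moments(self, rng):
        x = rng.standard_normal((5, 6, 128)) * 3 + 1
        out = normalize_windows(x)
        assert np.all(np.abs(out.mean(axis=-1)) < 1e-6)
        assert np.all(np.abs(out.var(axis=-1) - 1) < 1e-6)


class TestAugmentRotation:
    def test_zero_angle_identity(self, rng):
        x = rng.standard_normal((2, 12, 32))
        out = augment_rotation(x, rng, max_angle_rad=0.0)
        assert np.allclose(out, x, atol=1e-12)

    def test_ninety_degrees_about_z(self, rng):
        x = np.zeros((1, 6, 4))
        x[0, 0] = 1.0  # accel x
        angles = np.array([[[0.0, 0.0, np.pi / 2]]])
        out = augment_rotation(x, rng, angles=angles)
        assert np.allclose(out[0, 0], 0.0, atol=1e-9)  # x -> 0
        assert np.allclose(out[0, 1], 1.0, atol=1e-9)  # becomes +y

    def test_norm_preservation_many_draws(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 12, 20))
        worst = 0.0
        for _ in range(20):  # 20 x 50 windows = 1,000 random rotations
            out = augment_rotation(x, rng)
            norms_in = np.linalg.norm(x.reshape(50, 4, 3, 20), axis=2)
            norms_out = np.linalg.norm(out.reshape(50, 4, 3, 20), axis=2)
            worst = max(worst, float(np.max(np.abs(norms_in - norms_out))))
        assert worst < 1e-9

    def test_rotation_then_normalize_unit_variance(self, rng):
        x = rng.standard_normal((4, 6, 64)) * 2 + 0.3
        out = normalize_windows(augment_rotation(x, rng))
        nonzero = out.std(axis=-1) > 0
        assert np.all(np.abs(out.var(axis=-1)[nonzero] - 1) < 1e-6)


class TestComputeWeights:
    def _ws(self, labels_by_participant):
        from fogdetect.windowing import WindowSet

        labels, pids = [], []
        for p, labs in labels_by_participant.items():
            labels.extend(labs)
            pids.extend([p] * len(labs))
        n = len(labels)
        return WindowSet(
            data=np.zeros((n, 6, 8), dtype=np.float32),
            labels=np.array(labels, dtype=bool),
            participant_ids=np.array(pids, dtype=object),
            walk_ids=np.array(["w"] * n, dtype=object),
            start_s=np.zeros(n),
            sensor_set=(SensorLocation.ANKLE_L,),
            sample_rate=4.0,
            window_len_s=2.0,
            stride_s=2.0,
        )

    def test_forced_arithmetic(self):
        ws = self._ws({"A": [True] * 100 + [False] * 300})
        ws = compute_weights(ws)
        assert np.allclose(ws.weights[ws.labels], 0.005)
        assert np.allclose(ws.weights[~ws.labels], 0.5 / 300)

    def test_sums_per_participant_and_class(self):
        ws = self._ws({"A": [True] * 3 + [False] * 7, "B": [True] * 5 + [False] * 5})
        ws = compute_weights(ws)
        for p in ("A", "B"):
            sel = ws.participant_ids == p
            assert abs(ws.weights[sel].sum() - 1.0) < 1e-9
            for cls in (True, False):
                assert abs(ws.weights[sel & (ws.labels == cls)].sum() - 0.5) < 1e-9
        assert abs(ws.weights.sum() - 2.0) < 1e-9

    def test_missing_class_listed(self):
        ws = self._ws({"A": [True] * 4, "B": [True, False, True, False]})
        with pytest.raises(ValueError, match="A"):
            compute_weights(ws)

    def test_weights_independent_of_channels(self, tiny_cohort):
        a = compute_weights(segment(tiny_cohort, ["ankle_L", "head"], 2.0, 1.0))
        b = compute_weights(segment(tiny_cohort, ["ankle_L"], 2.0, 1.0))
        assert np.allclose(a.weights, b.weights)
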